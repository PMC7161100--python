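"""Exception hierarchy for gtmerge."""


class GtmergeError(Exception):
    """Base class for all gtmerge errors."""


class NewickError(GtmergeError, ValueError):
    """Raised when newick text cannot be parsed into a valid tree."""


class ValidationError(GtmergeError, ValueError):
    """Raised when an input violates a documented precondition."""


class InvariantError(GtmergeError, RuntimeError):
    """Raised when an internal invariant of the merge algorithm fails.

    If this ever surfaces on valid inputs it indicates a bug, not a bad
    input; the offending bipartition (when known) is attached for
    diagnosis.
    """

    def __init__(self, message, bipartition=None):
        super().__init__(message)
        self.bipartition = bipartition


class ResourceLimitError(GtmergeError, RuntimeError):
    """Raised when a brute-force enumeration would exceed its configured cap."""
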