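import random

import pytest
from hypothesis import HealthCheck, settings

from gtmerge import Tree, parse_newick
from gtmerge.synth import default_taxa, random_binary_tree

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def caterpillar8() -> Tree:
    """The 8-taxon caterpillar used as the motivating guide tree."""
    return parse_newick("(1,(2,(3,(4,(5,(6,(7,8)))))));")


@pytest.fixture
def half1() -> Tree:
    """Constraint tree on {1,5,6,7} compatible with the caterpillar."""
    return parse_newick("(1,(5,(6,7)));")


@pytest.fixture
def half2() -> Tree:
    """Constraint tree on {2,3,4,8}."""
    return parse_newick("(2,(3,(4,8)));")


def random_instance(rng: random.Random, k: int, max_size: int):
    """A fully random merge problem: independent random constraint trees
    on a shuffled label partition, and an unrelated random guide."""
    sizes = [rng.randint(1, max_size) for _ in range(k)]
    while sum(sizes) < 4:
        sizes[rng.randrange(k)] += 1
    labels = default_taxa(sum(sizes))
    rng.shuffle(labels)
    constraints = []
    idx = 0
    for s in sizes:
        constraints.append(
            random_binary_tree(labels[idx:idx + s], rng.randrange(2**31))
        )
        idx += s
    guide = random_binary_tree(sorted(labels), rng.randrange(2**31))
    return guide, constraints
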