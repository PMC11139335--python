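import random

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def worked_example():
    """The deterministic four-gene worked-example fixture."""
    from introntrace.synthetic_data import make_worked_example_fixture

    return make_worked_example_fixture()


@pytest.fixture()
def worked_example_proteins(worked_example):
    """Worked-example fixture pushed through the annotation stage."""
    from introntrace import annotate_gene, parse_gff3

    genome = worked_example.genomes["celegans"]
    models = parse_gff3(worked_example.gff3["celegans"], genome, species_id="celegans")
    return {m.gene_id: annotate_gene(m, genome) for m in models}


def random_binary_newick(leaves: list[str], rng: random.Random) -> str:
    """Random rooted binary topology over the given leaf labels."""
    nodes = list(leaves)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def all_binary_topologies(leaves: tuple[str, ...]):
    """Enumerate every rooted binary labeled topology (as Newick strings)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    # partition rest into the sibling sets of the two root children,
    # anchoring `first` on the left to avoid double counting
    n = len(rest)
    for mask in range(2 ** n):
        left_extra = [rest[i] for i in range(n) if mask & (1 << i)]
        right = [rest[i] for i in range(n) if not mask & (1 << i)]
        if not right:
            continue
        for lt in all_binary_topologies(tuple([first] + left_extra)):
            for rt in all_binary_topologies(tuple(right)):
                yield f"({lt},{rt})"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
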