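from collections import defaultdict

import pytest

from genediv import generate_phylotype_pool


def partition_of(labels: dict) -> set:
    """Order-free representation of a clustering as a set of frozensets."""
    groups = defaultdict(set)
    for sid, pid in labels.items():
        groups[pid].add(sid)
    return {frozenset(g) for g in groups.values()}


@pytest.fixture(scope="session")
def small_pool():
    """5 phylotypes x 3 variants with comfortable identity margins."""
    pool, truth = generate_phylotype_pool(
        n_phylotypes=5,
        variants_per_phylotype=3,
        seq_len_aa=80,
        between_identity_max=0.60,
        within_identity_min=0.96,
        seed=11,
        family="fam",
    )
    return pool, truth
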