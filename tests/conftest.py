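from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from amptax import build_tree, run_pipeline

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: A small hand-written taxonomy used across modules: two phyla, two genera
#: in the first, three species total, plus a lineage that stops at a phylum.
TINY_RECORDS = [
    ("seqA", "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae; g__Bacillus; s__subtilis"),
    ("seqB", "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae; g__Bacillus; s__cereus"),
    ("seqC", "k__Bacteria; p__Firmicutes; c__Clostridia; o__Clostridiales; f__Clostridiaceae; g__Clostridium; s__butyricum"),
    ("seqD", "k__Bacteria; p__Proteobacteria; c__; o__; f__; g__Escherichia; s__coli"),
    ("seqE", "k__Bacteria; p__Bacteroidetes"),
]


@pytest.fixture(scope="session")
def tiny_taxonomy():
    return build_tree(TINY_RECORDS)


@pytest.fixture(scope="session")
def benchmark_run():
    """The scaled-down per-read accuracy benchmark shared by the acceptance
    tests: 4 phyla / 12 genera / 24 species, 10,000 paired 250-bp reads at
    2% per-base substitution, classified against a k=35 index built from the
    same references."""
    return run_pipeline(
        n_phyla=4,
        genera_per_phylum=3,
        species_per_genus=2,
        profile_kind="gut-like",
        primer="V34",
        n_reads=10_000,
        read_len=250,
        mut_rate=0.02,
        k=35,
        seed=1,
    )
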