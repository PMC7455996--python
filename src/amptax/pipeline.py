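"""One-call wiring of simulate -> build -> classify for in-memory experiments.

This is the programmatic counterpart of the CLI workflow: generate a
synthetic community, build the k-mer database from the very same references,
classify every simulated read pair, and hand back all intermediate objects
so abundance estimation and metrics can be layered on top.  Tests, examples
and the reproduction script all drive the package through this surface.

Seeding: the three stochastic stages (reference generation, community
profile, read simulation) consume ``seed``, ``seed + 1`` and ``seed + 2`` so
one small integer pins the whole experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classifier import ReadClassification, classify_read, direct_counts
from .kmer_index import KmerIndex, build_index
from .simulator import (
    PRIMER_WINDOWS,
    CommunityProfile,
    PrimerWindow,
    extract_amplicon,
    make_profile,
    make_references,
    simulate_reads,
)
from .taxonomy import TaxonomyTree, build_tree


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, ready for downstream analysis."""

    tree: TaxonomyTree
    seq_to_taxon: dict[str, int]
    refs: list[tuple[str, str]]
    db_refs: list[tuple[str, str]]
    tax_records: list[tuple[str, str]]
    profile: CommunityProfile
    window: PrimerWindow
    index: KmerIndex
    reads: list[tuple[str, ...]]
    truth: dict[str, tuple[int, str]]
    classifications: list[ReadClassification] = field(default_factory=list)

    @property
    def assignments(self) -> dict[str, int | None]:
        return {
            rc.read_id: (rc.taxon if rc.classified else None)
            for rc in self.classifications
        }

    @property
    def direct_counts(self) -> dict[int, int]:
        return direct_counts(self.classifications)

    @property
    def n_unclassified(self) -> int:
        return sum(1 for rc in self.classifications if not rc.classified)


def run_pipeline(
    n_phyla: int = 4,
    genera_per_phylum: int = 3,
    species_per_genus: int = 2,
    profile_kind: str = "gut-like",
    primer: str = "V34",
    n_reads: int = 10_000,
    read_len: int = 250,
    mut_rate: float = 0.02,
    k: int = 35,
    seed: int = 0,
    block_plan=None,
    divergence_rates=None,
    paired: bool = True,
    amplicon_database: bool = False,
) -> PipelineResult:
    """Simulate a community, build its database, and classify its reads.

    With ``amplicon_database=True`` the index is built from primer-trimmed
    reference sequences (the analogue of a region-specific 16S database)
    instead of full-length genes; reads are unaffected, since they are drawn
    from the same primer window either way.
    """
    window = PRIMER_WINDOWS[primer] if isinstance(primer, str) else primer
    refs, tax_records = make_references(
        n_phyla,
        genera_per_phylum,
        species_per_genus,
        block_plan=block_plan,
        divergence_rates=divergence_rates,
        seed=seed,
    )
    tree, seq_to_taxon = build_tree(tax_records)
    profile = make_profile(tax_records, profile_kind, seed=seed + 1)
    db_refs = (
        [(sid, extract_amplicon(seq, window)) for sid, seq in refs]
        if amplicon_database
        else refs
    )
    index = build_index(db_refs, seq_to_taxon, tree, k=k)
    reads, truth = simulate_reads(
        refs,
        profile,
        window,
        n_reads,
        seq_to_taxon,
        read_len=read_len,
        mut_rate=mut_rate,
        paired=paired,
        seed=seed + 2,
    )
    result = PipelineResult(
        tree=tree,
        seq_to_taxon=seq_to_taxon,
        refs=refs,
        db_refs=db_refs,
        tax_records=tax_records,
        profile=profile,
        window=window,
        index=index,
        reads=reads,
        truth=truth,
    )
    for rec in reads:
        rid, mates = rec[0], rec[1:]
        result.classifications.append(
            classify_read(index, tree, *mates, read_id=rid)
        )
    return result
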