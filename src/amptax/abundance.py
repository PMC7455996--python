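"""Abundance re-estimation: push reads classified above a target rank back down.

A k-mer classifier places a read as specifically as the evidence allows, so
reads whose informative k-mers are shared across species (or genera) land on
internal nodes.  Left there, they silently deflate the abundances of the taxa
they came from.  This module redistributes those internal-node counts down to
a single target rank (genus or species) using a model of where reads drawn
from each target-rank taxon tend to be classified.

The model is estimated empirically: every read-length window of every
reference sequence (at a configurable stride) is classified against the same
index used for the reads, and ``P(node, taxon)`` is the fraction of windows
from ``taxon`` that land on ``node``.  Redistribution is then a single
deterministic pass: counts at or below the target rank roll up to their
target-rank ancestor, and a count at node ``n`` above the target rank is
split among the target-rank descendants ``x`` of ``n`` in proportion to
``P(n, x)``.  Counts at nodes with no supported descendant are reported as
unassigned, so total estimated reads + unassigned always equals the total
classified input.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .classifier import classify_read
from .kmer_index import KmerIndex
from .taxonomy import TaxonomyTree


@dataclass
class RedistributionModel:
    """Empirical classification-destination probabilities per target-rank taxon.

    ``P[(node, taxon)]`` is the probability that a read drawn from ``taxon``
    is classified at ``node``; for each taxon the probabilities sum to at
    most 1 (any remainder corresponds to windows that went unclassified).
    """

    target_rank: str
    read_length: int
    P: dict[tuple[int, int], float] = field(default_factory=dict)
    tree_ref: str = ""


@dataclass
class AbundanceProfile:
    """Estimated reads per target-rank taxon, plus reads that could not be
    placed at the target rank (no supported descendant)."""

    counts: dict[int, float]
    unassigned: float = 0.0

    @property
    def total(self) -> float:
        return sum(self.counts.values()) + self.unassigned


def estimate_distribution(
    index: KmerIndex,
    tree: TaxonomyTree,
    refs: Iterable[tuple[str, str]],
    seq_to_taxon: Mapping[str, int],
    read_length: int,
    stride: int = 1,
    target_rank: str = "genus",
) -> RedistributionModel:
    """Classify reference windows to learn where each taxon's reads land.

    Windows of ``read_length`` start at multiples of ``stride``; a reference
    shorter than ``read_length`` contributes one whole-sequence window.
    References whose taxon has no ancestor at ``target_rank`` are skipped
    (they cannot anchor a target-rank estimate).
    """
    if read_length < index.k:
        raise ValueError(
            f"read_length ({read_length}) must be >= index k ({index.k})"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    totals: dict[int, int] = defaultdict(int)
    assigned: dict[tuple[int, int], int] = defaultdict(int)
    for seq_id, seq in refs:
        if seq_id not in seq_to_taxon:
            raise KeyError(f"sequence {seq_id!r} has no taxon assignment")
        taxon = seq_to_taxon[seq_id]
        target = tree.ancestor_at_rank(taxon, target_rank)
        if target is None:
            continue
        if len(seq) <= read_length:
            starts: Iterable[int] = (0,)
        else:
            starts = range(0, len(seq) - read_length + 1, stride)
        for s in starts:
            rc = classify_read(index, tree, seq[s : s + read_length])
            totals[target] += 1
            if rc.classified:
                assigned[(rc.taxon, target)] += 1
    P = {key: n / totals[key[1]] for key, n in assigned.items()}
    return RedistributionModel(
        target_rank=target_rank, read_length=read_length, P=P, tree_ref=tree.content_hash
    )


def redistribute(
    direct_counts: Mapping[int, float],
    model: RedistributionModel,
    tree: TaxonomyTree,
) -> AbundanceProfile:
    """Convert per-node direct counts into a target-rank abundance profile.

    Counts at or below the target rank roll up into their target-rank
    ancestor.  A count at node ``n`` above the target rank is allocated among
    the target-rank descendants of ``n`` proportionally to ``P(n, .)``
    (normalized over those descendants); when no descendant has support the
    count goes to ``unassigned``.  Conservation holds exactly:
    sum(counts) + unassigned == sum(direct_counts).
    """
    rank = model.target_rank
    out: dict[int, float] = defaultdict(float)
    unassigned = 0.0
    desc_cache: dict[int, list[int]] = {}
    for node, c in direct_counts.items():
        if node not in tree:
            raise KeyError(f"taxon {node} not in tree")
        if c < 0:
            raise ValueError(f"negative read count at taxon {node}")
        target = tree.ancestor_at_rank(node, rank)
        if target is not None:
            out[target] += c
            continue
        if node not in desc_cache:
            desc_cache[node] = tree.descendants_at_rank(node, rank)
        weights = {x: model.P.get((node, x), 0.0) for x in desc_cache[node]}
        wsum = sum(weights.values())
        if wsum <= 0.0:
            unassigned += c
            continue
        for x, w in weights.items():
            if w > 0.0:
                out[x] += c * (w / wsum)
    return AbundanceProfile(counts=dict(out), unassigned=unassigned)


def rounded_counts(profile: AbundanceProfile) -> dict[int, int]:
    """Integer counts via largest-remainder rounding, preserving the rounded
    total of the profile's assigned mass exactly."""
    total = round(sum(profile.counts.values()))
    floors = {t: int(c) for t, c in profile.counts.items()}
    remainders = sorted(
        profile.counts,
        key=lambda t: (profile.counts[t] - floors[t], -t),
        reverse=True,
    )
    deficit = total - sum(floors.values())
    for t in remainders[:deficit]:
        floors[t] += 1
    return floors


def rollup_at_rank(
    direct_counts: Mapping[int, float], tree: TaxonomyTree, rank: str
) -> dict[int, float]:
    """Raw roll-up: sum counts at/below ``rank`` into their ``rank`` ancestor,
    dropping counts that sit above it.  This is the no-redistribution baseline."""
    out: dict[int, float] = defaultdict(float)
    for node, c in direct_counts.items():
        target = tree.ancestor_at_rank(node, rank)
        if target is not None:
            out[target] += c
    return dict(out)


def write_abundance(
    profile: AbundanceProfile,
    direct_counts: Mapping[int, float],
    tree: TaxonomyTree,
    path,
    header_comments: Iterable[str] = (),
) -> None:
    """Write a Bracken-style TSV: per target-rank taxon, the rolled-up reads
    the classifier assigned, the reads added by redistribution, the estimate,
    and its fraction of the classified total (integer columns use
    largest-remainder rounding so they sum exactly)."""
    assigned = rollup_at_rank(direct_counts, tree, _infer_rank(profile, tree))
    est = rounded_counts(profile)
    total = sum(est.values())
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write(
            "name\ttaxonomy_id\ttaxonomy_lvl\tkraken_assigned_reads"
            "\tadded_reads\tnew_est_reads\tfraction_total_reads\n"
        )
        for taxid in sorted(est, key=lambda t: -est[t]):
            n_est = est[taxid]
            n_assigned = int(round(assigned.get(taxid, 0)))
            frac = n_est / total if total else 0.0
            fh.write(
                f"{tree.name(taxid)}\t{taxid}\t{tree.rank(taxid)[0].upper()}"
                f"\t{n_assigned}\t{n_est - n_assigned}\t{n_est}\t{frac:.5f}\n"
            )


def _infer_rank(profile: AbundanceProfile, tree: TaxonomyTree) -> str:
    for taxid in profile.counts:
        return tree.rank(taxid)
    return "genus"


def read_abundance(path) -> dict[int, float]:
    """Read back ``taxonomy_id -> new_est_reads`` from a Bracken-style TSV."""
    out: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            out[int(parts[1])] = float(parts[5])
    return out
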