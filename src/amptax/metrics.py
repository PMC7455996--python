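"""Accuracy metrics for taxonomic profiles and per-read assignments.

Two profile-level error rates compare an estimated genus distribution A
against the truth T:

* modified MAPE: ``sum_g (T_g / sum T) * |A_g - T_g| / T_g`` over the true
  genera (abundance-weighted mean relative count error; algebraically the L1
  error normalized by total true reads).  As written it can exceed 1 when a
  genus is grossly over-counted; values are reported unclipped.
* Bray-Curtis dissimilarity: ``1 - 2C / (S_i + S_j)`` with C the summed
  minima over shared genera.  S_i and S_j are the two profile totals, which
  reduces to the classic equal-total form when they match.

Per-read accuracy partitions reads at an evaluation rank into true positives
(assigned inside the true clade at or below the rank), strict vague
positives (assigned to a strict ancestor — not wrong, just unspecific),
false positives (assigned outside the true lineage), and false negatives
(unclassified).  Sensitivity is TP over all reads; PPV is TP / (TP + FP),
deliberately excluding vague positives from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import pandas as pd

from .classifier import UNCLASSIFIED
from .taxonomy import GenusHarmonizationMap, TaxonomyTree

#: Evaluation levels, most specific first.
EVALUATION_LEVELS = ("species", "genus", "family", "order", "class", "phylum")


def mape(
    true_counts: Mapping[Hashable, float], est_counts: Mapping[Hashable, float]
) -> float:
    """Modified mean absolute proportion error over the true genera.

    Genera absent from ``est_counts`` contribute ``A_g = 0``; genera present
    only in the estimate contribute nothing.  Raises on an empty truth or a
    zero/negative true count (the per-genus relative error divides by T_g).
    """
    if not true_counts:
        raise ValueError("true distribution is empty")
    total = 0.0
    for g, t in true_counts.items():
        if t <= 0:
            raise ValueError(f"true count for {g!r} must be > 0")
        total += t
    acc = 0.0
    for g, t in true_counts.items():
        a = est_counts.get(g, 0.0)
        acc += (t / total) * (abs(a - t) / t)
    return acc


def bray_curtis(
    true_counts: Mapping[Hashable, float], est_counts: Mapping[Hashable, float]
) -> float:
    """Bray-Curtis dissimilarity between two count profiles (symmetric)."""
    if not true_counts and not est_counts:
        raise ValueError("both distributions are empty")
    c = sum(
        min(true_counts[g], est_counts[g]) for g in true_counts if g in est_counts
    )
    s_i = sum(true_counts.values())
    s_j = sum(est_counts.values())
    return 1.0 - 2.0 * c / (s_i + s_j)


@dataclass
class ConfusionCounts:
    """Per-level read partition; ``vp`` is strict (TP excluded), so the four
    classes always sum to the number of evaluated reads."""

    level: str
    tp: int = 0
    vp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.vp + self.fp + self.fn


def per_read_confusion(
    assignments: Mapping[str, int | None],
    truth: Mapping[str, tuple[int, str]],
    tree: TaxonomyTree,
    level: str,
) -> ConfusionCounts:
    """Partition every truth read into TP / VP / FP / FN at ``level``.

    TP: assigned at or below the true level-taxon, inside its clade (a read
    assigned to any species of the true genus is a genus-level TP).
    VP: assigned to a strict ancestor of the true level-taxon.
    FP: classified, but outside the true lineage.
    FN: unclassified.  Reads whose true lineage carries no named node at
    ``level`` are skipped (they cannot be scored at that rank).
    """
    c = ConfusionCounts(level=level)
    for rid, (true_taxon, _src) in truth.items():
        if rid not in assignments:
            raise ValueError(f"read {rid!r} has no assignment entry")
        a = assignments[rid]
        if a is None or a == UNCLASSIFIED:
            c.fn += 1
            continue
        if a not in tree:
            raise KeyError(f"assigned taxon {a} not in tree")
        true_level = tree.ancestor_at_rank(true_taxon, level)
        if true_level is None:
            continue
        if tree.is_ancestor(true_level, a):
            c.tp += 1
        elif tree.is_ancestor(a, true_level, strict=True):
            c.vp += 1
        else:
            c.fp += 1
    return c


def sensitivity(c: ConfusionCounts) -> float:
    """TP over all evaluated reads (TP + VP + FP + FN)."""
    if c.total == 0:
        raise ValueError("no reads evaluated")
    return c.tp / c.total


def ppv(c: ConfusionCounts) -> float:
    """Positive predictive value TP / (TP + FP); NaN when undefined
    (no confidently-placed reads at all)."""
    denom = c.tp + c.fp
    if denom == 0:
        return math.nan
    return c.tp / denom


# ---------------------------------------------------------------------------
# Whole-run evaluation
# ---------------------------------------------------------------------------


def genus_distribution(
    taxon_counts: Mapping[int, float],
    tree: TaxonomyTree,
    harmonization: GenusHarmonizationMap | None = None,
) -> dict[str, float]:
    """Aggregate per-taxon counts to harmonized genus names.

    Counts at or below genus roll up to the genus name; counts above genus
    (no genus ancestor) are dropped here — profile metrics compare genus
    distributions only.
    """
    if harmonization is None:
        harmonization = GenusHarmonizationMap.default()
    out: dict[str, float] = {}
    for taxid, n in taxon_counts.items():
        g = tree.ancestor_at_rank(taxid, "genus")
        if g is None:
            continue
        name = harmonization.canonical_of(tree.name(g))
        out[name] = out.get(name, 0.0) + n
    return out


def truth_genus_counts(
    truth: Mapping[str, tuple[int, str]],
    tree: TaxonomyTree,
    harmonization: GenusHarmonizationMap | None = None,
) -> dict[str, float]:
    """True reads per harmonized genus name, aggregated from the truth table."""
    counts: dict[int, float] = {}
    for taxid, _src in truth.values():
        counts[taxid] = counts.get(taxid, 0.0) + 1
    return genus_distribution(counts, tree, harmonization)


def evaluate_run(
    assignments: Mapping[str, int | None],
    abundance_counts: Mapping[int, float],
    truth: Mapping[str, tuple[int, str]],
    tree: TaxonomyTree,
    harmonization: GenusHarmonizationMap | None = None,
    sample: str = "sample",
) -> pd.DataFrame:
    """Evaluate one sample end to end.

    Returns a long-form table with columns (sample, metric, level, value)
    holding the genus-profile MAPE and Bray-Curtis dissimilarity plus
    sensitivity and PPV at each major taxonomic level.  Genus names are
    harmonized before the distribution comparison.
    """
    rows: list[tuple[str, str, str, float]] = []
    t_gen = truth_genus_counts(truth, tree, harmonization)
    a_gen = genus_distribution(abundance_counts, tree, harmonization)
    rows.append((sample, "MAPE", "genus", mape(t_gen, a_gen)))
    rows.append((sample, "BC", "genus", bray_curtis(t_gen, a_gen)))
    for level in EVALUATION_LEVELS:
        c = per_read_confusion(assignments, truth, tree, level)
        if c.total == 0:
            continue
        rows.append((sample, "sensitivity", level, sensitivity(c)))
        rows.append((sample, "PPV", level, ppv(c)))
    return pd.DataFrame(rows, columns=["sample", "metric", "level", "value"])


def average_runs(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Unweighted mean of each (metric, level) across per-sample tables."""
    if not tables:
        raise ValueError("no evaluation tables given")
    combined = pd.concat(tables, ignore_index=True)
    out = (
        combined.groupby(["metric", "level"], sort=False, as_index=False)["value"]
        .mean()
    )
    out.insert(0, "sample", "average")
    return out
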