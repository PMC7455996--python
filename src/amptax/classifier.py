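"""Per-read taxonomic assignment by k-mer lookup and path scoring.

Each k-mer window of a read (both mates pooled for a pair) is looked up in
the index, yielding a multiset of taxon hits.  The hit taxa induce a subtree
of the taxonomy; every root-to-leaf path of that subtree is scored by the sum
of hits on its nodes, and the read is assigned to the leaf of the maximal
path.  Ties go to the LCA of all tied leaves — two species with identical
evidence therefore resolve to their genus.  A read with no matching k-mer at
all is unclassified.

Output follows the familiar classifier dialect: one ``C``/``U`` line per
read with run-length-encoded per-window verdicts, plus a hierarchical report
whose clade counts aggregate each node's direct count with its descendants'.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .kmer_index import KmerIndex, reverse_complement
from .taxonomy import ROOT_ID, TaxonomyTree

#: Sentinel taxon id for k-mer windows with no database hit (and for
#: unclassified reads in tabular output).
UNCLASSIFIED = 0

RANK_CODES = {
    "root": "R",
    "domain": "D",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
    "no_rank": "-",
}


@dataclass
class ReadClassification:
    """Verdict for one read (or read pair: both mates pooled)."""

    read_id: str
    classified: bool
    taxon: int | None
    read_length: int
    hit_groups: list[tuple[int, int]]  # (taxon id or UNCLASSIFIED, run length)

    def to_line(self) -> str:
        """Tab-delimited per-read output line (C/U dialect)."""
        flag = "C" if self.classified else "U"
        taxid = self.taxon if self.classified else UNCLASSIFIED
        runs = " ".join(f"{t}:{n}" for t, n in self.hit_groups)
        return f"{flag}\t{self.read_id}\t{taxid}\t{self.read_length}\t{runs}"


def _window_verdicts(seq: str, index: KmerIndex) -> list[int]:
    """Per-window taxon verdicts over all k-mer windows of ``seq``.

    Windows spanning a non-ACGT character, and windows absent from the
    index, yield :data:`UNCLASSIFIED`.  A read shorter than k has no windows.
    """
    k = index.k
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return []
    rc = reverse_complement(seq)
    entries = index.entries
    verdicts = [UNCLASSIFIED] * (n - k + 1)
    # positions of ambiguous characters; usually none in simulated reads
    bad = [i for i, c in enumerate(seq) if c not in "ACGT"]
    if bad:
        blocked = [False] * (n - k + 1)
        for b in bad:
            for i in range(max(0, b - k + 1), min(n - k, b) + 1):
                blocked[i] = True
    else:
        blocked = None
    for i in range(n - k + 1):
        if blocked is not None and blocked[i]:
            continue
        fwd = seq[i : i + k]
        rev = rc[n - i - k : n - i]
        hit = entries.get(fwd if fwd <= rev else rev)
        if hit is not None:
            verdicts[i] = hit
    return verdicts


def _run_length_encode(verdicts: Sequence[int]) -> list[tuple[int, int]]:
    groups: list[tuple[int, int]] = []
    for v in verdicts:
        if groups and groups[-1][0] == v:
            groups[-1] = (v, groups[-1][1] + 1)
        else:
            groups.append((v, 1))
    return groups


def classify_read(
    index: KmerIndex,
    tree: TaxonomyTree,
    seq: str,
    seq2: str | None = None,
    read_id: str = "read",
) -> ReadClassification:
    """Assign a read (pair) to the taxon of its best-scoring root-to-leaf path.

    Hit counts from both mates are pooled.  Candidate leaves are the hit taxa
    with no hit taxon strictly below them; each candidate's score is the sum
    of hits on its root lineage.  Ties resolve to the LCA of the tied leaves;
    zero hits overall leave the read unclassified.
    """
    verdicts = _window_verdicts(seq, index)
    read_length = len(seq)
    if seq2 is not None:
        verdicts += _window_verdicts(seq2, index)
        read_length += len(seq2)
    counts = Counter(v for v in verdicts if v != UNCLASSIFIED)
    hit_groups = _run_length_encode(verdicts)
    if not counts:
        return ReadClassification(read_id, False, None, read_length, hit_groups)

    # leaves of the hit-induced subtree: hit taxa with no hit strictly below
    internal: set[int] = set()
    lineages: dict[int, list[int]] = {}
    for t in counts:
        lin = tree.lineage_of(t)
        lineages[t] = lin
        for anc in lin[:-1]:
            if anc in counts:
                internal.add(anc)
    leaves = [t for t in counts if t not in internal]
    scores = {t: sum(counts.get(a, 0) for a in lineages[t]) for t in leaves}
    best = max(scores.values())
    tied = [t for t in leaves if scores[t] == best]
    assigned = tied[0]
    for t in tied[1:]:
        assigned = tree.lca(assigned, t)
    return ReadClassification(read_id, True, assigned, read_length, hit_groups)


def _sniff_format(path) -> str:
    p = str(path).lower()
    if p.endswith((".fq", ".fastq")):
        return "fastq"
    if p.endswith((".fa", ".fasta", ".fna")):
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    return "fastq" if first == "@" else "fasta"


def _iter_records(path) -> Iterator[tuple[str, str]]:
    fmt = _sniff_format(path)
    for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: record {i} ({rec.id}) is empty")
        yield rec.id, seq


def classify_file(
    index: KmerIndex,
    tree: TaxonomyTree,
    reads: str | Path,
    reads2: str | Path | None = None,
) -> tuple[list[ReadClassification], dict]:
    """Classify every read (pair) of a FASTA/FASTQ file, preserving order.

    Returns the per-read classifications and a summary with classified /
    unclassified / total counts.  Paired files must align record-for-record.
    """
    results: list[ReadClassification] = []
    if reads2 is None:
        for rid, seq in _iter_records(reads):
            results.append(classify_read(index, tree, seq, read_id=rid))
    else:
        it1, it2 = _iter_records(reads), _iter_records(reads2)
        sentinel = object()
        from itertools import zip_longest

        for i, (a, b) in enumerate(zip_longest(it1, it2, fillvalue=sentinel)):
            if a is sentinel or b is sentinel:
                raise ValueError(
                    f"paired read files have different lengths (record {i})"
                )
            (rid, s1), (_, s2) = a, b
            results.append(classify_read(index, tree, s1, s2, read_id=rid))
    n_class = sum(1 for r in results if r.classified)
    summary = {
        "total": len(results),
        "classified": n_class,
        "unclassified": len(results) - n_class,
    }
    return results, summary


def direct_counts(classifications: Iterable[ReadClassification]) -> dict[int, int]:
    """Reads assigned directly to each taxon (unclassified reads excluded)."""
    counts: Counter[int] = Counter()
    for rc in classifications:
        if rc.classified:
            counts[rc.taxon] += 1
    return dict(counts)


# ---------------------------------------------------------------------------
# Hierarchical report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportRow:
    percent: float
    clade_count: int
    direct_count: int
    rank_code: str
    taxon_id: int
    name: str  # two-space indented per depth level

    def to_line(self) -> str:
        return (
            f"{self.percent:6.2f}\t{self.clade_count}\t{self.direct_count}"
            f"\t{self.rank_code}\t{self.taxon_id}\t{self.name}"
        )


def make_report(
    classifications: Sequence[ReadClassification], tree: TaxonomyTree
) -> list[ReportRow]:
    """Hierarchical report in depth-first tree order.

    A node's clade count is its direct count plus its descendants'; only
    nodes with nonzero clade counts are reported.  Percentages are clade
    counts over all reads, classified or not; the unclassified row leads.
    """
    total = len(classifications)
    direct = direct_counts(classifications)
    unclassified = total - sum(direct.values())

    clade: dict[int, int] = {}

    def fill(node: int) -> int:
        c = direct.get(node, 0) + sum(fill(ch) for ch in tree.children[node])
        clade[node] = c
        return c

    fill(ROOT_ID)

    def pct(count: int) -> float:
        return 100.0 * count / total if total else 0.0

    rows = [
        ReportRow(pct(unclassified), unclassified, unclassified, "U", UNCLASSIFIED, "unclassified")
    ]

    def walk(node: int, depth: int) -> None:
        if clade.get(node, 0) == 0:
            return
        t = tree.taxa[node]
        rows.append(
            ReportRow(
                pct(clade[node]),
                clade[node],
                direct.get(node, 0),
                RANK_CODES.get(t.rank, "-"),
                node,
                "  " * depth + t.name,
            )
        )
        for ch in tree.children[node]:
            walk(ch, depth + 1)

    walk(ROOT_ID, 0)
    return rows


def write_report(rows: Iterable[ReportRow], path, header_comments: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_report_direct_counts(path) -> dict[int, int]:
    """Recover per-taxon direct read counts from a report file."""
    counts: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            _, _, direct, code, taxid, _ = line.split("\t")
            if code == "U":
                continue
            if int(direct):
                counts[int(taxid)] = int(direct)
    return counts


def write_assignments(
    classifications: Iterable[ReadClassification], path, header_comments: Iterable[str] = ()
) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        for rc in classifications:
            fh.write(rc.to_line() + "\n")


def read_assignments(path) -> dict[str, int]:
    """Per-read assignment table: read id -> taxon id (0 = unclassified)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            flag, rid, taxid = parts[0], parts[1], int(parts[2])
            out[rid] = taxid if flag == "C" else UNCLASSIFIED
    return out
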