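"""Canonical k-mer -> LCA taxon index, the classification database.

Every k-mer of every reference sequence is recorded under its canonical form
(the lexicographic minimum of the k-mer and its reverse complement, so the
index is strand-independent).  A k-mer seen in a single species maps to that
species; a k-mer shared by several taxa maps to their lowest common ancestor.
Windows containing any non-ACGT character are skipped entirely, the usual
convention for exact-k-mer classifiers.

The index is stored as plain exact k-mers in a dict and serialized as a
sorted two-column TSV with a small header — inspectable, diff-able, and
bit-exact across rebuilds regardless of reference input order (LCA folding
is commutative and associative).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .taxonomy import TaxonomyTree

DEFAULT_K = 35

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(seq: str, k: int) -> list[tuple[int, str]]:
    """All (0-based position, canonical k-mer) windows of ``seq``.

    Only windows wholly free of non-ACGT characters are emitted.  A sequence
    shorter than ``k`` (or fully ambiguous) yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return []
    rc = reverse_complement(seq)
    # next_bad[i] = position of the first non-ACGT character at or after i
    next_bad = [n] * (n + 1)
    for i in range(n - 1, -1, -1):
        next_bad[i] = i if seq[i] not in "ACGT" else next_bad[i + 1]
    out = []
    for i in range(n - k + 1):
        if next_bad[i] < i + k:
            continue
        fwd = seq[i : i + k]
        rev = rc[n - i - k : n - i]
        out.append((i, fwd if fwd <= rev else rev))
    return out


@dataclass
class KmerIndex:
    """Map from canonical k-mer to the LCA of every taxon containing it."""

    k: int
    entries: dict[str, int] = field(default_factory=dict)
    n_sequences: int = 0
    tree_ref: str = ""

    def get(self, canonical_kmer: str) -> int | None:
        return self.entries.get(canonical_kmer)

    def __len__(self) -> int:
        return len(self.entries)


def build_index(
    refs: Iterable[tuple[str, str]],
    seq_to_taxon: Mapping[str, int],
    tree: TaxonomyTree,
    k: int = DEFAULT_K,
) -> KmerIndex:
    """Build the classification database over all reference sequences.

    Each reference contributes every canonical k-mer of its sequence under
    its mapped taxon; collisions fold through ``tree.lca``, so the result is
    independent of reference input order.  A sequence id missing from
    ``seq_to_taxon`` raises a ``KeyError`` naming the sequence.
    """
    entries: dict[str, int] = {}
    lca = tree.lca
    n_seq = 0
    for seq_id, seq in refs:
        if seq_id not in seq_to_taxon:
            raise KeyError(f"sequence {seq_id!r} has no taxon assignment")
        taxon = seq_to_taxon[seq_id]
        if taxon not in tree:
            raise KeyError(f"sequence {seq_id!r} maps to unknown taxon {taxon}")
        n_seq += 1
        for _, km in canonical_kmers(seq, k):
            cur = entries.get(km)
            entries[km] = taxon if cur is None or cur == taxon else lca(cur, taxon)
    return KmerIndex(k=k, entries=entries, n_sequences=n_seq, tree_ref=tree.content_hash)


def index_stats(index: KmerIndex, tree: TaxonomyTree) -> dict:
    """Summary of an index: distinct k-mers, per-rank entry counts, k, size."""
    per_rank = Counter(tree.rank(t) for t in index.entries.values())
    return {
        "k": index.k,
        "n_sequences": index.n_sequences,
        "distinct_kmers": len(index.entries),
        "entries_per_rank": dict(per_rank),
    }


def write_index(index: KmerIndex, path, extra_comments: Iterable[str] = ()) -> None:
    """Serialize as a sorted two-column TSV with a ``#key=value`` header."""
    with open(path, "w") as fh:
        for line in extra_comments:
            fh.write(f"# {line}\n")
        fh.write(f"#k={index.k}\n")
        fh.write(f"#tree={index.tree_ref}\n")
        fh.write(f"#n_sequences={index.n_sequences}\n")
        for km in sorted(index.entries):
            fh.write(f"{km}\t{index.entries[km]}\n")


def read_index(path) -> KmerIndex:
    k = None
    tree_ref = ""
    n_sequences = 0
    entries: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("k="):
                    k = int(body[2:])
                elif body.startswith("tree="):
                    tree_ref = body[5:]
                elif body.startswith("n_sequences="):
                    n_sequences = int(body[12:])
                continue
            km, taxid = line.split("\t")
            entries[km] = int(taxid)
    if k is None:
        raise ValueError(f"{path}: missing '#k=' header")
    return KmerIndex(k=k, entries=entries, n_sequences=n_sequences, tree_ref=tree_ref)
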