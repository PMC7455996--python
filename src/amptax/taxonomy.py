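"""Ranked taxonomy trees built from Greengenes-style lineage strings.

A lineage string such as ``k__Bacteria; p__Firmicutes; c__Clostridia`` names
a root-to-leaf path through the seven canonical bacterial ranks.  This module
turns a set of (sequence id, lineage) records into a rooted tree with dense
integer ids, and provides the queries the rest of the pipeline needs: lowest
common ancestor (LCA), root-to-node lineages, rank summaries, and genus-name
harmonization across database dialects (merged composites such as
"Escherichia-Shigella", split series such as "Clostridium sensu stricto N").

Unnamed intermediate ranks (an empty ``c__`` field) are skipped rather than
materialized as anonymous nodes, so a genus may attach directly to a phylum —
this mirrors how Greengenes lineages degrade and keeps per-rank node counts
honest.  Identical names under different parents are distinct nodes (the
public 16S taxonomies contain polyphyletic names).
"""

from __future__ import annotations

import hashlib
from collections import Counter, deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

#: Canonical rank hierarchy, broadest first.  ``root`` is the synthetic apex;
#: Greengenes' ``k__`` prefix maps onto ``domain``.
RANKS = ("root", "domain", "phylum", "class", "order", "family", "genus", "species")

#: Ranks that appear in lineage strings (everything below root).
NAMED_RANKS = RANKS[1:]

_PREFIX_TO_RANK = {
    "k": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}

_RANK_ORDER = {rank: i for i, rank in enumerate(RANKS)}

ROOT_ID = 1


class LineageFormatError(ValueError):
    """A lineage string field does not follow the ``x__Name`` convention."""


@dataclass(frozen=True)
class Taxon:
    """One node of the taxonomy: ``id`` is dense and assigned in
    first-encounter order; the root is its own parent."""

    id: int
    parent_id: int
    rank: str
    name: str


def parse_lineage(raw: str) -> list[tuple[str, str]]:
    """Parse a Greengenes-style lineage string into ``[(rank, name), ...]``.

    Fields with an empty name after the prefix (``c__``) are dropped.  Raises
    :class:`LineageFormatError` naming the offending field when a prefix is
    unknown, malformed, or out of canonical order.
    """
    if not raw or not raw.strip():
        raise LineageFormatError("empty lineage string")
    out: list[tuple[str, str]] = []
    last_order = 0  # root
    for field in raw.split(";"):
        field = field.strip()
        if not field:
            continue
        if len(field) < 3 or field[1:3] != "__":
            raise LineageFormatError(f"malformed lineage field {field!r}")
        prefix, name = field[0], field[3:].strip()
        rank = _PREFIX_TO_RANK.get(prefix)
        if rank is None:
            raise LineageFormatError(f"unknown rank prefix in field {field!r}")
        order = _RANK_ORDER[rank]
        if order <= last_order:
            raise LineageFormatError(f"rank prefix out of order at field {field!r}")
        last_order = order
        if name:
            out.append((rank, name))
    return out


class TaxonomyTree:
    """Rooted, ranked taxonomy with integer ids and O(depth) LCA queries."""

    def __init__(self) -> None:
        root = Taxon(ROOT_ID, ROOT_ID, "root", "root")
        self.taxa: dict[int, Taxon] = {ROOT_ID: root}
        self.children: dict[int, list[int]] = {ROOT_ID: []}
        self._depth: dict[int, int] = {ROOT_ID: 0}

    # -- construction ---------------------------------------------------

    def _add(self, parent_id: int, rank: str, name: str) -> int:
        if parent_id not in self.taxa:
            raise KeyError(f"unknown parent taxon id {parent_id}")
        new_id = max(self.taxa) + 1
        self.taxa[new_id] = Taxon(new_id, parent_id, rank, name)
        self.children[new_id] = []
        self.children[parent_id].append(new_id)
        self._depth[new_id] = self._depth[parent_id] + 1
        return new_id

    # -- queries --------------------------------------------------------

    def __contains__(self, taxon_id: int) -> bool:
        return taxon_id in self.taxa

    def __len__(self) -> int:
        return len(self.taxa)

    def parent(self, taxon_id: int) -> int:
        return self.taxa[taxon_id].parent_id

    def depth(self, taxon_id: int) -> int:
        if taxon_id not in self._depth:
            raise KeyError(f"unknown taxon id {taxon_id}")
        return self._depth[taxon_id]

    def name(self, taxon_id: int) -> str:
        return self.taxa[taxon_id].name

    def rank(self, taxon_id: int) -> str:
        return self.taxa[taxon_id].rank

    def lca(self, a: int, b: int) -> int:
        """Lowest common ancestor of two nodes (``lca(a, a) == a``)."""
        if a not in self.taxa:
            raise KeyError(f"unknown taxon id {a}")
        if b not in self.taxa:
            raise KeyError(f"unknown taxon id {b}")
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.taxa[a].parent_id
            da -= 1
        while db > da:
            b = self.taxa[b].parent_id
            db -= 1
        while a != b:
            a = self.taxa[a].parent_id
            b = self.taxa[b].parent_id
        return a

    def lineage_of(self, taxon_id: int) -> list[int]:
        """Ordered root-to-node id path; consecutive entries are parent/child."""
        if taxon_id not in self.taxa:
            raise KeyError(f"unknown taxon id {taxon_id}")
        path = []
        node = taxon_id
        while node != ROOT_ID:
            path.append(node)
            node = self.taxa[node].parent_id
        path.append(ROOT_ID)
        path.reverse()
        return path

    def is_ancestor(self, ancestor: int, node: int, *, strict: bool = False) -> bool:
        """True when ``ancestor`` lies on the root-to-``node`` path."""
        if ancestor not in self.taxa or node not in self.taxa:
            raise KeyError("unknown taxon id")
        if strict and ancestor == node:
            return False
        da = self._depth[ancestor]
        while self._depth[node] > da:
            node = self.taxa[node].parent_id
        return node == ancestor

    def ancestor_at_rank(self, taxon_id: int, rank: str) -> int | None:
        """Node at ``rank`` on the lineage of ``taxon_id`` (self included),
        or None when the lineage carries no named node at that rank."""
        if rank not in _RANK_ORDER:
            raise ValueError(f"unknown rank {rank!r}")
        node = taxon_id
        if node not in self.taxa:
            raise KeyError(f"unknown taxon id {taxon_id}")
        target = _RANK_ORDER[rank]
        while True:
            t = self.taxa[node]
            order = _RANK_ORDER.get(t.rank)
            if order == target:
                return node
            if order is not None and order < target:
                return None  # walked past the rank without finding it
            if node == ROOT_ID:
                return None
            node = t.parent_id

    def descendants_at_rank(self, taxon_id: int, rank: str) -> list[int]:
        """All nodes of ``rank`` inside the clade of ``taxon_id`` (self included)."""
        out = []
        queue = deque([taxon_id])
        while queue:
            node = queue.popleft()
            if self.taxa[node].rank == rank:
                out.append(node)
            queue.extend(self.children[node])
        return out

    def summarize_ranks(self) -> dict[str, int]:
        """Count distinct named nodes per canonical rank (root excluded)."""
        counts = Counter(t.rank for t in self.taxa.values())
        return {rank: counts.get(rank, 0) for rank in NAMED_RANKS}

    # -- serialization --------------------------------------------------

    def to_tsv(self) -> str:
        """Four-column TSV (id, parent_id, rank, name), ids ascending."""
        lines = ["id\tparent_id\trank\tname"]
        for tid in sorted(self.taxa):
            t = self.taxa[tid]
            lines.append(f"{t.id}\t{t.parent_id}\t{t.rank}\t{t.name}")
        return "\n".join(lines) + "\n"

    def write_tsv(self, path, header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"# {line}\n")
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        tree = cls.__new__(cls)
        tree.taxa = {}
        tree.children = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#") or line.startswith("id\t"):
                    continue
                tid, pid, rank, name = line.split("\t")
                rows.append(Taxon(int(tid), int(pid), rank, name))
        for t in rows:
            tree.taxa[t.id] = t
            tree.children.setdefault(t.id, [])
        for t in rows:
            if t.id != t.parent_id:
                tree.children.setdefault(t.parent_id, []).append(t.id)
        tree._depth = {}

        def depth(tid: int) -> int:
            if tid in tree._depth:
                return tree._depth[tid]
            t = tree.taxa[tid]
            d = 0 if t.id == t.parent_id else depth(t.parent_id) + 1
            tree._depth[tid] = d
            return d

        for tid in tree.taxa:
            depth(tid)
        return tree

    @property
    def content_hash(self) -> str:
        """Short digest of the serialized tree; used to pair an index with
        the taxonomy it was built against."""
        return hashlib.sha256(self.to_tsv().encode()).hexdigest()[:12]


def build_tree(
    records: Iterable[tuple[str, str]],
) -> tuple[TaxonomyTree, dict[str, int]]:
    """Build a :class:`TaxonomyTree` from (sequence_id, lineage string) records.

    Identical lineages share nodes; each sequence maps to its most specific
    named node (the root when every field is unnamed).  Ids are assigned in
    first-encounter order given the input order, so identical inputs yield
    byte-identical serialized trees.  A sequence id appearing twice with
    conflicting lineages is an error.
    """
    records = list(records)
    if not records:
        raise ValueError("at least one taxonomy record is required")
    tree = TaxonomyTree()
    path_to_id: dict[tuple[tuple[str, str], ...], int] = {(): ROOT_ID}
    seq_to_taxon: dict[str, int] = {}
    seen_lineage: dict[str, tuple[tuple[str, str], ...]] = {}
    for seq_id, raw in records:
        parsed = tuple(parse_lineage(raw))
        if seq_id in seen_lineage:
            if seen_lineage[seq_id] != parsed:
                raise ValueError(
                    f"sequence {seq_id!r} appears twice with conflicting lineages"
                )
            continue
        seen_lineage[seq_id] = parsed
        node = ROOT_ID
        for i in range(1, len(parsed) + 1):
            key = parsed[:i]
            nid = path_to_id.get(key)
            if nid is None:
                rank, name = parsed[i - 1]
                nid = tree._add(node, rank, name)
                path_to_id[key] = nid
            node = nid
        seq_to_taxon[seq_id] = node
    return tree, seq_to_taxon


def read_taxonomy_table(path) -> list[tuple[str, str]]:
    """Read a two-column TSV ``sequence_id<TAB>lineage_string``."""
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i}: expected 2 tab-separated columns")
            records.append((parts[0], parts[1]))
    return records


def write_taxonomy_table(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for seq_id, lineage in records:
            fh.write(f"{seq_id}\t{lineage}\n")


# ---------------------------------------------------------------------------
# Genus-name harmonization across database dialects
# ---------------------------------------------------------------------------

#: Curated default covering the merge/split patterns seen across the public
#: 16S taxonomies: hyphen-joined composite genera collapse onto a canonical
#: member, and numbered "sensu stricto" splits collapse onto their stem.
DEFAULT_GENUS_SYNONYMS: dict[str, frozenset[str]] = {
    "Rhizobium": frozenset(
        {
            "Allorhizobium-Neorhizobium-Pararhizobium-Rhizobium",
            # spelling variant seen in the wild
            "Allorhizobium-Neorhizbium-Pararhizobium-Rhizobium",
        }
    ),
    "Escherichia": frozenset({"Escherichia-Shigella"}),
    "Clostridium": frozenset(
        {f"Clostridium sensu stricto {i}" for i in range(1, 20)}
    ),
}


class GenusHarmonizationMap:
    """Many-to-one map from database-specific genus names to canonical names.

    Unmapped names pass through unchanged; no fuzzy matching is attempted
    (real-world discrepancies are resolved by curation, not string distance).
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, frozenset[str]] = {
            canon: frozenset(variants) for canon, variants in entries.items()
        }
        self._reverse: dict[str, str] = {}
        for canon, variants in self.entries.items():
            for v in variants:
                if v in self._reverse and self._reverse[v] != canon:
                    raise ValueError(
                        f"variant {v!r} mapped to both {self._reverse[v]!r} and {canon!r}"
                    )
                self._reverse[v] = canon

    def canonical_of(self, name: str) -> str:
        return self._reverse.get(name, name)

    @classmethod
    def default(cls) -> "GenusHarmonizationMap":
        return cls(DEFAULT_GENUS_SYNONYMS)

    @classmethod
    def from_tsv(cls, path) -> "GenusHarmonizationMap":
        """Load ``canonical<TAB>variant`` rows."""
        entries: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                canon, variant = line.split("\t")
                entries.setdefault(canon, set()).add(variant)
        return cls(entries)

    @classmethod
    def from_yaml(cls, path) -> "GenusHarmonizationMap":
        """Load a YAML mapping of canonical name to a list of variants."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("harmonization YAML must be a mapping")
        return cls({k: list(v) for k, v in data.items()})


def harmonize_genus(name: str, mapping: GenusHarmonizationMap | None = None) -> str:
    """Resolve a database-specific genus name to its canonical form."""
    if mapping is None:
        mapping = GenusHarmonizationMap.default()
    return mapping.canonical_of(name)
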