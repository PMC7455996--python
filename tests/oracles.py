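"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own tree/index/classifier code paths:
LCA by full-ancestor-set intersection, k-mer labels by scanning every
sequence on both strands, path scores by exhaustive enumeration over all
nodes.  They are slow but obviously correct on small inputs.
"""

from __future__ import annotations

from collections import Counter


def ancestor_set(tree, node: int) -> set[int]:
    out = set()
    while True:
        out.add(node)
        parent = tree.taxa[node].parent_id
        if parent == node:
            return out
        node = parent


def brute_lca(tree, a: int, b: int) -> int:
    """Deepest member of the intersection of the two full ancestor sets."""
    common = ancestor_set(tree, a) & ancestor_set(tree, b)
    return max(common, key=lambda n: (tree.depth(n), n))


def brute_lca_many(tree, nodes) -> int:
    nodes = list(nodes)
    common = ancestor_set(tree, nodes[0])
    for n in nodes[1:]:
        common &= ancestor_set(tree, n)
    return max(common, key=lambda n: (tree.depth(n), n))


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(seq))


def brute_kmer_labels(refs, seq_to_taxon, tree, k: int) -> dict[str, int]:
    """Expected index: for every canonical k-mer, the brute-force LCA of all
    taxa whose sequence contains it on either strand."""
    containing: dict[str, set[int]] = {}
    for seq_id, seq in refs:
        taxon = seq_to_taxon[seq_id]
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if any(c not in "ACGT" for c in km):
                continue
            canon = min(km, revcomp(km))
            containing.setdefault(canon, set()).add(taxon)
    return {km: brute_lca_many(tree, taxa) for km, taxa in containing.items()}


def brute_classify(tree, window_verdicts: list[int]) -> int | None:
    """Exhaustive path-scoring oracle over per-window taxon verdicts.

    Scores every node of the whole tree by the hits on its root path, keeps
    the hit-bearing nodes with no hit-bearing strict descendant, and returns
    the best-scoring one (ties resolved to the brute-force LCA of all tied).
    """
    hits = Counter(v for v in window_verdicts if v)
    if not hits:
        return None
    score = {
        n: sum(hits.get(a, 0) for a in ancestor_set(tree, n)) for n in hits
    }
    leaves = [
        n
        for n in hits
        if not any(m != n and n in ancestor_set(tree, m) for m in hits)
    ]
    best = max(score[n] for n in leaves)
    tied = [n for n in leaves if score[n] == best]
    return brute_lca_many(tree, tied)


def random_lineage(rng) -> str:
    """A random Greengenes-style lineage, possibly with unnamed ranks."""
    phylum = f"P{rng.randint(1, 3)}"
    cls = f"C{rng.randint(1, 2)}" if rng.random() < 0.8 else ""
    order = f"O{rng.randint(1, 2)}" if rng.random() < 0.8 else ""
    family = f"F{rng.randint(1, 3)}" if rng.random() < 0.8 else ""
    genus = f"G{rng.randint(1, 5)}" if rng.random() < 0.9 else ""
    species = f"S{rng.randint(1, 9)}" if rng.random() < 0.9 else ""
    return (
        f"k__Bacteria; p__{phylum}; c__{cls}; o__{order}; "
        f"f__{family}; g__{genus}; s__{species}"
    )
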