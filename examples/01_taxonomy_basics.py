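"""Build a taxonomy tree from Greengenes-style lineage strings and query it."""

from amptax import build_tree, harmonize_genus

records = [
    ("seq1", "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae; g__Bacillus; s__subtilis"),
    ("seq2", "k__Bacteria; p__Firmicutes; c__Bacilli; o__Bacillales; f__Bacillaceae; g__Bacillus; s__cereus"),
    ("seq3", "k__Bacteria; p__Proteobacteria; c__; o__; f__; g__Escherichia; s__coli"),
]

tree, seq_to_taxon = build_tree(records)

print("nodes per rank:", tree.summarize_ranks())
a, b = seq_to_taxon["seq1"], seq_to_taxon["seq2"]
lca = tree.lca(a, b)
print(f"LCA of the two Bacillus species: {tree.name(lca)} (rank {tree.rank(lca)})")
print("lineage of E. coli:", [tree.name(t) for t in tree.lineage_of(seq_to_taxon["seq3"])])
print("harmonized 'Escherichia-Shigella' ->", harmonize_genus("Escherichia-Shigella"))

# The LCA of two congeneric species is their genus: that is exactly where a
# k-mer shared by both species will be stored in the classification index.
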