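"""Build a k-mer LCA database and classify simulated read pairs."""

from amptax import run_pipeline, make_report
from amptax.kmer_index import index_stats

result = run_pipeline(
    n_phyla=2, genera_per_phylum=2, species_per_genus=2,
    profile_kind="ocean-like", primer="V34", n_reads=500,
    mut_rate=0.02, k=35, seed=3,
)

stats = index_stats(result.index, result.tree)
print(f"index: {stats['distinct_kmers']} canonical {stats['k']}-mers "
      f"over {stats['n_sequences']} references")
print("k-mers stored per rank:", stats["entries_per_rank"])

n_class = sum(1 for rc in result.classifications if rc.classified)
print(f"\n{n_class}/{len(result.classifications)} read pairs classified")
print("\nhierarchical report (percent, clade, direct, rank, taxid, name):")
for row in make_report(result.classifications, result.tree):
    print(row.to_line())

# k-mers unique to one species are stored at species rank; k-mers shared
# across taxa sit at their LCA.  A read's assignment is the leaf of the
# best-scoring root-to-leaf path over its k-mer hits.
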