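# Methods

## Scope and model

`amptax` implements the classification semantics of exact-k-mer LCA
profilers at desk scale. The unit of evidence is the canonical k-mer (the
lexicographic minimum of a window and its reverse complement, so indexing
and lookup are strand-independent). Engineering devices used by production
tools to shrink these databases — minimizers, spaced seeds, probabilistic
hash tables, binary on-disk formats — change memory and speed but not the
assignment semantics, and are deliberately absent: the index is a Python
dict serialized as a sorted TSV, which keeps every test bit-exact and every
artifact human-readable.

### Taxonomy

Lineage strings in the Greengenes dialect are parsed into a rooted tree
over the ranks domain–species (the `k__` prefix maps to domain; bacterial
16S taxonomies carry no separate kingdom). Three choices matter:

* Unnamed ranks (`c__`) are skipped, not materialized as anonymous nodes,
  so a genus can attach directly to a phylum. This mirrors how public 16S
  lineages degrade and keeps per-rank node counts equal to the number of
  *named* taxa.
* Identical names under different parents are distinct nodes, because the
  public taxonomies contain polyphyletic names.
* Ids are dense integers in first-encounter order (root = 1), making tree
  construction reproducible byte-for-byte without any external id source.

Genus harmonization (composite names such as `Escherichia-Shigella`,
numbered `Clostridium sensu stricto` splits) is a curated many-to-one map,
loadable from YAML/TSV with a small packaged default. No fuzzy matching is
attempted: real cross-database discrepancies are resolved editorially, and
guessing silently would corrupt the evaluation.

### Classifier

Hits from both mates of a pair are pooled (a pair is one molecule of
evidence; per-mate verdicts are not produced). Candidate assignments are
the hit taxa with no hit strictly below them; each is scored by the summed
hits on its root lineage and ties resolve to the LCA of the tied leaves.
The tie rule is a convention rather than a published fact; it is the
behaviour implied by "two species with identical matches classify at their
genus", and it is what the exhaustive path-enumeration oracle in the test
suite checks against. There are no confidence thresholds or minimum-hit
criteria. Windows containing non-ACGT characters count as misses, like
absent k-mers, so a fully ambiguous read is unclassified.

### Abundance redistribution

The redistribution model P(node | taxon) is estimated empirically: every
read-length window of every reference (stride configurable, 1 in tests,
5–10 where speed matters) is classified against the same index the reads
use, and P is the fraction of a taxon's windows landing on each node.
Redistribution is a single deterministic pass — counts at/below the target
rank roll up; a count at node *n* above the rank is split among *n*'s
target-rank descendants proportionally to P(n, ·); counts with no supported
descendant are reported as `unassigned`, preserving
`Σ counts + unassigned = Σ input` exactly.

The single-pass rule deliberately does **not** weight by the reads already
assigned to each candidate (a posterior-style scheme). When two genera are
mutually indistinguishable in the sequenced window, *neither* receives
direct reads, and posterior weighting would hand their entire clade count
to whichever third genus has any direct mass — strictly worsening the
profile. Pure-P weighting splits the mass between the two candidates, which
can be shown never to be worse than dropping it (|p_x − p_y| ≤ p_x + p_y).
Fractional estimates are kept as reals internally; tabular output rounds by
largest remainder so column sums are preserved.

### Metrics

The modified MAPE weights each true genus's relative count error by its
share of the sample; algebraically it equals the L1 distance divided by the
true total, an identity the suite verifies term-by-term. As defined it can
exceed 1 when one genus is grossly over-counted; values are reported
unclipped rather than clamped to the nominal [0, 1] range. Bray-Curtis is
generalized to profiles with unequal totals (S_i = ΣT, S_j = ΣA), reducing
to the classic equal-total form when totals match — necessary because
unclassified reads can shrink the estimated total.

In the per-read partition, "vague positive" is counted *strictly* (reads
assigned to a proper ancestor of the true taxon at the evaluated rank), so
TP + VP + FP + FN equals the number of evaluated reads and sensitivity is
simply TP over all reads. Unclassified reads are the false negatives. PPV
excludes vague positives from its denominator: an unspecific read is not
evidence against precision. Reads whose true lineage has no named node at
the evaluated rank are skipped at that rank. Multi-sample averages are
unweighted means.

## Synthetic data generator

The generator emulates the structure of 16S amplicon benchmarks without any
external data. The synthetic gene is 1,700 bp: ten conserved blocks of
80 bp alternating with nine hypervariable (HV) blocks of 100 bp. (With
70-bp conserved blocks the single-block V4 amplicon would be 240 bp,
shorter than the 250-bp reads the benchmarks mandate; 80 bp makes every
preset amplicon ≥ 250 bp.) Each HV block carries the deepest rank it can
separate — the default plan gives blocks 1–3 species resolution, block 4
genus, block 5 phylum, mirroring how real V-regions differ in resolving
power — and a branch of the reference phylogeny at rank r substitutes
bases, at that rank's divergence rate, in every block of plan rank r or
deeper. Default divergence rates are 10% (phylum), 5% (genus), 2%
(species) per base within HV blocks: large enough that 35-mers in
species-rank blocks are species-specific with high probability, small
enough that conserved blocks still dominate the gene. Primer windows are
fixed coordinates over this layout (V12 = [0, 460), V34 = [360, 800),
V4 = [540, 800), V45 = [540, 980)), not real primer coordinates, which are
database-specific.

Communities draw genus abundances from a log-normal whose sigma sets the
evenness (gut-like 1.5, ocean-like 1.0, soil-like 0.5 — dominance-heavy to
even), species uniform within genus. Reads are the 5′ prefix and
reverse-complemented 3′ suffix of the amplicon, mutated by independent
per-base substitution at 2% by default. Substitutions only: indels would
add an alignment dimension the k-mer model does not represent, and the
error process being emulated is unspecified beyond its rate. FASTQ quality
is a constant 'I' (Q40) and is never consumed downstream.

What the simulator does *not* reproduce: real 16S copy-number variation,
chimeras, quality-trimming artifacts, length variation between taxa, or
realistically curated taxonomies. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms under a controlled
error model, not field performance on real amplicon data.

## Numerical and procedural choices

* All randomness flows through `numpy.random.default_rng` from a single
  small-integer seed; the pipeline derives seed, seed+1, seed+2 for the
  reference, profile, and read stages. Identical seeds give byte-identical
  FASTA/FASTQ/TSV outputs.
* LCA folding over k-mer collisions is commutative and associative, so the
  index is independent of reference input order (tested by permutation).
* Degenerate inputs: empty read files yield empty outputs with zero
  totals; reads shorter than k have no windows and are unclassified; an
  index/taxonomy pair is cross-checked by a content hash and refused on
  mismatch.
* PPV with no confidently-placed reads (TP+FP = 0) is NaN, distinct from
  zero; sensitivity of an empty evaluation is an error, not 0.

## Benchmark problem sizes

The standing benchmark used by the test suite and `scripts/acceptance.py`
is 4 phyla / 12 genera / 24 species with 10,000 paired 250-bp reads at 2%
substitution against a k = 35 index (V34 window, gut-like profile). The
redistribution study uses 5 replicates of 3,000 read pairs through the V4
window with genus divergence lowered to 0.5%, so that a substantial share
of genus pairs is identical across the amplicon and their reads classify
above genus — the regime redistribution exists for. These sizes give
stable metric estimates (binomial standard error ≤ 0.5% on proportions
near 0.95) while keeping any single run in seconds.

## Known limitations

* The index stores raw k-mer strings; memory scales linearly with unique
  k-mers and is not suitable for production-size reference sets.
* Redistribution assumes the model windows and the reads come from the
  same sequence space; building the index from full genes while sequencing
  a narrow amplicon dilutes P with windows the experiment never produces
  (the `amplicon_database` pipeline option builds a region-trimmed
  database for that case).
* MAPE is undefined for genera with zero true reads; truth tables built
  from realized reads never contain them, but externally supplied truth
  must respect this.
* Paired mates are assumed to be innermost-first and outermost-second on
  the amplicon; there is no insert-size model.
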