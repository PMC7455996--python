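"""Synthetic 16S-like communities, amplicons, and mutated paired-end reads.

The simulator builds a reference set with the structure that makes 16S
profiling work — and makes it hard.  A synthetic marker gene alternates
conserved blocks (identical in every reference, the anchor for "universal"
primers) with nine hypervariable blocks.  Each hypervariable block is tagged
with the deepest rank at which it diverges: a "species" block separates
sister species, a "genus" block is identical within a genus but separates
genera, a "phylum" block only separates phyla.  Primer windows (V12, V34,
V4, V45) excise different sub-regions, so different primers see different
taxonomic resolution — the property that drives primer-dependent accuracy in
real amplicon studies.

Reads are drawn from a community profile (log-normal rank-abundance over
genera), taken as the 5' prefix (mate 1) and reverse-complemented 3' suffix
(mate 2) of the amplicon, and mutated by independent per-base substitution.
Every read is logged in a truth table for downstream evaluation.  All
randomness flows from a single seed; identical seeds give byte-identical
FASTA/FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .kmer_index import reverse_complement

# -- gene layout ------------------------------------------------------------

HV_LEN = 100
CONS_LEN = 80
N_HV = 9
#: ten conserved blocks of 80 bp bracketing nine hypervariable blocks of
#: 100 bp; total 1,700 bp, a 16S-like scale.
GENE_LEN = (N_HV + 1) * CONS_LEN + N_HV * HV_LEN


def hv_interval(i: int) -> tuple[int, int]:
    """Half-open coordinates of hypervariable block ``i`` (1-based)."""
    if not 1 <= i <= N_HV:
        raise ValueError(f"hypervariable block index {i} out of range")
    start = i * CONS_LEN + (i - 1) * HV_LEN
    return start, start + HV_LEN


@dataclass(frozen=True)
class PrimerWindow:
    """Half-open sub-region of the synthetic gene excised by a primer set."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= GENE_LEN):
            raise ValueError(
                f"primer window {self.name}: invalid coordinates "
                f"[{self.start}, {self.end}) on a {GENE_LEN} bp gene"
            )


#: Fixed coordinate presets over the synthetic gene layout.  V12 spans
#: hypervariable blocks 1-2, V34 blocks 3-4, V4 block 4 alone, V45 blocks
#: 4-5 (each with flanking conserved sequence, as real amplicons have).
PRIMER_WINDOWS: dict[str, PrimerWindow] = {
    "V12": PrimerWindow("V12", 0, 460),
    "V34": PrimerWindow("V34", 360, 800),
    "V4": PrimerWindow("V4", 540, 800),
    "V45": PrimerWindow("V45", 540, 980),
}

#: Deepest rank diverging in each hypervariable block (blocks 1..9).  Blocks
#: covered by V12/V34 resolve species; block 4 (the V4 target) resolves only
#: genera and block 5 only phyla, mirroring the lower resolution of
#: 3'-proximal primer sets.
DEFAULT_BLOCK_PLAN: tuple[str, ...] = (
    "species", "species", "species", "genus", "phylum",
    "species", "genus", "species", "species",
)

#: Per-rank substitution rates applied on the corresponding branch of the
#: reference phylogeny; more distant ranks diverge more.
DEFAULT_DIVERGENCE: dict[str, float] = {"phylum": 0.10, "genus": 0.05, "species": 0.02}

_RANK_DEPTH = {"phylum": 0, "genus": 1, "species": 2}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_DECODE = {i: c for i, c in enumerate("ACGT")}


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate_blocks(
    gene: np.ndarray, rate: float, blocks: Sequence[int], rng: np.random.Generator
) -> np.ndarray:
    """Substitute bases within the given hypervariable blocks at ``rate``."""
    out = gene.copy()
    for b in blocks:
        s, e = hv_interval(b)
        mask = rng.random(HV_LEN) < rate
        n = int(mask.sum())
        if n:
            shifts = rng.integers(1, 4, size=n)
            seg = out[s:e]
            seg[mask] = (seg[mask] + shifts) % 4
    return out


def make_references(
    n_phyla: int,
    genera_per_phylum: int,
    species_per_genus: int,
    block_plan: Sequence[str] | None = None,
    divergence_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Generate reference sequences and their Greengenes-style taxonomy.

    The reference phylogeny is a balanced tree: ``n_phyla`` phyla (each with
    a mirrored class/order), ``genera_per_phylum`` genera per phylum (each
    with a mirrored family), ``species_per_genus`` species per genus, one
    full-length gene per species.  A branch at rank r substitutes bases, at
    that rank's divergence rate, in every hypervariable block whose plan rank
    is r or deeper — so a "species" block varies at every rank while a
    "phylum" block is frozen below the phylum branch.

    Returns ``(references, taxonomy_records)`` as parallel lists of
    ``(sequence_id, sequence)`` and ``(sequence_id, lineage_string)``.
    """
    if min(n_phyla, genera_per_phylum, species_per_genus) < 1:
        raise ValueError("all taxon counts must be >= 1")
    plan = tuple(block_plan) if block_plan is not None else DEFAULT_BLOCK_PLAN
    if len(plan) != N_HV:
        raise ValueError(f"block plan must cover {N_HV} hypervariable blocks")
    for r in plan:
        if r not in _RANK_DEPTH:
            raise ValueError(f"unknown rank {r!r} in block plan")
    rates = dict(divergence_rates) if divergence_rates is not None else dict(DEFAULT_DIVERGENCE)
    for rank, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"divergence rate for {rank} outside [0, 1]")
    if not rates["phylum"] >= rates["genus"] >= rates["species"]:
        raise ValueError(
            "divergence rates must not increase with rank depth "
            "(phylum >= genus >= species)"
        )

    # blocks touched by a branch at each rank: plan rank at-or-deeper
    blocks_at = {
        rank: [i + 1 for i, r in enumerate(plan) if _RANK_DEPTH[r] >= d]
        for rank, d in _RANK_DEPTH.items()
    }

    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=GENE_LEN, dtype=np.uint8)

    refs: list[tuple[str, str]] = []
    tax: list[tuple[str, str]] = []
    genus_idx = 0
    for p in range(1, n_phyla + 1):
        phylum_gene = _mutate_blocks(root, rates["phylum"], blocks_at["phylum"], rng)
        for _ in range(genera_per_phylum):
            genus_idx += 1
            genus_gene = _mutate_blocks(phylum_gene, rates["genus"], blocks_at["genus"], rng)
            genus = f"Genus{genus_idx:02d}"
            for s in range(1, species_per_genus + 1):
                species_gene = _mutate_blocks(
                    genus_gene, rates["species"], blocks_at["species"], rng
                )
                species = f"{genus}_sp{s}"
                seq_id = f"ref_{species}"
                lineage = (
                    f"k__Bacteria; p__Phylum{p:02d}; c__Class{p:02d}; "
                    f"o__Order{p:02d}; f__Family{genus_idx:02d}; "
                    f"g__{genus}; s__{species}"
                )
                refs.append((seq_id, _decode(species_gene)))
                tax.append((seq_id, lineage))
    return refs, tax


def extract_amplicon(ref_seq: str, window: PrimerWindow) -> str:
    """Exact half-open substring of the gene excised by ``window``."""
    if not (0 <= window.start < window.end <= len(ref_seq)):
        raise ValueError(
            f"primer window {window.name} [{window.start}, {window.end}) "
            f"out of range for a {len(ref_seq)} bp sequence"
        )
    return ref_seq[window.start : window.end]


# -- community profiles -----------------------------------------------------


@dataclass
class CommunityProfile:
    """Relative genus abundances with the species available under each genus.

    ``taxa`` holds ``(genus name, [sequence ids of its species], abundance)``;
    abundances are positive and sum to 1.
    """

    name: str
    taxa: list[tuple[str, list[str], float]]

    def __post_init__(self) -> None:
        total = sum(a for _, _, a in self.taxa)
        if not self.taxa or any(a <= 0 for _, _, a in self.taxa):
            raise ValueError("abundances must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")


#: Log-normal sigma of the genus rank-abundance curve per environment style:
#: gut-like communities are dominated by a few genera, soil-like ones are
#: comparatively even, ocean-like sit in between.
PROFILE_SIGMA = {"gut-like": 1.5, "ocean-like": 1.0, "soil-like": 0.5}


def make_profile(
    taxonomy_records: Iterable[tuple[str, str]],
    kind: str = "gut-like",
    seed: int = 0,
) -> CommunityProfile:
    """Draw a community profile over the genera of a reference taxonomy."""
    from .taxonomy import parse_lineage

    if kind not in PROFILE_SIGMA:
        raise ValueError(f"unknown profile kind {kind!r}; options: {sorted(PROFILE_SIGMA)}")
    by_genus: dict[str, list[str]] = {}
    for seq_id, lineage in taxonomy_records:
        ranks = dict(parse_lineage(lineage))
        genus = ranks.get("genus")
        if genus is not None:
            by_genus.setdefault(genus, []).append(seq_id)
    if not by_genus:
        raise ValueError("taxonomy contains no named genera")
    rng = np.random.default_rng(seed)
    genera = sorted(by_genus)
    weights = rng.lognormal(mean=0.0, sigma=PROFILE_SIGMA[kind], size=len(genera))
    weights /= weights.sum()
    taxa = [(g, by_genus[g], float(w)) for g, w in zip(genera, weights)]
    return CommunityProfile(name=kind, taxa=taxa)


# -- read simulation --------------------------------------------------------


def _mutate_read(arr: np.ndarray, mut_rate: float, rng: np.random.Generator) -> np.ndarray:
    if mut_rate <= 0.0:
        return arr
    mask = rng.random(arr.size) < mut_rate
    n = int(mask.sum())
    if n:
        arr = arr.copy()
        arr[mask] = (arr[mask] + rng.integers(1, 4, size=n)) % 4
    return arr


def simulate_reads(
    references: Sequence[tuple[str, str]],
    profile: CommunityProfile,
    window: PrimerWindow,
    n_reads: int,
    seq_to_taxon: Mapping[str, int],
    read_len: int = 250,
    mut_rate: float = 0.02,
    paired: bool = True,
    seed: int = 0,
) -> tuple[list[tuple[str, ...]], dict[str, tuple[int, str]]]:
    """Simulate amplicon reads with ground truth.

    For each read a genus is drawn by profile abundance and a species
    uniformly within it; mate 1 is the 5' ``read_len`` prefix of the
    amplicon, mate 2 the reverse complement of its 3' suffix.  Each base is
    substituted independently with probability ``mut_rate`` (substitutions
    only; no indels).  Returns ``(reads, truth)`` where each read is
    ``(read_id, seq1[, seq2])`` and truth maps read id to
    ``(true taxon id, source sequence id)``.
    """
    if not 0.0 <= mut_rate < 1.0:
        raise ValueError("mut_rate must be in [0, 1)")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    ref_seqs = dict(references)
    amplicons: dict[str, np.ndarray] = {}
    for genus, seq_ids, _ in profile.taxa:
        for sid in seq_ids:
            if sid in amplicons:
                continue
            if sid not in ref_seqs:
                raise KeyError(f"profile names unknown reference {sid!r}")
            if sid not in seq_to_taxon:
                raise KeyError(f"reference {sid!r} has no taxon assignment")
            amp = extract_amplicon(ref_seqs[sid], window)
            if len(amp) < read_len:
                raise ValueError(
                    f"amplicon of {sid!r} ({len(amp)} bp) shorter than "
                    f"read length {read_len}"
                )
            fwd = np.frombuffer(amp.encode(), dtype=np.uint8)
            amplicons[sid] = _encode(fwd)

    rng = np.random.default_rng(seed)
    abunds = np.array([a for _, _, a in profile.taxa])
    genus_draws = rng.choice(len(profile.taxa), size=n_reads, p=abunds)

    reads: list[tuple[str, ...]] = []
    truth: dict[str, tuple[int, str]] = {}
    for i in range(n_reads):
        genus, seq_ids, _ = profile.taxa[genus_draws[i]]
        sid = seq_ids[int(rng.integers(len(seq_ids)))]
        amp = amplicons[sid]
        rid = f"r{i:06d}"
        m1 = _decode(_mutate_read(amp[:read_len], mut_rate, rng))
        if paired:
            m2_src = np.frombuffer(
                reverse_complement(_decode(amp[-read_len:])).encode(), dtype=np.uint8
            )
            m2 = _decode(_mutate_read(_encode(m2_src), mut_rate, rng))
            reads.append((rid, m1, m2))
        else:
            reads.append((rid, m1))
        truth[rid] = (seq_to_taxon[sid], sid)
    return reads, truth


_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _ENC[_c] = _i


def _encode(ascii_arr: np.ndarray) -> np.ndarray:
    return _ENC[ascii_arr]


# -- plain-text writers -----------------------------------------------------


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(
    reads: Sequence[tuple[str, ...]], path1, path2=None
) -> None:
    """Write simulated reads as FASTQ with constant Q40 quality ('I')."""
    paired = len(reads[0]) == 3 if reads else path2 is not None
    if paired and path2 is None:
        raise ValueError("paired reads require two output paths")
    with open(path1, "w") as f1:
        f2 = open(path2, "w") if paired else None
        try:
            for rec in reads:
                rid, m1 = rec[0], rec[1]
                f1.write(f"@{rid}\n{m1}\n+\n{'I' * len(m1)}\n")
                if paired:
                    m2 = rec[2]
                    f2.write(f"@{rid}\n{m2}\n+\n{'I' * len(m2)}\n")
        finally:
            if f2 is not None:
                f2.close()


def write_truth(truth: Mapping[str, tuple[int, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxid\tsource_id\n")
        for rid in truth:
            taxid, sid = truth[rid]
            fh.write(f"{rid}\t{taxid}\t{sid}\n")


def read_truth(path) -> dict[str, tuple[int, str]]:
    out: dict[str, tuple[int, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("read_id\t"):
                continue
            rid, taxid, sid = line.split("\t")
            out[rid] = (int(taxid), sid)
    return out
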