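from __future__ import annotations

import random

import pytest

from amptax.classifier import (
    UNCLASSIFIED,
    classify_file,
    classify_read,
    make_report,
    read_assignments,
    read_report_direct_counts,
    write_assignments,
)
from amptax.kmer_index import KmerIndex, build_index, canonical_kmers
from amptax.simulator import write_fasta, write_fastq
from amptax.taxonomy import ROOT_ID, build_tree

from oracles import brute_classify, random_lineage


def random_read(rng, length=60):
    return "".join(rng.choice("ACGT") for _ in range(length))


def index_and_verdicts(read, k, assignment):
    """Build an index from intended per-window taxa and return it together
    with the verdicts it actually realizes (canonical k-mers occasionally
    collide across windows, in which case the last write wins for both)."""
    kmers = dict(canonical_kmers(read, k))
    entries = {kmers[i]: t for i, t in assignment.items()}
    index = KmerIndex(k=k, entries=entries, n_sequences=1, tree_ref="")
    n_win = len(read) - k + 1
    verdicts = [entries.get(kmers[i], 0) for i in range(n_win)]
    return index, verdicts


def index_for_read(read, k, assignment):
    """Craft an index whose lookups yield ``assignment[i]`` for window i.

    ``assignment`` maps window position to taxon id; windows not listed miss
    the index.  Requires the read's canonical k-mers to be distinct.
    """
    kmers = dict(canonical_kmers(read, k))
    assert len(set(kmers.values())) == len(kmers), "k-mer collision in test read"
    entries = {kmers[i]: t for i, t in assignment.items()}
    return KmerIndex(k=k, entries=entries, n_sequences=1, tree_ref="")


@pytest.fixture(scope="module")
def small_tree():
    # two genera under one phylum plus an outgroup phylum
    tree, seq_map = build_tree(
        [
            ("r1", "k__B; p__P1; g__G1; s__S1"),
            ("r2", "k__B; p__P1; g__G1; s__S2"),
            ("r3", "k__B; p__P2; g__G2; s__S3"),
        ]
    )
    ids = {tree.name(t): t for t in tree.taxa}
    return tree, seq_map, ids


class TestClassifyRead:
    def test_unanimous_hits_assign_that_species(self, small_tree):
        tree, _, ids = small_tree
        rng = random.Random(0)
        read = random_read(rng)
        n_windows = len(read) - 9 + 1
        index = index_for_read(read, 9, {i: ids["S1"] for i in range(n_windows)})
        rc = classify_read(index, tree, read)
        assert rc.classified and rc.taxon == ids["S1"]

    def test_tied_species_with_genus_hits_resolve_to_genus(self, small_tree):
        # equal evidence for two congeneric species plus genus-level hits
        tree, _, ids = small_tree
        rng = random.Random(1)
        read = random_read(rng)
        index = index_for_read(
            read, 9,
            {0: ids["S1"], 1: ids["S2"], 2: ids["G1"], 3: ids["S1"], 4: ids["S2"]},
        )
        rc = classify_read(index, tree, read)
        assert rc.taxon == ids["G1"]

    def test_path_sums_decide_between_branches(self, small_tree):
        # hits S1:5, G1:2, S3:3 -> path(S1)=7 beats path(S3)=3
        tree, _, ids = small_tree
        rng = random.Random(2)
        read = random_read(rng)
        assignment = {}
        pattern = [ids["S1"]] * 5 + [ids["G1"]] * 2 + [ids["S3"]] * 3
        for i, t in enumerate(pattern):
            assignment[i] = t
        index = index_for_read(read, 9, assignment)
        rc = classify_read(index, tree, read)
        assert rc.taxon == ids["S1"]

    def test_no_hits_is_unclassified(self, small_tree):
        tree, _, _ = small_tree
        index = KmerIndex(k=9, entries={}, n_sequences=0)
        rc = classify_read(index, tree, "ACGT" * 10)
        assert not rc.classified and rc.taxon is None

    def test_read_shorter_than_k_is_unclassified(self, small_tree):
        tree, _, _ = small_tree
        index = KmerIndex(k=9, entries={}, n_sequences=0)
        rc = classify_read(index, tree, "ACGT")
        assert not rc.classified and rc.hit_groups == []

    def test_hit_groups_cover_all_windows_of_both_mates(self, small_tree):
        tree, _, ids = small_tree
        rng = random.Random(3)
        read1, read2 = random_read(rng, 40), random_read(rng, 50)
        index = index_for_read(read1, 9, {0: ids["S1"]})
        rc = classify_read(index, tree, read1, read2)
        expected_windows = (40 - 9 + 1) + (50 - 9 + 1)
        assert sum(n for _, n in rc.hit_groups) == expected_windows
        assert rc.read_length == 90

    def test_mates_pool_their_evidence(self, small_tree):
        tree, _, ids = small_tree
        rng = random.Random(4)
        read1, read2 = random_read(rng), random_read(rng)
        k1 = dict(canonical_kmers(read1, 9))
        k2 = dict(canonical_kmers(read2, 9))
        # mate1 carries S1 evidence, mate2 tips the balance to S2 via 3 hits
        entries = {k1[0]: ids["S1"]}
        entries.update({k2[i]: ids["S2"] for i in range(3)})
        index = KmerIndex(k=9, entries=entries, n_sequences=1)
        assert classify_read(index, tree, read1).taxon == ids["S1"]
        assert classify_read(index, tree, read1, read2).taxon == ids["S2"]

    def test_assigned_taxon_on_lineage_of_some_hit(self, small_tree):
        tree, _, _ = small_tree
        rng = random.Random(5)
        ids = sorted(tree.taxa)
        for _ in range(50):
            read = random_read(rng)
            n_win = len(read) - 9 + 1
            assignment = {
                i: rng.choice(ids) for i in range(n_win) if rng.random() < 0.5
            }
            index, verdicts = index_and_verdicts(read, 9, assignment)
            rc = classify_read(index, tree, read)
            if rc.classified:
                assert any(
                    rc.taxon in tree.lineage_of(t) for t in verdicts if t
                )

    def test_matches_exhaustive_path_enumeration(self):
        # random trees (<=50 nodes) and random window verdicts
        for seed in range(8):
            rng = random.Random(seed)
            records = [(f"s{i}", random_lineage(rng)) for i in range(10)]
            tree, _ = build_tree(records)
            assert len(tree) <= 60
            ids = sorted(tree.taxa)
            for _ in range(30):
                read = random_read(rng)
                n_win = len(read) - 9 + 1
                assignment = {
                    i: rng.choice(ids) for i in range(n_win) if rng.random() < 0.4
                }
                index, verdicts = index_and_verdicts(read, 9, assignment)
                rc = classify_read(index, tree, read)
                expected = brute_classify(tree, verdicts)
                assert (rc.taxon if rc.classified else None) == expected

    def test_unrelated_references_never_break_a_correct_assignment(self, small_tree):
        # growing the database may lift an assignment toward an ancestor but
        # must not push it onto a wrong lineage
        tree, seq_map, ids = small_tree
        rng = random.Random(9)
        ref1 = random_read(rng, 80)
        outgroup = random_read(rng, 80)
        small = build_index([("r1", ref1)], seq_map, tree, k=11)
        grown = build_index([("r1", ref1), ("r3", outgroup)], seq_map, tree, k=11)
        read = ref1[10:50]
        before = classify_read(small, tree, read)
        after = classify_read(grown, tree, read)
        assert before.taxon == seq_map["r1"]
        assert after.taxon in tree.lineage_of(seq_map["r1"])


class TestClassifyFile:
    def test_empty_file(self, small_tree, tmp_path):
        tree, _, _ = small_tree
        path = tmp_path / "empty.fa"
        path.write_text("")
        index = KmerIndex(k=9, entries={}, n_sequences=0)
        results, summary = classify_file(index, tree, path)
        assert results == [] and summary == {
            "total": 0, "classified": 0, "unclassified": 0,
        }

    def test_verbatim_reference_reads_fully_classified(self, small_tree, tmp_path):
        tree, seq_map, _ = small_tree
        rng = random.Random(11)
        refs = [(sid, random_read(rng, 120)) for sid in ("r1", "r2", "r3")]
        index = build_index(refs, seq_map, tree, k=11)
        reads = [(f"read_{sid}", seq[20:80]) for sid, seq in refs]
        path = tmp_path / "reads.fa"
        write_fasta(reads, path)
        results, summary = classify_file(index, tree, path)
        assert summary["classified"] == summary["total"] == 3
        for rc, (sid, _) in zip(results, refs):
            assert rc.taxon in tree.lineage_of(seq_map[sid])

    def test_all_n_read_is_unclassified(self, small_tree, tmp_path):
        tree, _, _ = small_tree
        path = tmp_path / "reads.fq"
        path.write_text("@n1\n" + "N" * 30 + "\n+\n" + "I" * 30 + "\n")
        index = KmerIndex(k=9, entries={"A" * 9: 2}, n_sequences=1)
        results, summary = classify_file(index, tree, path)
        assert summary["unclassified"] == 1
        assert results[0].to_line().startswith("U\t")

    def test_mismatched_pair_lengths_raise(self, small_tree, tmp_path):
        tree, _, _ = small_tree
        p1, p2 = tmp_path / "r1.fa", tmp_path / "r2.fa"
        write_fasta([("a", "ACGT" * 10), ("b", "ACGT" * 10)], p1)
        write_fasta([("a", "ACGT" * 10)], p2)
        index = KmerIndex(k=9, entries={}, n_sequences=0)
        with pytest.raises(ValueError, match="different lengths"):
            classify_file(index, tree, p1, p2)

    def test_assignment_roundtrip(self, small_tree, tmp_path):
        tree, seq_map, ids = small_tree
        rng = random.Random(12)
        read = random_read(rng)
        index = index_for_read(read, 9, {0: ids["S1"]})
        rc1 = classify_read(index, tree, read, read_id="x1")
        rc2 = classify_read(KmerIndex(k=9, entries={}), tree, read, read_id="x2")
        path = tmp_path / "out.tsv"
        write_assignments([rc1, rc2], path, header_comments=["demo"])
        loaded = read_assignments(path)
        assert loaded == {"x1": ids["S1"], "x2": UNCLASSIFIED}


class TestReport:
    def _classify_counts(self, tree, taxon_counts, n_unclassified=0):
        """Fabricate classifications with the given per-taxon direct counts."""
        from amptax.classifier import ReadClassification

        out = []
        i = 0
        for taxon, n in taxon_counts.items():
            for _ in range(n):
                out.append(ReadClassification(f"r{i}", True, taxon, 100, [(taxon, 92)]))
                i += 1
        for _ in range(n_unclassified):
            out.append(ReadClassification(f"r{i}", False, None, 100, [(0, 92)]))
            i += 1
        return out

    def test_species_counts_propagate_to_genus_clade(self, small_tree):
        tree, _, ids = small_tree
        rows = make_report(self._classify_counts(tree, {ids["S1"]: 10}), tree)
        by_tax = {r.taxon_id: r for r in rows}
        assert by_tax[ids["S1"]].direct_count == 10
        assert by_tax[ids["S1"]].clade_count == 10
        assert by_tax[ids["G1"]].direct_count == 0
        assert by_tax[ids["G1"]].clade_count == 10

    def test_mixed_direct_and_descendant_counts(self, small_tree):
        tree, _, ids = small_tree
        rows = make_report(
            self._classify_counts(tree, {ids["G1"]: 5, ids["S1"]: 5}), tree
        )
        by_tax = {r.taxon_id: r for r in rows}
        assert by_tax[ids["G1"]].clade_count == 10
        assert by_tax[ids["G1"]].direct_count == 5

    def test_all_unclassified_yields_only_u_row(self, small_tree):
        tree, _, _ = small_tree
        rows = make_report(self._classify_counts(tree, {}, n_unclassified=4), tree)
        assert len(rows) == 1
        assert rows[0].rank_code == "U" and rows[0].clade_count == 4
        assert rows[0].percent == 100.0

    def test_clade_invariant_and_root_total(self, small_tree):
        tree, _, ids = small_tree
        rng = random.Random(13)
        counts = {t: rng.randint(0, 5) for t in tree.taxa if t != ROOT_ID}
        classifs = self._classify_counts(tree, counts, n_unclassified=3)
        rows = make_report(classifs, tree)
        by_tax = {r.taxon_id: r for r in rows if r.rank_code != "U"}
        for taxid, row in by_tax.items():
            child_sum = sum(
                by_tax[c].clade_count for c in tree.children[taxid] if c in by_tax
            )
            assert row.clade_count == row.direct_count + child_sum
        assert by_tax[ROOT_ID].clade_count == sum(counts.values())

    def test_report_direct_counts_roundtrip(self, small_tree, tmp_path):
        tree, _, ids = small_tree
        classifs = self._classify_counts(tree, {ids["S1"]: 7, ids["G2"]: 2})
        from amptax.classifier import write_report

        path = tmp_path / "report.tsv"
        write_report(make_report(classifs, tree), path)
        assert read_report_direct_counts(path) == {ids["S1"]: 7, ids["G2"]: 2}
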