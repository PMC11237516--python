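import math

import numpy as np
import pytest

from polyamp.classify import (
    ClassifierModel,
    build_kmer_model,
    classify_read,
    load_external_profile,
    profile_sample,
    read_seed,
)
from polyamp.io import Kingdom, LineageRecord, write_abundance_table
from polyamp.segregate import reverse_complement


def _lineage(tax_id, names7, kingdom=Kingdom.bacteria):
    return LineageRecord(tax_id, tuple(names7) + ("",), kingdom)


def _enumerate_kmers(seq, k=8, with_rc=False):
    kmers = {seq[i : i + k] for i in range(len(seq) - k + 1)}
    if with_rc:
        rc = reverse_complement(seq)
        kmers |= {rc[i : i + k] for i in range(len(rc) - k + 1)}
    return kmers


def _kmer_code(kmer):
    return sum({"A": 0, "C": 1, "G": 2, "T": 3}[c] * 4 ** (len(kmer) - 1 - i)
               for i, c in enumerate(kmer))


LIN_A = _lineage("A", ("Bacteria", "P1", "C1", "O1", "F1", "G1", "G1 a"))
LIN_B = _lineage("B", ("Bacteria", "P1", "C1", "O1", "F1", "G1", "G1 b"))
LIN_C = _lineage("C", ("Bacteria", "P2", "C2", "O2", "F2", "G2", "G2 c"))


class TestBuildKmerModel:
    def test_presence_set_matches_enumeration(self):
        seq = "ACGTACGTACGT"
        model = build_kmer_model([(LIN_A, seq)], k=8, index_revcomp=False)
        expected = _enumerate_kmers(seq)  # 5 positions, one palindromic repeat
        # single taxon, N=1: present words have P(w)=0.75, P(w|t)=(1+0.75)/2
        present = np.flatnonzero(np.isclose(np.exp(model.log_cond[0]), 0.875))
        assert set(present) == {_kmer_code(k) for k in expected}
        assert len(expected) == 4  # distinct k-mers, not k-mer positions

    def test_taxa_sharing_all_kmers_have_identical_conditionals(self):
        seq = "ACGTACGTACGTACGT"
        model = build_kmer_model([(LIN_A, seq), (LIN_B, seq)], k=8)
        assert np.allclose(model.log_cond[0], model.log_cond[1])

    def test_conditionals_match_hand_computed_fractions(self):
        """3-taxon toy database: P(w) = (n(w)+0.5)/(N+1), P(w|t) = (m+P(w))/(M+1)."""
        seqs = {"A": "ACGTACGTAAAA", "B": "ACGTACGTCCCC", "C": "TTTTTTTTTTTT"}
        model = build_kmer_model(
            [(LIN_A, seqs["A"]), (LIN_B, seqs["B"]), (LIN_C, seqs["C"])],
            k=8,
            index_revcomp=False,
        )
        kmer_sets = {t: _enumerate_kmers(s) for t, s in seqs.items()}
        all_kmers = set.union(*kmer_sets.values())
        for w in all_kmers:
            n_w = sum(w in ks for ks in kmer_sets.values())
            p_w = (n_w + 0.5) / (3 + 1)
            for ti, t in enumerate(["A", "B", "C"]):
                m = 1 if w in kmer_sets[t] else 0
                expected = (m + p_w) / (1 + 1)
                got = math.exp(model.log_cond[ti, _kmer_code(w)])
                assert got == pytest.approx(expected, rel=1e-6)

    def test_multiple_references_increase_m(self):
        model = build_kmer_model(
            [(LIN_A, "ACGTACGTACGT"), (LIN_A, "ACGTACGTACGT")], k=8,
            index_revcomp=False,
        )
        # M=2: conditional for a present word is (1 + P(w)) / 3
        p_w = (1 + 0.5) / (1 + 1)
        got = math.exp(model.log_cond[0, _kmer_code("ACGTACGT")])
        assert got == pytest.approx((1 + p_w) / 3)

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_model([])

    def test_save_load_roundtrip(self, tmp_path, small_db):
        model = build_kmer_model(small_db.fungi[:2])
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = ClassifierModel.load(path)
        assert loaded.k == model.k
        assert [t.tax_id for t in loaded.taxa] == [t.tax_id for t in model.taxa]
        assert np.array_equal(loaded.log_cond, model.log_cond)


class TestClassifyRead:
    def test_self_classification_on_disjoint_taxa(self, small_db):
        model = build_kmer_model(small_db.bacteria)
        for lineage, seq in small_db.bacteria:
            a = classify_read(model, seq, seed=3)
            assert a.best_taxon == lineage.tax_id
            assert a.confidences[-1] == 1.0
            assert a.assigned_rank == 6

    def test_reverse_complement_read_still_classifies(self, small_db):
        model = build_kmer_model(small_db.bacteria)
        lineage, seq = small_db.bacteria[2]
        a = classify_read(model, reverse_complement(seq), seed=3)
        assert a.best_taxon == lineage.tax_id

    def test_alien_read_ties_are_flagged(self):
        model = build_kmer_model(
            [(LIN_A, "ACGTACGTACGT"), (LIN_B, "ACGTACGTACGT")], k=8
        )
        a = classify_read(model, "G" * 20, seed=0)
        assert a.tie

    def test_short_read_unassigned_with_reason(self, small_db):
        model = build_kmer_model(small_db.bacteria)
        a = classify_read(model, "ACGT", seed=0)
        assert a.best_taxon == "unassigned" and a.reason

    def test_deterministic_given_seed(self, small_db):
        model = build_kmer_model(small_db.bacteria)
        seq = small_db.bacteria[0][1][:300]
        a1 = classify_read(model, seq, seed=99)
        a2 = classify_read(model, seq, seed=99)
        assert a1 == a2

    def test_confidences_rank_monotone(self, small_db, rng):
        model = build_kmer_model(small_db.bacteria)
        for _ in range(20):
            read = "".join(rng.choice(list("ACGT"), 120))
            a = classify_read(model, read, seed=5)
            if a.confidences:
                assert all(
                    a.confidences[i] >= a.confidences[i + 1] for i in range(6)
                )

    def test_bootstrap_confidence_matches_exact_enumeration(self):
        """12-mer read -> V<=5 distinct 8-mers, draw size 1: the bootstrap
        winner distribution is exactly enumerable over the read's k-mers."""
        model = build_kmer_model(
            [(LIN_A, "ACGTACGTAAAATTTTGGGG"), (LIN_C, "TTTTCCCCGGGGAAAACCCC")],
            k=8,
            index_revcomp=False,
            n_bootstrap=4000,
        )
        read = "ACGTACGTAAAA"
        from polyamp.classify import _kmer_ids

        kmers = _kmer_ids(read, 8)
        assert kmers.size <= 5
        scores = model.log_cond[:, kmers]  # (2, V)
        winners = np.argmax(scores, axis=0)
        exact = float(np.mean(winners == 0))
        a = classify_read(model, read, seed=12)
        # species-level confidence vs exact single-draw probability, 3 sigma
        se = math.sqrt(exact * (1 - exact) / 4000) if 0 < exact < 1 else 0.0
        assert a.confidences[-1] == pytest.approx(exact, abs=max(3 * se, 1e-9))


class TestProfileSample:
    def _assign(self, tax, rank, rid="r"):
        from polyamp.classify import TaxonAssignment

        return TaxonAssignment(rid, tax, (1.0,) * 7, rank)

    def test_species_counting(self, small_db):
        model = build_kmer_model(small_db.bacteria)
        t = model.taxa[0].tax_id
        profile = profile_sample([self._assign(t, 6, f"r{i}") for i in range(3)], model)
        assert profile.species_counts() == {model.taxa[0].species: 3}

    def test_genus_level_rollup(self):
        model = build_kmer_model(
            [(LIN_A, "ACGTACGTACGTAAAA"), (LIN_B, "TTTTACGTACGTACGT")], k=8
        )
        assignments = [
            self._assign("A", 6, "r1"),
            self._assign("A", 6, "r2"),
            self._assign("B", 5, "r3"),  # confident only to genus
        ]
        profile = profile_sample(assignments, model)
        assert profile.counts_at_rank("genus") == {"G1": 3}
        assert profile.counts_at_rank("species") == {
            "G1 a": 2,
            "unclassified-below-genus": 1,
        }

    def test_read_conservation(self, small_db, rng):
        from polyamp.classify import TaxonAssignment

        model = build_kmer_model(small_db.bacteria)
        tax_ids = [t.tax_id for t in model.taxa]
        assignments = []
        for i in range(50):
            if rng.random() < 0.2:
                assignments.append(TaxonAssignment(f"r{i}", "unassigned"))
            else:
                rank = int(rng.integers(0, 7))
                assignments.append(
                    TaxonAssignment(f"r{i}", str(rng.choice(tax_ids)), (1.0,) * 7, rank)
                )
        profile = profile_sample(assignments, model)
        assert profile.total_assigned + profile.unassigned == 50
        # rank-sum conservation: counts at rank r cover reads assigned at >= r
        for r in range(7):
            n_deep = sum(
                1 for a in assignments if a.is_assigned and a.assigned_rank >= r
            )
            at_rank = {
                k: v for k, v in profile.counts_at_rank(r).items()
                if not k.startswith("unclassified-below")
            }
            assert sum(at_rank.values()) == n_deep


class TestLoadExternalProfile:
    def _write(self, path, rows, ab_col="abundance"):
        header = f"tax_id\t{ab_col}\tspecies\tgenus\n"
        path.write_text(header + "".join(rows))

    def test_two_taxon_table(self, tmp_path):
        path = tmp_path / "emu.tsv"
        self._write(path, ["1\t0.6\tG a\tG\n", "2\t0.4\tG b\tG\n"])
        p = load_external_profile(path, Kingdom.bacteria, "S1")
        rels = p.relative_abundances()
        assert rels[("1", 6)] == pytest.approx(0.6, abs=1e-5)

    def test_renormalises_with_warning(self, tmp_path):
        path = tmp_path / "emu.tsv"
        self._write(path, ["1\t0.58\tG a\tG\n", "2\t0.40\tG b\tG\n"])
        with pytest.warns(UserWarning, match="renormalis"):
            p = load_external_profile(path, Kingdom.bacteria)
        total = sum(p.relative_abundances().values())
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("tax_id\tspecies\n1\tx\n")
        with pytest.raises(ValueError, match="abundance"):
            load_external_profile(path, Kingdom.fungi)

    def test_roundtrip_through_abundance_table(self, tmp_path):
        path = tmp_path / "emu.tsv"
        path.write_text(
            "tax_id\tabundance\testimated counts\tspecies\tgenus\n"
            "1\t0.75\t300\tG a\tG\n"
            "2\t0.25\t100\tG b\tG\n"
        )
        p = load_external_profile(path, Kingdom.fungi, "S1")
        out = tmp_path / "ab.tsv"
        write_abundance_table([p], out)
        from polyamp.io import read_abundance_table

        (back,) = read_abundance_table(out)
        assert dict(back.counts) == dict(p.counts)
        assert back.unassigned == p.unassigned == 0


class TestReadSeed:
    def test_stable_and_bounded(self):
        s1 = read_seed(7, "read-1")
        assert s1 == read_seed(7, "read-1")
        assert 0 <= s1 < 2**31
        assert s1 != read_seed(7, "read-2")
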