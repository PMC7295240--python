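import numpy as np
import pandas as pd
import pytest

from miningd import (
    CDR3Set,
    GermlineDB,
    add_decoy_alleles,
    assign_cdr3,
    compute_usage,
    detect_overuse,
    find_unique_kmers,
    haplotype_v_genes,
)
from miningd.io import GermlineEntry
from miningd.usage import UniqueKmerIndex, UsageProfile, gene_index


def _db(*entries):
    return GermlineDB(entries=[GermlineEntry(*e) for e in entries])


class TestUniqueKmers:
    def test_shared_kmer_unique_to_neither(self):
        shared = "ACGTACGT"
        db = _db(("d1", "01", "TT" + shared + "CC"), ("d2", "01", "GG" + shared + "AA"))
        uniq = find_unique_kmers(db, 8)
        assert shared not in uniq.get("d1", set())
        assert shared not in uniq.get("d2", set())

    def test_single_gene_db_owns_everything(self):
        db = _db(("d1", "01", "ACGTACGTACGT"))
        uniq = find_unique_kmers(db, 8)
        expected = {
            "ACGTACGTACGT"[i : i + L]
            for L in range(8, 13)
            for i in range(13 - L)
        }
        assert uniq["d1"] == expected

    def test_two_gene_example(self):
        db = _db(("d1", "01", "ACGTACGTAC"), ("d2", "01", "TTTTGGGGCCAA"))
        uniq = find_unique_kmers(db, 8)
        assert "ACGTACGT" in uniq["d1"]
        assert "TTTTGGGG" in uniq["d2"]


class TestAssignment:
    def test_whole_gene_containment(self):
        db = _db(("d1", "01", "ACGTTACGGCAT"), ("d2", "01", "TTGGCCAATTGG"))
        idx = gene_index(db, 8)
        assert assign_cdr3("AAAACGTTACGGCATAAA", idx) == "d1"

    def test_longer_unique_match_wins(self):
        # c holds a unique 8-mer of d1 but a unique 9-mer of d2
        db = _db(("d1", "01", "ACGTTACG"), ("d2", "01", "TTGGCCAAT"))
        idx = gene_index(db, 8)
        c = "ACGTTACG" + "AAA" + "TTGGCCAAT"
        assert assign_cdr3(c, idx) == "d2"

    def test_equal_longest_matches_tie_to_none(self):
        db = _db(("d1", "01", "ACGTTACGG"), ("d2", "01", "TTGGCCAAT"))
        idx = gene_index(db, 8)
        c = "ACGTTACGG" + "AAA" + "TTGGCCAAT"
        assert assign_cdr3(c, idx) is None

    def test_no_hit_non_traceable(self):
        db = _db(("d1", "01", "ACGTTACGG"))
        idx = gene_index(db, 8)
        assert assign_cdr3("TTTTTTTTTTTT", idx) is None

    def test_permutation_invariance(self):
        e1 = ("d1", "01", "ACGTTACGG")
        e2 = ("d2", "01", "TTGGCCAAT")
        c = "AACGTTACGGTT"
        assert assign_cdr3(c, gene_index(_db(e1, e2), 8)) == assign_cdr3(
            c, gene_index(_db(e2, e1), 8)
        )


class TestUsage:
    def test_toy_proportions(self):
        db = _db(("d1", "01", "ACGTTACGGCAT"), ("d2", "01", "TTGGCCAATTGG"))
        seqs = (
            ["AA" + "ACGTTACGGCAT" + "TT"] * 1  # distinct strings needed
            + ["CC" + "ACGTTACGGCAT" + str_tail for str_tail in ["A", "C", "G", "T", "AA"]]
            + ["GG" + "TTGGCCAATTGG" + t for t in ["A", "C"]]
            + ["ACACACACAC", "GTGTGTGTGT"]
        )
        cdr3s = CDR3Set.from_sequences(seqs)
        prof = compute_usage(cdr3s, db, 8)
        assert prof.n_cdr3s == 10
        assert prof.traceable_fraction == pytest.approx(0.8)
        assert prof.gene_usage == pytest.approx({"d1": 0.75, "d2": 0.25})

    def test_single_gene_db(self):
        db = _db(("d1", "01", "ACGTTACGGCAT"))
        cdr3s = CDR3Set.from_sequences(["AAACGTTACGGCATAA", "TTTTTTTTTTTT"])
        prof = compute_usage(cdr3s, db, 8)
        assert prof.gene_usage == {"d1": 1.0}
        assert prof.allele_shares == {"d1": {"d1*01": 1.0}}

    def test_no_traceable_warns_empty_profile(self):
        db = _db(("d1", "01", "ACGTTACGGCAT"))
        prof = compute_usage(CDR3Set.from_sequences(["TTTTTTTTTT"]), db, 8)
        assert prof.traceable_fraction == 0.0
        assert prof.gene_usage == {}

    def test_usage_sums_to_one(self):
        rng = np.random.default_rng(5)
        genes = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(4)]
        db = _db(*[(f"d{i}", "01", g) for i, g in enumerate(genes)])
        seqs = []
        for _ in range(300):
            g = genes[int(rng.integers(4))]
            flank = "".join(rng.choice(list("ACGT"), size=8))
            seqs.append(flank[:4] + g + flank[4:])
        prof = compute_usage(CDR3Set.from_sequences(seqs), db, 8)
        assert sum(prof.gene_usage.values()) == pytest.approx(1.0, abs=1e-9)
        for shares in prof.allele_shares.values():
            assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)


class TestDecoyAlleles:
    def test_combinatorics(self):
        db = _db(("d1", "01", "ACGTACGTACGT"))
        out = add_decoy_alleles(db, "d1", [2, 7], [["A", "C", "T"], ["A", "C", "G"]])
        fa = [e for e in out if e.allele.startswith("FA")]
        assert len(fa) == 15  # 4*4 combinations minus the original

    def test_empty_sites_unchanged(self):
        db = _db(("d1", "01", "ACGTACGTACGT"))
        out = add_decoy_alleles(db, "d1", [], [])
        assert [e for e in out] == [e for e in db]

    def test_site_out_of_range(self):
        db = _db(("d1", "01", "ACGT"))
        with pytest.raises(ValueError):
            add_decoy_alleles(db, "d1", [10], [["A"]])

    def test_cap_truncates(self):
        db = _db(("d1", "01", "ACGTACGTACGT"))
        out = add_decoy_alleles(
            db, "d1", [0, 1, 2], [["A", "C", "G", "T"]] * 3, cap=5
        )
        assert sum(e.allele.startswith("FA") for e in out) == 5


class TestOveruse:
    def _profile(self, usage):
        return UsageProfile(usage, {}, 1.0, 100, 80)

    def test_ratio_above_factor(self):
        over, absent = detect_overuse(
            self._profile({"d1": 0.10}), [self._profile({"d1": 0.04})]
        )
        assert over == [("d1", pytest.approx(2.5))]
        assert absent == []

    def test_ratio_below_factor(self):
        over, _ = detect_overuse(
            self._profile({"d1": 0.07}), [self._profile({"d1": 0.04})]
        )
        assert over == []

    def test_factor_one_reports_everything_nonzero(self):
        over, _ = detect_overuse(
            self._profile({"d1": 0.05, "d2": 0.01}),
            [self._profile({"d1": 0.05, "d2": 0.02})],
            factor=1.0,
        )
        assert ("d1", pytest.approx(1.0)) in over

    def test_absent_in_reference(self):
        over, absent = detect_overuse(
            self._profile({"dX": 0.2}), [self._profile({"d1": 0.1})]
        )
        assert absent == ["dX"]

    def test_scale_free(self):
        t = self._profile({"d1": 0.10, "d2": 0.30})
        r = self._profile({"d1": 0.04, "d2": 0.10})
        t2 = self._profile({g: u * 0.5 for g, u in t.gene_usage.items()})
        r2 = self._profile({g: u * 0.5 for g, u in r.gene_usage.items()})
        assert detect_overuse(t, [r]) == detect_overuse(t2, [r2])


def _haplotype_table(rng, n_per_combo=60, swap_fraction=0.05):
    """Two haplotypes: (V1*a with D1*x) and (V1*b with D1*y)."""
    d_alleles = {
        "x": "ACGTTACGGCATCCGGAAT",
        "y": "ACGTTACGGCATCCGGAAC",
    }
    db = _db(("D1", "x", d_alleles["x"]), ("D1", "y", d_alleles["y"]))
    rows = []
    for v_allele, d_allele in [("a", "x"), ("b", "y")]:
        for i in range(n_per_combo):
            d = d_allele
            if rng.random() < swap_fraction:  # occasional trans pairing noise
                d = "x" if d_allele == "y" else "y"
            flank = "".join(rng.choice(list("ACGT"), size=12))
            cdr3 = flank[:6] + d_alleles[d] + flank[6:]
            rows.append({"cdr3": cdr3, "v_call": f"IGHV1-1*{v_allele}"})
    return pd.DataFrame(rows), db


class TestHaplotyping:
    def test_planted_phasing_recovered(self):
        rng = np.random.default_rng(77)
        table, db = _haplotype_table(rng)
        rep = haplotype_v_genes(table, db, min_cdr3s=10, k_min=8)
        assert rep.v_genes == ["IGHV1-1"]
        assert rep.consistent["IGHV1-1"]
        assert rep.assignments["IGHV1-1"]["D1"] == {"a": "x", "b": "y"}
        m = rep.matrices["IGHV1-1"]
        assert m.loc["a"].sum() == pytest.approx(1.0)
        assert m.loc["a", "D1*x"] > 0.8

    def test_single_allele_v_gene_excluded(self):
        rng = np.random.default_rng(78)
        table, db = _haplotype_table(rng)
        table.loc[table["v_call"] == "IGHV1-1*b", "v_call"] = "IGHV9-9*01"
        # IGHV1-1 and IGHV9-9 each retain one allele: nothing heterozygous
        with pytest.raises(ValueError):
            haplotype_v_genes(table, db, min_cdr3s=10, k_min=8)

    def test_low_usage_alleles_ignored(self):
        rng = np.random.default_rng(79)
        table, db = _haplotype_table(rng, n_per_combo=60)
        extra = table.iloc[:3].copy()
        extra["v_call"] = "IGHV1-1*c"  # rare third allele below the floor
        rep = haplotype_v_genes(pd.concat([table, extra]), db, min_cdr3s=10, k_min=8)
        assert sorted(rep.matrices["IGHV1-1"].index) == ["a", "b"]

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(80)
        table, db = _haplotype_table(rng)
        swapped = table.copy()
        swapped["v_call"] = swapped["v_call"].map(
            {"IGHV1-1*a": "IGHV1-1*b", "IGHV1-1*b": "IGHV1-1*a"}
        )
        rep1 = haplotype_v_genes(table, db, min_cdr3s=10, k_min=8)
        rep2 = haplotype_v_genes(swapped, db, min_cdr3s=10, k_min=8)
        a1 = rep1.assignments["IGHV1-1"]["D1"]
        a2 = rep2.assignments["IGHV1-1"]["D1"]
        assert a1["a"] == a2["b"] and a1["b"] == a2["a"]
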