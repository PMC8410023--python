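import numpy as np
import pytest

from clonodyn import (
    donor_recipient_overlap,
    expansion_size_correlation,
    origin_composition,
    overlap_coefficient,
    public_background,
    shared_clonotypes,
    shared_size_pairs,
)
from clonodyn.metrics import ExpansionThreshold
from clonodyn.overlap import OverlapError, PublicBackground
from .conftest import make_table, random_table

TAU5 = ExpansionThreshold.fixed(5)


class TestSharedClonotypes:
    def test_disjoint_and_identical(self):
        a = make_table({"CAAF": 2, "CABF": 1})
        b = make_table({"CACF": 3})
        assert shared_clonotypes(a, b) == set()
        assert shared_clonotypes(a, a) == {"CAAF", "CABF"}

    def test_pathological_class_restricts_both_sides(self):
        a = make_table({"CXF": 6, "CYF": 1})
        b = make_table({"CXF": 6, "CZF": 9}, sample_id="b")
        # equal depth 7 vs 15? pathological filter requires common depth
        a2 = make_table({"CXF": 6, "CYF": 9})
        assert shared_clonotypes(a2, b, "pathological", TAU5) == {"CXF"}

    def test_depth_mismatch_with_size_class_errors(self):
        a = make_table({"CXF": 6})
        b = make_table({"CXF": 6, "CZF": 9}, sample_id="b")
        with pytest.raises(OverlapError, match="depth"):
            shared_clonotypes(a, b, "expanded", TAU5)

    def test_symmetry_and_brute_force_oracle(self, rng):
        for _ in range(25):
            a = random_table(rng, sample_id="a")
            b = random_table(rng, sample_id="b")
            # overlap some keys deliberately
            k = min(len(a.counts), len(b.counts) // 2)
            b.counts.index = list(a.counts.index[:k]) + [
                f"CB{i}F" for i in range(len(b.counts) - k)
            ]
            got = shared_clonotypes(a, b)
            brute = {ka for ka in a.counts.index for kb in b.counts.index if ka == kb}
            assert got == brute
            assert got == shared_clonotypes(b, a)


class TestOverlapCoefficient:
    def test_identical_tables_are_one(self):
        t = make_table({"CAAF": 3, "CABF": 1})
        assert overlap_coefficient(t, t, "count") == pytest.approx(1.0)
        assert overlap_coefficient(t, t, "weighted") == pytest.approx(1.0)

    def test_hand_worked_example(self):
        a = make_table({"CXF": 2, "CYF": 1, "CZF": 1})
        b = make_table({"CXF": 1, "CWF": 3})
        assert overlap_coefficient(a, b, "count") == pytest.approx(0.5)
        assert overlap_coefficient(a, b, "weighted") == pytest.approx(0.25)

    def test_disjoint_is_zero(self):
        a = make_table({"CXF": 2})
        b = make_table({"CYF": 2})
        assert overlap_coefficient(a, b, "count") == 0.0
        assert overlap_coefficient(a, b, "weighted") == 0.0

    def test_symmetric_and_bounded(self, rng):
        for _ in range(25):
            a = random_table(rng, sample_id="a", max_clones=15)
            b = random_table(rng, sample_id="b", max_clones=15)
            k = min(len(a.counts), len(b.counts) // 2)
            b.counts.index = list(a.counts.index[:k]) + [
                f"CB{i}F" for i in range(len(b.counts) - k)
            ]
            for method in ("count", "weighted"):
                ab = overlap_coefficient(a, b, method)
                assert ab == pytest.approx(overlap_coefficient(b, a, method))
                assert 0.0 <= ab <= 1.0


class TestPublicBackground:
    def test_identical_cohort_fraction_one(self):
        t = make_table({"CAAF": 6, "CABF": 2, "CACF": 1})
        tables = [
            make_table(t.counts.to_dict(), sample_id=f"s{i}") for i in range(3)
        ]
        bg = public_background(tables, TAU5)
        assert bg.fraction_all == pytest.approx(1.0)
        assert bg.fraction_expanded == pytest.approx(1.0)
        assert bg.n_pairs == 3

    def test_disjoint_cohort_fraction_zero(self):
        tables = [
            make_table({f"C{i}AF": 2, f"C{i}BF": 1}, sample_id=f"s{i}") for i in range(3)
        ]
        bg = public_background(tables, TAU5)
        assert bg.fraction_all == 0.0
        assert bg.fraction_path_expanded == 0.0

    def test_hand_worked_fraction(self):
        # 3 samples, every pair shares exactly 2 keys, mean richness 100
        shared = {"CSHARE1F": 1, "CSHARE2F": 1}
        tables = [
            make_table(
                {**shared, **{f"C{i}X{j}F": 1 for j in range(98)}}, sample_id=f"s{i}"
            )
            for i in range(3)
        ]
        bg = public_background(tables, TAU5)
        assert bg.fraction_all == pytest.approx(2 / 100)

    def test_exclusion_list_and_minimum_pairs(self):
        t1 = make_table({"CAAF": 1}, sample_id="a")
        t2 = make_table({"CAAF": 1}, sample_id="b")
        with pytest.raises(OverlapError):
            public_background([t1, t2], TAU5, exclude_pairs={("a", "b")})


class TestDonorRecipientOverlap:
    def test_identical_pair_minus_background(self):
        t = make_table({f"C{i}F": 1 for i in range(10)}, sample_id="r")
        d = make_table(t.counts.to_dict(), sample_id="d")
        bg = PublicBackground(0.009, 0.0, 0.0, 1)
        res = donor_recipient_overlap(t, d, bg)
        assert res.recipient_shared_fraction == pytest.approx(1.0)
        assert res.adjusted_fraction == pytest.approx(0.991)

    def test_disjoint_pair_floors_at_zero(self):
        r = make_table({"CAAF": 1}, sample_id="r")
        d = make_table({"CABF": 1}, sample_id="d")
        bg = PublicBackground(0.009, 0.0, 0.0, 1)
        res = donor_recipient_overlap(r, d, bg)
        assert res.adjusted_fraction == 0.0
        assert res.raw_minus_background == pytest.approx(-0.009)

    def test_subtraction_arithmetic(self):
        # shared fraction 0.025 with background 0.009 -> adjusted 0.016
        keys = {f"C{i:03d}F": 1 for i in range(1000)}
        r = make_table(keys, sample_id="r")
        donor_keys = {f"C{i:03d}F": 1 for i in range(25)}  # 25/1000 shared
        donor_keys.update({f"D{i:03d}F": 1 for i in range(975)})
        d = make_table(donor_keys, sample_id="d")
        bg = PublicBackground(0.009, 0.0, 0.0, 1)
        res = donor_recipient_overlap(r, d, bg)
        assert res.recipient_shared_fraction == pytest.approx(0.025)
        assert res.adjusted_fraction == pytest.approx(0.016)

    def test_adjusted_fraction_bounded(self, rng):
        for _ in range(20):
            r = random_table(rng, sample_id="r")
            d = random_table(rng, sample_id="d")
            res = donor_recipient_overlap(r, d, PublicBackground(0.5, 0, 0, 1))
            assert 0.0 <= res.adjusted_fraction <= 1.0
            assert res.adjusted_fraction <= res.recipient_shared_fraction


class TestOriginComposition:
    def test_donor_disjoint_recipient_all_absent(self):
        r = make_table({"CAAF": 1, "CABF": 9})
        d = make_table({"CXF": 3}, sample_id="d")
        tab = origin_composition(r, d, TAU5)
        assert tab["absent"].sum() == 2
        assert tab.to_numpy().sum() == 2

    def test_pathological_in_both(self):
        tab = origin_composition(
            make_table({"CXF": 9}), make_table({"CXF": 8}, sample_id="d"), TAU5
        )
        assert tab.loc["pathological", "pathological"] == 1

    def test_nonexpanded_in_both(self):
        tab = origin_composition(
            make_table({"CXF": 1}), make_table({"CXF": 1}, sample_id="d"), TAU5
        )
        assert tab.loc["nonexpanded", "nonexpanded"] == 1

    def test_row_sums_equal_recipient_class_sizes(self, rng):
        r = random_table(rng, sample_id="r", max_size=12)
        d = random_table(rng, sample_id="d", max_size=12)
        k = min(len(r.counts), len(d.counts) // 2)
        d.counts.index = list(r.counts.index[:k]) + [
            f"CD{i}F" for i in range(len(d.counts) - k)
        ]
        tab = origin_composition(r, d, TAU5)
        sizes = r.counts
        assert tab.loc["nonexpanded"].sum() == (sizes == 1).sum()
        assert tab.loc["normal"].sum() == ((sizes > 1) & (sizes <= 5)).sum()
        assert tab.loc["pathological"].sum() == (sizes > 5).sum()


class TestExpansionSizeCorrelation:
    def test_monotone_and_reversed(self):
        rho, _ = expansion_size_correlation([(1, 2), (3, 5), (8, 9)])
        assert rho == pytest.approx(1.0)
        rho, _ = expansion_size_correlation([(1, 9), (3, 5), (8, 2)])
        assert rho == pytest.approx(-1.0)

    def test_hand_worked_spearman(self):
        rho, _ = expansion_size_correlation([(1, 2), (5, 4), (9, 8), (2, 1)])
        assert rho == pytest.approx(0.8)

    def test_guards(self):
        with pytest.raises(OverlapError):
            expansion_size_correlation([(1, 1), (2, 2)])
        with pytest.raises(OverlapError):
            expansion_size_correlation([(3, 1), (3, 2), (3, 5)])

    def test_shared_size_pairs_feed_correlation(self):
        r = make_table({"CAF": 1, "CBF": 5, "CCF": 9, "CDF": 2, "CRF": 7})
        d = make_table({"CAF": 2, "CBF": 4, "CCF": 8, "CDF": 1, "CQF": 3}, sample_id="d")
        pairs = shared_size_pairs(r, d)
        assert set(pairs["clonotype_key"]) == {"CAF", "CBF", "CCF", "CDF"}
        rho, _ = expansion_size_correlation(
            pairs[["recipient_size", "donor_size"]].to_numpy()
        )
        assert rho == pytest.approx(0.8)
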