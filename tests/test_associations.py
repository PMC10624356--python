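"""CN loss / WGD calls, motif and expression associations, KO test."""

import numpy as np
import pandas as pd
import pytest

from sgmsig import associations as assoc
from sgmsig.exceptions import ConfigError, InputError
from tests.test_enrichment import hypergeom_tail_oracle


def _segments(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])


class TestDetectWGD:
    def test_diploid_false(self):
        seg = _segments([("chr1", 1, 1_000_000, 2.0)])
        assert assoc.detect_wgd(seg) is False

    def test_above_threshold_true(self):
        seg = _segments([("chr1", 1, 1_000_000, 2.6)])
        assert assoc.detect_wgd(seg) is True

    def test_length_weighted_mean(self):
        seg = _segments([("chr1", 1, 500_000, 2.0), ("chr1", 500_001, 1_000_000, 4.0)])
        assert assoc.detect_wgd(seg) is True  # mean 3.0

    def test_subdivision_invariance(self):
        whole = _segments([("chr1", 1, 1000, 2.4), ("chr1", 1001, 3000, 2.7)])
        split = _segments(
            [("chr1", 1, 500, 2.4), ("chr1", 501, 1000, 2.4), ("chr1", 1001, 3000, 2.7)]
        )
        assert assoc.detect_wgd(whole) == assoc.detect_wgd(split)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            assoc.detect_wgd(_segments([]))


class TestGeneCN:
    def test_single_overlap(self):
        seg = _segments([("chr1", 1, 5000, 1.2)])
        assert assoc.gene_cn(seg, "chr1", 100, 400) == 1.2

    def test_minimum_rule(self):
        seg = _segments(
            [("chr1", 1, 2000, 2.1), ("chr1", 2001, 4000, 0.8), ("chr1", 4001, 9000, 1.5)]
        )
        assert assoc.gene_cn(seg, "chr1", 1500, 4500) == 0.8

    def test_short_segment_ignored(self):
        seg = _segments([("chr1", 100, 599, 0.5)])
        assert assoc.gene_cn(seg, "chr1", 100, 400) is None

    def test_wrong_chromosome(self):
        seg = _segments([("chr2", 1, 5000, 1.2)])
        assert assoc.gene_cn(seg, "chr1", 100, 400) is None


class TestGeneLoss:
    @pytest.mark.parametrize(
        "cn,platform,wgd,chrom,sex,expected",
        [
            (1.4, "WGS", False, "1", "female", True),
            (1.5, "WGS", False, "1", "female", False),
            (1.9, "WGS", True, "1", "female", True),
            (2.0, "WGS", True, "1", "female", False),
            (1.2, "WGS", False, "X", "male", False),
            (0.9, "WGS", False, "X", "male", True),
            (1.4, "WGS", True, "X", "male", True),
            (1.4, "WGS", False, "X", "female", True),
            (-0.1, "TCGA", False, "1", "female", True),
            (0.0, "TCGA", False, "1", "female", False),
            (None, "WGS", False, "1", "female", False),
        ],
    )
    def test_threshold_table(self, cn, platform, wgd, chrom, sex, expected):
        assert assoc.gene_loss(cn, platform, wgd, chrom, sex) is expected

    def test_unknown_platform_rejected(self):
        with pytest.raises(ConfigError):
            assoc.gene_loss(1.0, "array")

    def test_missing_sex_on_x_warns(self):
        with pytest.warns(UserWarning):
            assoc.gene_loss(1.4, "WGS", False, "X", None)

    def test_monotone_in_cn(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cn = rng.uniform(0, 3)
            lower = cn - rng.uniform(0, 1)
            for wgd in (False, True):
                if assoc.gene_loss(cn, "WGS", wgd):
                    assert assoc.gene_loss(lower, "WGS", wgd)


class TestCooccurrence:
    def test_published_count_fractions(self):
        sgm = [f"s{i}" for i in range(467)]
        loss = sgm[:275]
        k, n, frac = assoc.cooccurrence(sgm, loss)
        assert (k, n) == (275, 467)
        assert round(100 * frac, 1) == 58.9

    def test_small_gene(self):
        sgm = [f"s{i}" for i in range(29)]
        k, n, frac = assoc.cooccurrence(sgm, sgm[:25])
        assert round(100 * frac, 1) == 86.2

    def test_no_losses(self):
        assert assoc.cooccurrence(["a", "b"], [])[2] == 0.0

    def test_empty_sgm_rejected(self):
        with pytest.raises(InputError):
            assoc.cooccurrence([], ["a"])


class TestMotifTest:
    def _frame(self, ytca, rtca, other):
        return pd.DataFrame(
            {"motif_class": ["YTCA"] * ytca + ["RTCA"] * rtca + ["other"] * other}
        )

    def test_identical_composition_null(self):
        res = assoc.motif_test(self._frame(10, 10, 10), self._frame(20, 20, 20))
        assert (res["p"] >= 0.5).all()

    def test_extreme_separation(self):
        res = assoc.motif_test(self._frame(20, 0, 0), self._frame(0, 20, 0))
        y = res[res.motif == "YTCA"].iloc[0]
        assert y.p == pytest.approx(hypergeom_tail_oracle(20, 0, 0, 20), rel=1e-9)

    def test_small_table_matches_enumeration(self):
        res = assoc.motif_test(self._frame(3, 1, 2), self._frame(2, 4, 5))
        y = res[res.motif == "YTCA"].iloc[0]
        assert y.p == pytest.approx(hypergeom_tail_oracle(3, 3, 2, 9), rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            assoc.motif_test(self._frame(0, 0, 0), self._frame(1, 1, 1))


class TestExpressionAssociation:
    def test_counts_follow_expression_rank(self):
        idx = [f"s{i}" for i in range(20)]
        expr = pd.Series(np.arange(20, dtype=float), index=idx)
        counts = pd.DataFrame({"sgm": np.arange(20)}, index=idx)
        res = assoc.expression_association(expr, counts)
        assert res.loc[0, "p"] < 1e-4

    def test_independent_counts_calibrated(self):
        rng = np.random.default_rng(5)
        idx = [f"s{i}" for i in range(40)]
        rejections = 0
        n_rep = 50
        for _ in range(n_rep):
            expr = pd.Series(rng.normal(size=40), index=idx)
            counts = pd.DataFrame({"sgm": rng.poisson(2.0, 40)}, index=idx)
            res = assoc.expression_association(expr, counts)
            rejections += res.loc[0, "p"] < 0.05
        assert rejections / n_rep < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_constant_expression_skipped(self):
        idx = [f"s{i}" for i in range(10)]
        expr = pd.Series(1.0, index=idx)
        counts = pd.DataFrame({"sgm": np.arange(10)}, index=idx)
        res = assoc.expression_association(expr, counts)
        assert np.isnan(res.loc[0, "p"])

    def test_tiny_group_skipped(self):
        idx = [f"s{i}" for i in range(4)]
        expr = pd.Series([1.0, 1.0, 1.0, 5.0], index=idx)  # one sample above median
        counts = pd.DataFrame({"sgm": [1, 2, 3, 4]}, index=idx)
        res = assoc.expression_association(expr, counts)
        assert np.isnan(res.loc[0, "p"])

    def test_too_few_samples_rejected(self):
        idx = ["a", "b", "c"]
        with pytest.raises(InputError):
            assoc.expression_association(
                pd.Series([1.0, 2.0, 3.0], index=idx),
                pd.DataFrame({"sgm": [1, 2, 3]}, index=idx),
            )


class TestSmokingBurden:
    def _data(self, shift=0.0, seed=0, n=15):
        rng = np.random.default_rng(seed)
        cats = ["never", "reformed_long", "reformed_recent", "current"]
        idx, grp, cnt = [], [], []
        for ci, cat in enumerate(cats):
            for i in range(n):
                idx.append(f"{cat}{i}")
                grp.append(cat)
                lam = 3.0 + (shift if cat == "current" else 0.0)
                cnt.append(rng.poisson(lam))
        groups = pd.Series(grp, index=idx)
        counts = pd.DataFrame({"sbs4_sgms": cnt}, index=idx)
        return groups, counts

    def test_null_no_significant_pairs(self):
        hits = 0
        for s in range(10):
            groups, counts = self._data(seed=s)
            res = assoc.smoking_burden(groups, counts)
            hits += (res["fdr"] < 0.05).any()
        assert hits <= 2

    def test_shifted_group_detected(self):
        groups, counts = self._data(shift=15.0, seed=1)
        res = assoc.smoking_burden(groups, counts)
        current = res[(res.group_a == "current") | (res.group_b == "current")]
        assert (current["p"] < 0.01).all()
        assert res["p"].min() == current["p"].min()

    def test_single_group_no_tests(self):
        idx = ["a", "b"]
        res = assoc.smoking_burden(
            pd.Series(["current", "current"], index=idx),
            pd.DataFrame({"c": [1, 2]}, index=idx),
        )
        assert res.empty


class TestKOTest:
    def _clones(self, wt_mean, ko_mean, n=10, seed=0, dispersion=0.3):
        rng = np.random.default_rng(seed)
        rows = []
        for grp, mean in (("WT", wt_mean), ("KO", ko_mean)):
            lam = rng.gamma(1 / dispersion, mean * dispersion, n)
            for i, l in enumerate(lam):
                rows.append({"cell_line": "BT474", "clone_id": f"{grp}{i}", "group": grp, "sgm": rng.poisson(l)})
        return pd.DataFrame(rows)

    def test_strong_knockout_effect_detected(self):
        res = assoc.ko_test(self._clones(50, 10, seed=2), "sgm")
        assert res.p < 0.01

    def test_null_not_significant(self):
        ps = [assoc.ko_test(self._clones(30, 30, seed=s), "sgm").p for s in range(10)]
        assert np.mean(np.array(ps) < 0.05) <= 0.3

    def test_single_clone_group_rejected(self):
        df = pd.DataFrame(
            {"group": ["WT", "KO", "KO"], "sgm": [5, 1, 2]}
        )
        with pytest.raises(InputError):
            assoc.ko_test(df, "sgm")

    def test_all_zero_counts_rejected(self):
        df = pd.DataFrame({"group": ["WT"] * 3 + ["KO"] * 3, "sgm": [0] * 6})
        with pytest.raises(InputError):
            assoc.ko_test(df, "sgm")

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame({"group": ["WT"] * 3 + ["KO"] * 3, "sgm": [1.5] * 6})
        with pytest.raises(InputError):
            assoc.ko_test(df, "sgm")


def test_loss_calls_for_gene():
    seg = pd.DataFrame(
        {
            "sample_id": ["a", "a", "b"],
            "chrom": ["chr1"] * 3,
            "start": [1, 5001, 1],
            "end": [5000, 10_000, 10_000],
            "cn": [1.2, 2.0, 2.0],
        }
    )
    meta = pd.DataFrame({"sample_id": ["a", "b"], "sex": ["female", "male"]})
    calls = assoc.loss_calls_for_gene(seg, "chr1", 2000, 3000, meta)
    calls = calls.set_index("sample_id")
    assert bool(calls.loc["a", "loss"]) is True
    assert bool(calls.loc["b", "loss"]) is False
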