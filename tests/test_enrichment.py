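"""QC filters and the signature x class enrichment engine."""

import math

import numpy as np
import pandas as pd
import pytest

from sgmsig import enrichment as enr
from sgmsig import signatures as sig
from sgmsig.exceptions import FormatError, InputError


def hypergeom_tail_oracle(a, b, c, d):
    """Exhaustive one-tailed p: sum hypergeometric terms with x >= a."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    p = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if x >= a:
            p += math.comb(row1, x) * math.comb(n - row1, col1 - x) / denom
    return p


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 15, size=4)
        assert enr.fisher_greater(a, b, c, d) == pytest.approx(
            hypergeom_tail_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


def test_fisher_worked_example():
    assert enr.fisher_greater(8, 2, 2, 8) == pytest.approx(
        hypergeom_tail_oracle(8, 2, 2, 8), rel=1e-12
    )


def bh_oracle(p):
    """Hand-written Benjamini-Hochberg step-up."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def test_bh_fdr_matches_hand_oracle():
    rng = np.random.default_rng(1)
    for _ in range(20):
        p = rng.random(rng.integers(1, 40))
        assert np.allclose(enr.bh_fdr(p), bh_oracle(p), atol=1e-12)


def test_bh_fdr_properties():
    rng = np.random.default_rng(2)
    p = rng.random(50)
    q = enr.bh_fdr(p)
    assert (q >= p - 1e-12).all() and (q <= 1 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


class TestExpectedCount:
    def test_analytic_mean(self):
        mean, _ = enr.expected_count(1000, 0.5, 0.2, 10_000, seed=0)
        sd = np.sqrt(1000 * 0.1 * 0.9 / 10_000)
        assert abs(mean - 100) < 3 * sd

    def test_zero_probability(self):
        mean, (lo, hi) = enr.expected_count(1000, 0.5, 0.0, 100, seed=0)
        assert (mean, lo, hi) == (0.0, 0.0, 0.0)

    def test_ci_covers_analytic_mean(self):
        hits = 0
        for s in range(20):
            _, (lo, hi) = enr.expected_count(1000, 0.5, 0.2, 10_000, seed=s)
            hits += lo <= 100 <= hi
        assert hits >= 18

    def test_invalid_probability_rejected(self):
        with pytest.raises(InputError):
            enr.expected_count(10, 1.5, 0.1, 10, seed=0)


def _metadata(samples, platform="WGS", cancer_type="lung", purity=0.8):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "platform": platform,
            "cancer_type": cancer_type,
            "patient_id": samples,
            "purity": purity,
        }
    )


def _mutations(sample_counts):
    rows = []
    for s, n in sample_counts.items():
        for i in range(n):
            rows.append({"sample_id": s, "chrom": "chr1", "pos": i + 1, "ref": "C", "alt": "A"})
    return pd.DataFrame(rows)


class TestQCFilter:
    def test_wgs_hypermutator_removed(self):
        muts = _mutations({"a": 90_001, "b": 100})
        meta = _metadata(["a", "b"] + [f"x{i}" for i in range(25)])
        kept, meta_kept, log = enr.qc_filter(muts, meta)
        assert "a" not in set(meta_kept["sample_id"])
        assert log.loc[log.sample_id == "a", "rule"].item() == "hypermutator"

    def test_wes_low_count_removed(self):
        muts = _mutations({"a": 19, "b": 100})
        meta = _metadata(["a", "b"] + [f"x{i}" for i in range(25)], platform="WES")
        kept, meta_kept, log = enr.qc_filter(muts, meta)
        assert "a" not in set(meta_kept["sample_id"])
        assert "low_confidence" in set(log["rule"])

    def test_artifact_sample_removed(self):
        muts = _mutations({"a": 100, "b": 100})
        labels = ["SBS45"] * 21 + ["SBS4"] * 79 + ["SBS4"] * 100
        muts["signature_label"] = labels
        meta = _metadata(["a", "b"] + [f"x{i}" for i in range(25)])
        kept, meta_kept, log = enr.qc_filter(muts, meta)
        assert "a" not in set(meta_kept["sample_id"])
        assert "artifact_signatures" in set(log["rule"])

    def test_patient_dedup_keeps_highest_purity(self):
        muts = _mutations({"a": 100, "b": 100})
        meta = _metadata(["a", "b"] + [f"x{i}" for i in range(25)])
        meta.loc[meta.sample_id.isin(["a", "b"]), "patient_id"] = "p1"
        meta.loc[meta.sample_id == "a", "purity"] = 0.9
        meta.loc[meta.sample_id == "b", "purity"] = 0.5
        kept, meta_kept, log = enr.qc_filter(muts, meta)
        assert "a" in set(meta_kept["sample_id"])
        assert "b" not in set(meta_kept["sample_id"])

    def test_small_cancer_type_dropped(self):
        muts = _mutations({f"s{i}": 50 for i in range(30)})
        meta = _metadata([f"s{i}" for i in range(30)])
        meta.loc[meta.sample_id.isin(["s0", "s1"]), "cancer_type"] = "rare"
        kept, meta_kept, log = enr.qc_filter(muts, meta)
        assert "rare" not in set(meta_kept["cancer_type"])

    def test_missing_metadata_column_rejected(self):
        with pytest.raises(FormatError):
            enr.qc_filter(_mutations({"a": 5}), pd.DataFrame({"sample_id": ["a"]}))


def _labeled_frame(n, sig_frac, class_frac, rng, coupled=0.0):
    """Synthetic annotated+labelled table; `coupled` adds signature-class excess."""
    is_sig = rng.random(n) < sig_frac
    p_class = np.where(is_sig, class_frac + coupled, class_frac)
    is_cls = rng.random(n) < p_class
    return pd.DataFrame(
        {
            "sample_id": "s",
            "functional_class": np.where(is_cls, "stop_gain", "missense"),
            "signature_label": np.where(is_sig, "SBS_X", "SBS_Y"),
        }
    )


class TestClassSignatureTests:
    def test_extreme_table_minimal_p(self):
        df = pd.DataFrame(
            {
                "sample_id": "s",
                "functional_class": ["stop_gain"] * 30 + ["missense"] * 170,
                "signature_label": ["SBS_X"] * 30 + ["SBS_Y"] * 170,
            }
        )
        config = enr.CohortConfig(min_signature_snvs=10)
        res = enr.class_signature_tests(df, config)
        row = res[(res.signature == "SBS_X") & (res.target == "stop_gain")].iloc[0]
        assert row.p == pytest.approx(hypergeom_tail_oracle(30, 0, 0, 170), rel=1e-9)

    def test_signature_below_threshold_skipped(self):
        rng = np.random.default_rng(3)
        df = _labeled_frame(150, 0.5, 0.2, rng)
        res = enr.class_signature_tests(df, enr.CohortConfig(min_signature_snvs=100))
        assert set(res["signature"]) <= {"SBS_X", "SBS_Y"}
        res2 = enr.class_signature_tests(df, enr.CohortConfig(min_signature_snvs=1000))
        assert res2.empty

    def test_unassigned_retained_in_totals_but_not_tested(self):
        df = pd.DataFrame(
            {
                "sample_id": "s",
                "functional_class": ["stop_gain"] * 20 + ["missense"] * 180,
                "signature_label": ["SBS_X"] * 100 + [sig.UNASSIGNED] * 100,
            }
        )
        res = enr.class_signature_tests(df, enr.CohortConfig(min_signature_snvs=10))
        assert sig.UNASSIGNED not in set(res["signature"])
        # totals include the unassigned SNVs: expected ~ n * p_sig * p_class
        row = res[(res.signature == "SBS_X") & (res.target == "stop_gain")].iloc[0]
        assert row.expected_mean == pytest.approx(200 * 0.5 * 0.1, rel=0.1)

    def test_fold_change_definition(self):
        assert enr.fold_change(10, 5) == 2.0
        assert np.isnan(enr.fold_change(10, 0))


class TestAminoAcidTests:
    def test_signature_hits_only_serine(self):
        df = pd.DataFrame(
            {
                "functional_class": "stop_gain",
                "signature_label": ["SBS_X"] * 10 + ["SBS_Y"] * 40,
                "ref_aa": ["S"] * 10 + ["E"] * 40,
            }
        )
        res = enr.amino_acid_tests(df, "SBS_X")
        ser = res[res.target == "S"].iloc[0]
        assert ser.p == pytest.approx(hypergeom_tail_oracle(10, 0, 0, 40), rel=1e-9)
        assert ser.frac_signature == 1.0

    def test_no_signature_sgms_rejected(self):
        df = pd.DataFrame(
            {"functional_class": ["stop_gain"], "signature_label": ["SBS_Y"], "ref_aa": ["S"]}
        )
        with pytest.raises(InputError):
            enr.amino_acid_tests(df, "SBS_X")


class TestProbabilisticReplication:
    def test_degenerate_exposures_reduce_to_top(self, catalog):
        df = pd.DataFrame(
            {
                "sample_id": "s",
                "channel": ["T[C>G]A"] * 120 + ["T[C>A]A"] * 80,
                "functional_class": ["stop_gain"] * 60 + ["missense"] * 140,
            }
        )
        exposures = {"s": sig.ExposureVector("s", {"SBS13": 1.0})}
        config = enr.CohortConfig(min_signature_snvs=10)
        rep = enr.probabilistic_replication(
            df, exposures, catalog, config, seed=3, iterations=5
        )
        assert rep["iteration"].nunique() == 5
        # single-signature exposure: every iteration identical to top assignment
        top = sig.assign_top_table(df, exposures, catalog)
        ref = enr.class_signature_tests(top, config, seed=enr.child_seed(3, 1), classes=("stop_gain",))
        for _, grp in rep.groupby("iteration"):
            assert grp["observed"].tolist() == ref["observed"].tolist()
            assert grp["p"].tolist() == ref["p"].tolist()

    def test_seed_derivation_reproducible(self):
        assert enr.child_seed(5, 1) == (5 * 100003 + 1) % 2**31
        assert enr.child_seed(5, 1) != enr.child_seed(5, 2)


class TestPanCancer:
    def _cohort(self, seed, n=400):
        rng = np.random.default_rng(seed)
        return _labeled_frame(n, 0.5, 0.2, rng)

    def test_single_cohort_identity(self):
        df = self._cohort(0)
        config = enr.CohortConfig(min_signature_snvs=50)
        single = enr.class_signature_tests(df, config, seed=1)
        pooled = enr.pan_cancer([df], config, seed=1)
        assert pooled["observed"].tolist() == single["observed"].tolist()
        assert pooled["p"].tolist() == single["p"].tolist()

    def test_pooled_counts_are_sums(self):
        a, b = self._cohort(1), self._cohort(2)
        config = enr.CohortConfig(min_signature_snvs=50)
        pooled = enr.pan_cancer([a, b], config)
        for df in (a, b):
            pass
        obs = pooled.set_index(["signature", "target"])["observed"]
        for sig_name in ("SBS_X", "SBS_Y"):
            total = sum(
                ((df.signature_label == sig_name) & (df.functional_class == "stop_gain")).sum()
                for df in (a, b)
            )
            assert obs.loc[(sig_name, "stop_gain")] == total

    def test_empty_pool_rejected(self):
        with pytest.raises(InputError):
            enr.pan_cancer([])
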