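"""Cohort QC and signature x functional-class enrichment statistics.

The core question: do SNVs attributed to a given SBS signature and SNVs of a
given protein-coding functional class (stop-gain in particular) co-occur more
often than expected under independence?  Tested with one-tailed Fisher's exact
tests on 2x2 tables, Benjamini-Hochberg FDR within each cohort x cancer-type
family, and expected counts with 95% CIs from binomial resampling under the
product of the marginal signature and class frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from sgmsig.exceptions import FormatError, InputError
from sgmsig.signatures import ARTIFACT_SIGNATURES, UNASSIGNED, sample_assignments

CODING_CLASSES = ("missense", "silent", "stop_gain", "stop_loss", "start_loss")

#: Fixed arithmetic mapping a master seed to per-iteration child seeds.
def child_seed(master_seed: int, iteration: int) -> int:
    return (int(master_seed) * 100003 + int(iteration)) % (2**31)


@dataclass
class CohortConfig:
    """Analysis thresholds; defaults follow the study design.

    Hypermutators (>90,000 SNVs WGS / >1,800 WES, ~30 SNVs/Mbp) and
    low-confidence WES samples (<20 SNVs) are removed; samples with >20% of
    SNVs on artifact signatures are removed; cancer types need >=25 samples;
    signatures are tested at >=100 SNVs per cohort and FDR < 0.01.
    """

    hypermutator_threshold_wgs: int = 90_000
    hypermutator_threshold_wes: int = 1_800
    min_snvs_wes: int = 20
    artifact_fraction_threshold: float = 0.20
    min_samples_per_type: int = 25
    min_signature_snvs: int = 100
    fdr_threshold: float = 0.01
    binomial_iterations: int = 10_000
    probabilistic_iterations: int = 100
    artifact_signatures: frozenset = field(default_factory=lambda: ARTIFACT_SIGNATURES)

    def __post_init__(self) -> None:
        for name in (
            "hypermutator_threshold_wgs",
            "hypermutator_threshold_wes",
            "min_snvs_wes",
            "artifact_fraction_threshold",
            "min_samples_per_type",
            "min_signature_snvs",
            "fdr_threshold",
            "binomial_iterations",
            "probabilistic_iterations",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass
class EnrichmentResult:
    cohort: str
    cancer_type: str
    signature: str
    target: str
    observed: int
    expected_mean: float
    expected_lo: float
    expected_hi: float
    fold_change: float
    p: float
    fdr: float = np.nan


def fold_change(observed: float, expected: float) -> float:
    """Observed over expected; the enrichment effect size."""
    if expected <= 0:
        return np.nan
    return observed / expected


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-tailed (enrichment) Fisher's exact p for the 2x2 table [[a,b],[c,d]]."""
    for x in (a, b, c, d):
        if x < 0:
            raise InputError("contingency counts must be non-negative")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def bh_fdr(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def expected_count(
    n_total: int, p_signature: float, p_class: float, iterations: int, seed: int
) -> tuple[float, tuple[float, float]]:
    """Expected co-occurrence count under independence, by binomial sampling.

    Draws Binomial(n_total, p_signature * p_class) ``iterations`` times and
    returns the sample mean and the 2.5/97.5 percentiles.
    """
    if not (0 <= p_signature <= 1 and 0 <= p_class <= 1):
        raise InputError("probabilities must lie in [0, 1]")
    if iterations < 1:
        raise InputError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(n_total, p_signature * p_class, size=iterations)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), (float(lo), float(hi))


def qc_filter(
    mutations: pd.DataFrame, metadata: pd.DataFrame, config: CohortConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply cohort QC filters in order; returns (mutations, metadata, exclusion log).

    Order: hypermutator removal (platform-specific SNV-count threshold), WES
    low-count removal, artifact-signature-fraction removal (needs a
    ``signature_label`` column; skipped otherwise), per-patient deduplication
    keeping the highest-purity sample, and consolidation dropping cancer types
    with fewer than the minimum sample count.
    """
    config = config or CohortConfig()
    required = {"sample_id", "platform", "cancer_type", "patient_id", "purity"}
    missing = required - set(metadata.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    meta = metadata.copy()
    counts = mutations.groupby("sample_id").size()
    log: list[dict] = []

    def drop(sample_ids: Iterable[str], rule: str) -> None:
        nonlocal meta
        ids = [s for s in sample_ids if s in set(meta["sample_id"])]
        for s in ids:
            log.append({"sample_id": s, "rule": rule})
        meta = meta[~meta["sample_id"].isin(ids)]

    n = meta.set_index("sample_id").join(counts.rename("n_snvs"), how="left")["n_snvs"].fillna(0)
    platform = meta.set_index("sample_id")["platform"]
    hyper = n[
        ((platform == "WGS") & (n > config.hypermutator_threshold_wgs))
        | ((platform == "WES") & (n > config.hypermutator_threshold_wes))
    ].index
    drop(hyper, "hypermutator")

    low = n[(platform == "WES") & (n < config.min_snvs_wes)].index
    drop(low, "low_confidence")

    if "signature_label" in mutations.columns:
        frac = (
            mutations.assign(is_art=mutations["signature_label"].isin(config.artifact_signatures))
            .groupby("sample_id")["is_art"]
            .mean()
        )
        # the artifact filter applies to WGS data only
        wgs = platform[platform == "WGS"].index
        art = frac[(frac > config.artifact_fraction_threshold) & frac.index.isin(wgs)].index
        drop(art, "artifact_signatures")

    dup = meta.sort_values(["purity", "sample_id"], ascending=[False, True]).duplicated(
        subset=["patient_id", "platform"], keep="first"
    )
    drop(meta.loc[dup[dup].index, "sample_id"], "duplicate_patient")

    type_sizes = meta.groupby("cancer_type")["sample_id"].nunique()
    small = type_sizes[type_sizes < config.min_samples_per_type].index
    drop(meta.loc[meta["cancer_type"].isin(small), "sample_id"], "small_cancer_type")

    kept = mutations[mutations["sample_id"].isin(set(meta["sample_id"]))]
    return kept.reset_index(drop=True), meta.reset_index(drop=True), pd.DataFrame(log, columns=["sample_id", "rule"])


def _exonic(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["functional_class"].isin(CODING_CLASSES)]


def class_signature_tests(
    annotated: pd.DataFrame,
    config: CohortConfig | None = None,
    seed: int = 0,
    cohort: str = "cohort",
    cancer_type: str = "all",
    classes: Iterable[str] = CODING_CLASSES,
) -> pd.DataFrame:
    """All eligible signature x class enrichment tests for one analysis family.

    A signature is eligible with >= ``min_signature_snvs`` exonic SNVs (and it
    must not be an artifact signature); each test additionally requires at
    least one SNV of the tested class carrying the signature.  FDR is BH
    within this family.  Expected counts and 95% CIs come from binomial
    sampling under the empirical marginal frequencies.
    """
    config = config or CohortConfig()
    df = _exonic(annotated)
    n_total = len(df)
    results: list[EnrichmentResult] = []
    empty = pd.DataFrame(columns=list(EnrichmentResult.__dataclass_fields__))
    if n_total == 0:
        return empty
    sig_counts = df["signature_label"].value_counts()
    eligible = [
        s
        for s in sig_counts.index
        if s != UNASSIGNED
        and s not in config.artifact_signatures
        and sig_counts[s] >= config.min_signature_snvs
    ]
    i = 0
    for sig in sorted(eligible):
        is_sig = df["signature_label"] == sig
        for cls in classes:
            is_cls = df["functional_class"] == cls
            a = int((is_sig & is_cls).sum())
            if a < 1:
                continue  # eligibility: >=1 SNV of the class in the signature
            b = int(is_sig.sum()) - a
            c = int(is_cls.sum()) - a
            d = n_total - a - b - c
            p = fisher_greater(a, b, c, d)
            i += 1
            mean, (lo, hi) = expected_count(
                n_total,
                (a + b) / n_total,
                (a + c) / n_total,
                config.binomial_iterations,
                child_seed(seed, i),
            )
            results.append(
                EnrichmentResult(
                    cohort, cancer_type, sig, cls, a, mean, lo, hi,
                    fold_change(a, mean), p,
                )
            )
    if not results:
        return empty
    out = pd.DataFrame([asdict(r) for r in results])
    out["fdr"] = bh_fdr(out["p"])
    return out


def amino_acid_tests(
    sgms: pd.DataFrame,
    signature: str,
    cohort: str = "cohort",
    cancer_type: str = "all",
) -> pd.DataFrame:
    """Per-amino-acid enrichment of a signature among stop-gain mutations.

    For each reference amino acid, a one-tailed Fisher test of
    {signature vs other signatures} x {this amino acid vs others} among SGMs;
    FDR across amino acids.  Reports the observed fraction of the signature's
    SGMs hitting the amino acid and the corresponding fraction in all other
    signatures, whose ratio is the fold change.
    """
    df = sgms[sgms["functional_class"] == "stop_gain"]
    is_sig = df["signature_label"] == signature
    n_sig = int(is_sig.sum())
    if n_sig < 1:
        raise InputError(f"no stop-gain mutations assigned to {signature}")
    rows = []
    for aa in sorted(df["ref_aa"].dropna().unique()):
        is_aa = df["ref_aa"] == aa
        a = int((is_sig & is_aa).sum())
        b = n_sig - a
        c = int(is_aa.sum()) - a
        d = len(df) - a - b - c
        frac_sig = a / n_sig
        frac_other = c / (c + d) if (c + d) > 0 else np.nan
        rows.append(
            {
                "cohort": cohort,
                "cancer_type": cancer_type,
                "signature": signature,
                "target": aa,
                "observed": a,
                "frac_signature": frac_sig,
                "frac_other": frac_other,
                "expected_mean": n_sig * frac_other if np.isfinite(frac_other) else np.nan,
                "fold_change": fold_change(frac_sig, frac_other),
                "p": fisher_greater(a, b, c, d),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["p"])
    return out


def probabilistic_replication(
    annotated: pd.DataFrame,
    exposures: dict,
    catalog,
    config: CohortConfig | None = None,
    seed: int = 0,
    target_class: str = "stop_gain",
    iterations: int | None = None,
) -> pd.DataFrame:
    """Repeat the SGM enrichment analysis over multinomial label draws.

    Per iteration, per-SNV signatures are sampled from the full per-sample
    posterior (rather than the top assignment), the signature x stop-gain
    tests are re-run, and FDR is adjusted separately within the iteration.
    Iteration ``i`` uses the derived seed ``child_seed(seed, i)``.
    """
    config = config or CohortConfig()
    n_iter = iterations or config.probabilistic_iterations
    frames = []
    for i in range(1, n_iter + 1):
        s = child_seed(seed, i)
        labels = sample_assignments(annotated, exposures, catalog, seed=s)
        drawn = annotated.copy()
        drawn["signature_label"] = labels
        res = class_signature_tests(drawn, config, seed=s, classes=(target_class,))
        res["iteration"] = i
        frames.append(res)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if not out.empty:
        out["significant"] = out["fdr"] < 0.05
    return out


def pan_cancer(
    cohorts: list[pd.DataFrame],
    config: CohortConfig | None = None,
    seed: int = 0,
    cohort: str = "pooled",
) -> pd.DataFrame:
    """Pool annotated+labelled samples across cancer types and re-test.

    FDR is computed within the pooled family.
    """
    if not cohorts:
        raise InputError("no cohorts to pool")
    pooled = pd.concat(cohorts, ignore_index=True)
    return class_signature_tests(pooled, config, seed=seed, cohort=cohort, cancer_type="pan-cancer")
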