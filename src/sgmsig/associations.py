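"""Molecular and clinical associations of stop-gain mutation burden.

Covers: copy-number loss calls with whole-genome-duplication (WGD)-aware
thresholds and their co-occurrence with SGMs (biallelic inactivation);
APOBEC quadnucleotide motif enrichment (YTCA vs RTCA); association of SGM
burden with median-dichotomised gene expression; smoking-history burden
comparisons; and a negative-binomial two-model likelihood-ratio test for
knockout-clone experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from sgmsig.enrichment import bh_fdr, fisher_greater
from sgmsig.exceptions import ConfigError, InputError

WGD_THRESHOLD = 2.5
MIN_SEGMENT_BP = 1000
X_NAMES = frozenset({"X", "chrX"})

MOTIF_CLASSES = ("YTCA", "RTCA", "other")


def detect_wgd(segments: pd.DataFrame) -> bool:
    """Whole-genome duplication call: length-weighted mean CN > 2.5.

    ``segments`` needs columns start, end (1-based inclusive) and cn.
    """
    if len(segments) == 0:
        raise InputError("empty CN profile")
    lengths = segments["end"].to_numpy() - segments["start"].to_numpy() + 1
    if (lengths <= 0).any():
        raise InputError("segment with start > end")
    mean_cn = float(np.average(segments["cn"].to_numpy(dtype=float), weights=lengths))
    return mean_cn > WGD_THRESHOLD


def gene_cn(
    segments: pd.DataFrame, chrom: str, start: int, end: int
) -> float | None:
    """Gene-level CN: the lowest CN among overlapping segments >= 1000 bp.

    Returns None when no qualifying segment overlaps the gene (interpreted
    downstream as "no CNA data", i.e. no deletion).
    """
    seg = segments[segments["chrom"].astype(str) == str(chrom)]
    lengths = seg["end"] - seg["start"] + 1
    overlap = (seg["start"] <= end) & (seg["end"] >= start) & (lengths >= MIN_SEGMENT_BP)
    if not overlap.any():
        return None
    return float(seg.loc[overlap, "cn"].min())


def gene_loss(
    cn: float | None,
    platform: str,
    wgd: bool = False,
    chrom: str = "1",
    sex: str | None = None,
) -> bool:
    """Platform-, WGD-, and sex-aware gene-loss call from gene CN.

    TCGA relative CN calls: loss when cn < 0.0.  WGS absolute CN: autosomes
    and female X use cn < 1.5 (non-WGD) / cn < 2.0 (WGD); male X uses
    cn < 1.0 (non-WGD) / cn < 1.5 (WGD).  Missing CN data means no loss;
    missing sex on X falls back to the autosome rule with a warning.
    """
    if cn is None:
        return False
    if platform == "TCGA":
        return cn < 0.0
    if platform != "WGS":
        raise ConfigError(f"unknown CN platform {platform!r}")
    on_x = str(chrom) in X_NAMES
    if on_x and sex is None:
        warnings.warn("sample on chrX without sex annotation; using autosome rule")
    if on_x and sex == "male":
        return cn < (1.5 if wgd else 1.0)
    return cn < (2.0 if wgd else 1.5)


def cooccurrence(
    sgm_samples: Iterable[str], loss_samples: Iterable[str]
) -> tuple[int, int, float]:
    """Co-occurrence of SGMs and CN losses of a gene in the same samples.

    Returns (k, n, fraction): of the n samples carrying an SGM in the gene,
    k also carry a CN loss of it.
    """
    sgm = set(sgm_samples)
    n = len(sgm)
    if n < 1:
        raise InputError("need at least one SGM-carrying sample")
    k = len(sgm & set(loss_samples))
    return k, n, k / n


def loss_calls_for_gene(
    cn_segments: pd.DataFrame,
    gene_chrom: str,
    gene_start: int,
    gene_end: int,
    sample_meta: pd.DataFrame,
    platform: str = "WGS",
) -> pd.DataFrame:
    """Per-sample gene CN and loss call for one gene.

    ``cn_segments`` holds columns sample_id, chrom, start, end, cn for all
    samples; ``sample_meta`` provides optional ``sex`` per sample_id.  WGD is
    detected per sample from its full segment profile.
    """
    sex_map = (
        sample_meta.set_index("sample_id")["sex"].to_dict()
        if "sex" in sample_meta.columns
        else {}
    )
    rows = []
    for sample, seg in cn_segments.groupby("sample_id"):
        wgd = detect_wgd(seg) if platform == "WGS" else False
        cn = gene_cn(seg, gene_chrom, gene_start, gene_end)
        rows.append(
            {
                "sample_id": sample,
                "gene_cn": np.nan if cn is None else cn,
                "wgd": wgd,
                "loss": gene_loss(cn, platform, wgd, gene_chrom, sex_map.get(sample)),
            }
        )
    return pd.DataFrame(rows)


def motif_test(sgms: pd.DataFrame, non_sgms: pd.DataFrame) -> pd.DataFrame:
    """Per-motif enrichment of SGMs relative to non-SGM mutations.

    Both tables are expected to carry a ``motif_class`` column and to contain
    mutations of the same signature (SBS13 in the reference analysis).  For
    each motif class, a one-tailed Fisher test of {SGM vs non-SGM} x
    {this motif vs others}.
    """
    if len(sgms) == 0 or len(non_sgms) == 0:
        raise InputError("both SGM and non-SGM sets must be non-empty")
    rows = []
    for motif in MOTIF_CLASSES:
        a = int((sgms["motif_class"] == motif).sum())
        b = len(sgms) - a
        c = int((non_sgms["motif_class"] == motif).sum())
        d = len(non_sgms) - c
        rows.append(
            {
                "motif": motif,
                "sgm_count": a,
                "sgm_fraction": a / len(sgms),
                "non_sgm_count": c,
                "non_sgm_fraction": c / len(non_sgms),
                "p": fisher_greater(a, b, c, d),
            }
        )
    return pd.DataFrame(rows)


def expression_association(
    expression: pd.Series,
    sgm_counts: pd.DataFrame,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """SGM burden vs median-dichotomised expression of one gene.

    Samples strictly above the median expression form the high group (ties go
    low); per count category, a one-tailed Wilcoxon rank-sum test asks whether
    the high group carries more SGMs.  Samples with zero counts are included.
    Returns one row per category with the p value; categories are the columns
    of ``sgm_counts``.  Constant expression or groups smaller than
    ``min_per_group`` yield a skipped (NaN) test.
    """
    common = expression.index.intersection(sgm_counts.index)
    if len(common) < 4:
        raise InputError("need at least 4 samples with expression and counts")
    expr = expression.loc[common]
    counts = sgm_counts.loc[common]
    med = float(expr.median())
    high = expr > med
    rows = []
    skip = expr.nunique() == 1 or high.sum() < min_per_group or (~high).sum() < min_per_group
    for cat in counts.columns:
        if skip:
            rows.append({"category": cat, "n_high": int(high.sum()), "n_low": int((~high).sum()), "p": np.nan})
            continue
        x = counts.loc[high, cat].to_numpy(dtype=float)
        y = counts.loc[~high, cat].to_numpy(dtype=float)
        p = float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)
        rows.append({"category": cat, "n_high": len(x), "n_low": len(y), "p": p})
    return pd.DataFrame(rows)


def smoking_burden(
    groups: pd.Series, counts: pd.DataFrame
) -> pd.DataFrame:
    """Pairwise rank-sum comparison of SGM burden across smoking categories.

    ``groups`` maps sample_id to a smoking-history category; ``counts`` holds
    one column per mutation-count category (e.g. SBS4 SGMs, Glu>Stop SGMs).
    All non-empty group pairs are compared with two-sided Wilcoxon rank-sum
    tests per count category, BH-adjusted across all pairs and categories.
    """
    common = groups.index.intersection(counts.index)
    g = groups.loc[common]
    c = counts.loc[common]
    levels = [lv for lv in pd.unique(g) if (g == lv).sum() > 0]
    rows = []
    for i, ga in enumerate(levels):
        for gb in levels[i + 1 :]:
            for cat in c.columns:
                x = c.loc[g == ga, cat].to_numpy(dtype=float)
                y = c.loc[g == gb, cat].to_numpy(dtype=float)
                if len(x) == 0 or len(y) == 0:
                    continue
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
                rows.append({"category": cat, "group_a": ga, "group_b": gb, "n_a": len(x), "n_b": len(y), "p": p})
    out = pd.DataFrame(rows, columns=["category", "group_a", "group_b", "n_a", "n_b", "p"])
    if not out.empty:
        out["fdr"] = bh_fdr(out["p"])
    return out


@dataclass
class KOTestResult:
    p: float
    method: str  # "negative_binomial" or "poisson"
    converged: bool


def ko_test(clones: pd.DataFrame, category: str) -> KOTestResult:
    """Two-model likelihood-ratio test for a knockout effect on SGM counts.

    Fits negative-binomial regressions (log link) of the per-clone counts in
    ``category`` with and without a treatment-group indicator (WT vs KO) and
    compares them with a chi-square LRT on 1 degree of freedom.  When the
    dispersion estimate collapses to the Poisson limit or the NB fit fails to
    converge, the equivalent Poisson LRT is used and reported as such.
    """
    if not {"group", category} <= set(clones.columns):
        raise InputError(f"clone table needs 'group' and {category!r} columns")
    y = clones[category].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise InputError("counts must be non-negative integers")
    groups = clones["group"].to_numpy()
    levels = np.unique(groups)
    if len(levels) != 2:
        raise InputError(f"need exactly 2 treatment groups, got {list(levels)}")
    if min((groups == lv).sum() for lv in levels) < 2:
        raise InputError("need at least 2 clones per group")
    if np.all(y == 0):
        raise InputError("all counts are zero; test degenerate")
    x_null = np.ones((len(y), 1))
    x_alt = np.column_stack([np.ones(len(y)), (groups == levels[1]).astype(float)])

    def _nb_llf(exog):
        model = sm.NegativeBinomial(y, exog, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=200)
        return res.llf, bool(res.mle_retvals.get("converged", True)), float(res.params[-1])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            llf0, conv0, alpha0 = _nb_llf(x_null)
            llf1, conv1, alpha1 = _nb_llf(x_alt)
        converged = conv0 and conv1
        poisson_limit = alpha0 < 1e-6 or alpha1 < 1e-6
        if converged and not poisson_limit and np.isfinite(llf0) and np.isfinite(llf1):
            lr = max(0.0, 2.0 * (llf1 - llf0))
            return KOTestResult(float(stats.chi2.sf(lr, df=1)), "negative_binomial", True)
    except Exception:
        pass
    # Poisson limit / non-convergence fallback
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res0 = sm.GLM(y, x_null, family=sm.families.Poisson()).fit()
        res1 = sm.GLM(y, x_alt, family=sm.families.Poisson()).fit()
    lr = max(0.0, 2.0 * (res1.llf - res0.llf))
    return KOTestResult(float(stats.chi2.sf(lr, df=1)), "poisson", True)
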