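"""Gene-level enrichment of signature-associated stop-gain mutations.

Identifies genes whose stop-gain mutations (SGMs) are attributed to a given
SBS signature more often than the exome-wide background, merges per-cohort
p values with Brown's method (Fisher's combination with an empirically
estimated covariance correction), and characterises the resulting gene sets:
overlap with known cancer genes, serine/glutamic-acid sequence content, and
the positional skew of truncations along the protein.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sgmsig import genetic_code as gc
from sgmsig.enrichment import bh_fdr, fisher_greater
from sgmsig.exceptions import InputError

_P_FLOOR = 1e-300


def gene_test(
    sgms: pd.DataFrame,
    gene_id: str,
    signature: str,
    mode: str = "sgm",
) -> float:
    """One-tailed Fisher p for signature-SGM enrichment in one gene.

    Default conditioning (``mode="sgm"``): among all exome-wide SGMs, test
    {in gene vs elsewhere} x {assigned to the signature vs not}, so the
    expected count is the gene's SGM count times the exome-wide signature
    fraction among SGMs.  The alternative conditioning (``mode="all"``)
    tests {in gene vs elsewhere} x {SGM vs other class} among the signature's
    exonic mutations.
    """
    if mode == "sgm":
        df = sgms[sgms["functional_class"] == "stop_gain"]
        in_gene = df["gene_id"] == gene_id
        is_sig = df["signature_label"] == signature
    elif mode == "all":
        df = sgms[sgms["signature_label"] == signature]
        in_gene = df["gene_id"] == gene_id
        is_sig = df["functional_class"] == "stop_gain"
    else:
        raise InputError(f"unknown gene_test mode {mode!r}")
    if len(df) == 0 or not (in_gene & is_sig).any():
        raise InputError(
            f"gene {gene_id} has no qualifying signature SGM; test not applicable"
        )
    a = int((in_gene & is_sig).sum())
    b = int(in_gene.sum()) - a
    c = int(is_sig.sum()) - a
    d = len(df) - a - b - c
    return fisher_greater(a, b, c, d)


def _fisher_method(p_values: np.ndarray) -> float:
    t = -2.0 * np.log(np.clip(p_values, _P_FLOOR, 1.0)).sum()
    return float(stats.chi2.sf(t, df=2 * len(p_values)))


def brown_combine(
    p_values: Sequence[float],
    p_matrix: pd.DataFrame | np.ndarray | None = None,
    min_complete: int = 20,
) -> float:
    """Merge per-cohort p values with the empirical Brown method.

    Fisher's statistic T = -2 sum(ln p) is referred to a scaled chi-square
    whose scale and degrees of freedom are derived from the empirical
    covariance of -2 ln p across genes tested in all contributing cohorts
    (``p_matrix``: one row per gene, one column per cohort, same column order
    as ``p_values``).  With a single cohort the input p is returned; with no
    usable covariance estimate (or fewer than ``min_complete`` complete rows)
    the method falls back to Fisher's combination.
    """
    p = np.asarray([float(x) for x in p_values], dtype=float)
    if p.size == 0:
        raise InputError("brown_combine needs at least one p value")
    if ((p < 0) | (p > 1)).any():
        raise InputError("p values must lie in [0, 1]")
    k = p.size
    if k == 1:
        return float(p[0])
    t = -2.0 * np.log(np.clip(p, _P_FLOOR, 1.0)).sum()

    cov_sum = 0.0
    if p_matrix is not None:
        mat = np.asarray(p_matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != k:
            raise InputError("p_matrix must have one column per combined p value")
        complete = mat[~np.isnan(mat).any(axis=1)]
        if complete.shape[0] < min_complete:
            warnings.warn(
                f"only {complete.shape[0]} genes tested in all cohorts; "
                "falling back to Fisher's method"
            )
        else:
            x = -2.0 * np.log(np.clip(complete, _P_FLOOR, 1.0))
            cov = np.cov(x, rowvar=False)
            iu = np.triu_indices(k, 1)
            cov_sum = float(cov[iu].sum())
    expected = 2.0 * k
    variance = 4.0 * k + 2.0 * cov_sum
    if variance <= 0 or cov_sum <= 0:
        return _fisher_method(p)
    c = variance / (2.0 * expected)
    df = 2.0 * expected**2 / variance
    return float(stats.chi2.sf(t / c, df=df))


def gene_enrichment_table(
    cohort_sgms: Mapping[str, pd.DataFrame],
    signature: str,
    mode: str = "sgm",
) -> pd.DataFrame:
    """Per-gene signature-SGM enrichment merged across cohorts.

    ``cohort_sgms`` maps cohort name to an annotated+labelled mutation table.
    A gene is tested in a cohort if it has at least one SGM assigned to the
    signature there.  Per-cohort p values are merged with the empirical Brown
    method (covariance estimated from genes tested in every cohort) and
    BH-adjusted across all merged genes.
    """
    cohort_names = list(cohort_sgms)
    per_cohort: dict[str, dict[str, float]] = {c: {} for c in cohort_names}
    n_sgms: dict[str, int] = {}
    positions: dict[str, list[int]] = {}
    for cname, df in cohort_sgms.items():
        sgm = df[df["functional_class"] == "stop_gain"]
        sig_sgm = sgm[sgm["signature_label"] == signature]
        for gid, sub in sig_sgm.groupby("gene_id"):
            per_cohort[cname][gid] = gene_test(df, gid, signature, mode=mode)
            n_sgms[gid] = n_sgms.get(gid, 0) + len(sub)
            positions.setdefault(gid, []).extend(
                int(x) for x in sub["protein_position"].dropna()
            )
    all_genes = sorted(n_sgms)
    pmat = pd.DataFrame(
        {c: [per_cohort[c].get(g, np.nan) for g in all_genes] for c in cohort_names},
        index=all_genes,
    )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gid in all_genes:
            avail = [c for c in cohort_names if not np.isnan(pmat.loc[gid, c])]
            ps = pmat.loc[gid, avail].to_numpy(dtype=float)
            brown_p = brown_combine(ps, pmat[avail].to_numpy())
            row = {
                "gene_id": gid,
                "signature": signature,
                "n_signature_sgms": n_sgms[gid],
                "brown_p": brown_p,
                "sgm_protein_positions": ",".join(map(str, sorted(positions[gid]))),
            }
            for c in cohort_names:
                row[f"p_{c}"] = pmat.loc[gid, c]
            rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr"] = bh_fdr(out["brown_p"])
        out = out.sort_values("brown_p").reset_index(drop=True)
    return out


def cgc_overlap(
    significant_genes: Iterable[str],
    known_cancer_genes: Iterable[str],
    background: Iterable[str],
) -> float:
    """One-tailed Fisher p for overlap of a gene list with known cancer genes."""
    bg = set(background)
    sig = set(significant_genes) & bg
    known = set(known_cancer_genes) & bg
    a = len(sig & known)
    b = len(sig - known)
    c = len(known - sig)
    d = len(bg) - a - b - c
    return fisher_greater(a, b, c, d)


def proteome_from_model(model) -> pd.DataFrame:
    """Residue-count table (one row per gene, one column per amino acid).

    Computed from the translated CDS of each gene, excluding the terminal
    stop codon; a ``length`` column holds the protein length.
    """
    aas = sorted(set(gc.CODON_TO_AA.values()) - {"*"})
    rows = []
    for gene in model.genes:
        protein = [gc.CODON_TO_AA[gene.cds[i : i + 3]] for i in range(0, len(gene.cds) - 3, 3)]
        counts = {aa: 0 for aa in aas}
        for aa in protein:
            counts[aa] += 1
        counts["gene_id"] = gene.gene_id
        counts["length"] = len(protein)
        rows.append(counts)
    return pd.DataFrame(rows).set_index("gene_id")


def residue_content_test(
    gene_set: Iterable[str], residue: str, proteome: pd.DataFrame
) -> float:
    """One-tailed Mann-Whitney p: is the gene set richer in ``residue``?

    Compares per-protein counts of the residue in ``gene_set`` against all
    other proteins of the proteome table, alternative = greater.
    """
    genes = set(gene_set)
    if not genes:
        raise InputError("gene set is empty")
    unknown = genes - set(proteome.index)
    if unknown:
        raise InputError(f"genes absent from proteome: {sorted(unknown)[:3]}")
    rest = proteome.index.difference(genes)
    if len(rest) == 0:
        raise InputError("gene set equals the whole proteome; no reference left")
    x = proteome.loc[sorted(genes), residue].to_numpy(dtype=float)
    y = proteome.loc[rest, residue].to_numpy(dtype=float)
    return float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)


def positional_skew(
    positions: Sequence[int], protein_length: int
) -> tuple[str, float]:
    """Direction and p value of truncation skew along the protein.

    Positions are normalised to (0, 1] and tested against the midpoint 0.5
    with one-sample Wilcoxon signed-rank tests, one-tailed in each direction;
    the smaller-p direction ('N' or 'C') is reported.  Positions exactly at
    the midpoint carry no information; if none remain, p = 1 by convention.
    """
    pos = np.asarray(list(positions), dtype=float)
    if pos.size == 0:
        raise InputError("need at least one position")
    if (pos < 1).any() or (pos > protein_length).any():
        raise InputError("positions must lie in [1, protein_length]")
    rel = pos / protein_length
    d = rel - 0.5
    if np.all(d == 0):
        return "N", 1.0
    p_n = float(stats.wilcoxon(d, alternative="less", zero_method="wilcox").pvalue)
    p_c = float(stats.wilcoxon(d, alternative="greater", zero_method="wilcox").pvalue)
    if p_n <= p_c:
        return "N", p_n
    return "C", p_c


def read_gene_list(path) -> set[str]:
    """Read a one-gene-per-line text file (e.g. a known-cancer-gene list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
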