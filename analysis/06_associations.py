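#!/usr/bin/env python
"""Molecular and clinical correlates of the stop-gain burden.

Four analyses on the simulated cohort: (i) co-occurrence of stop-gains in the
top enriched gene with copy-number losses of that gene (biallelic
inactivation); (ii) YTCA/RTCA motif composition of APOBEC stop-gains versus
other APOBEC mutations; (iii) stop-gain burden versus median-dichotomised
APOBEC3A expression; (iv) burden differences across smoking-history groups.
"""

from pathlib import Path

import pandas as pd

from sgmsig import annotate, associations, enrichment

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")
GENE = "G0007"


def main() -> None:
    labeled = pd.read_csv(SCRATCH / "labeled.tsv", sep="\t", dtype={"chrom": str})
    clinical = pd.read_csv(SCRATCH / "clinical.tsv", sep="\t")
    cn = pd.read_csv(SCRATCH / "cn_segments.tsv", sep="\t", dtype={"chrom": str})
    expression = pd.read_csv(SCRATCH / "expression.tsv", sep="\t", index_col="sample_id")
    model = annotate.build_coding_model(SCRATCH / "genome.fa", SCRATCH / "gene_model.tsv")

    # (i) SGM / CN-loss co-occurrence in the spiked driver
    gene = model.by_id[GENE]
    sgm_samples = set(
        labeled[(labeled.gene_id == GENE) & (labeled.functional_class == "stop_gain")][
            "sample_id"
        ]
    )
    calls = associations.loss_calls_for_gene(
        cn, gene.chrom, int(gene.positions.min()), int(gene.positions.max()), clinical
    )
    loss_samples = set(calls.loc[calls.loss, "sample_id"])
    k, n, frac = associations.cooccurrence(sgm_samples, loss_samples)
    print(f"{GENE}: {k} of {n} SGM-carrying samples also lose the gene ({100*frac:.1f}%)")

    # (ii) motif composition of APOBEC stop-gains
    sbs13 = labeled[labeled.signature_label == "SBS13"]
    sgm = sbs13[sbs13.functional_class == "stop_gain"]
    non = sbs13[sbs13.functional_class != "stop_gain"]
    motif = associations.motif_test(sgm, non)
    motif.round(6).to_csv(RESULTS / "06_motif.tsv", sep="\t", index=False)
    y = motif.set_index("motif").loc["YTCA"]
    print(f"YTCA motif: {100*y.sgm_fraction:.1f}% of SBS13 SGMs vs "
          f"{100*y.non_sgm_fraction:.1f}% of non-SGMs (p={y.p:.3g})")

    # (iii) expression association (APOBEC3A-linked in the simulation)
    counts = (
        sgm.groupby("sample_id").size()
        .reindex(expression.index)
        .fillna(0)
        .to_frame("sbs13_sgms")
    )
    rows = []
    for g in expression.columns:
        res = associations.expression_association(expression[g], counts)
        res["gene"] = g
        rows.append(res)
    expr_res = pd.concat(rows, ignore_index=True)
    expr_res["fdr"] = enrichment.bh_fdr(expr_res["p"].fillna(1.0))
    expr_res.round(6).to_csv(RESULTS / "06_expression.tsv", sep="\t", index=False)
    for row in expr_res.itertuples(index=False):
        print(f"high vs low {row.gene}: SBS13 SGM burden one-tailed p={row.p:.3g}")

    # (iv) smoking-history burden comparison (burden-linked in the simulation)
    total = labeled.groupby("sample_id").size()
    groups = clinical.set_index("sample_id")["smoking_category"]
    burden = associations.smoking_burden(groups, total.to_frame("snvs"))
    burden.round(6).to_csv(RESULTS / "06_smoking.tsv", sep="\t", index=False)
    sig = burden[burden.fdr < 0.05]
    print(f"smoking-history comparisons: {len(sig)} of {len(burden)} pairs at FDR<0.05")


if __name__ == "__main__":
    main()
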