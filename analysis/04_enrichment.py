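#!/usr/bin/env python
"""Which signatures are enriched in stop-gain mutations, and in which residues?

Runs the signature x functional-class Fisher tests with BH FDR and binomial
expected counts, the per-amino-acid enrichment among stop-gains for the
APOBEC-like signature, and a short multinomial-sampling replication that
re-draws per-SNV labels from the full exposure posterior.
"""

from pathlib import Path

import pandas as pd

from sgmsig import enrichment, signatures

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")
SEED = 2026


def main() -> None:
    labeled = pd.read_csv(SCRATCH / "labeled.tsv", sep="\t", dtype={"chrom": str})
    config = enrichment.CohortConfig()

    res = enrichment.class_signature_tests(labeled, config, seed=SEED)
    res.round(6).to_csv(RESULTS / "04_sgm_enrichment.tsv", sep="\t", index=False)
    sgm = res[res.target == "stop_gain"].sort_values("p")
    print("signature x stop-gain enrichment:")
    for row in sgm.itertuples(index=False):
        flag = "*" if row.fdr < config.fdr_threshold else " "
        print(f" {flag} {row.signature:6s} observed={row.observed:4d} "
              f"expected={row.expected_mean:7.1f} FC={row.fold_change:5.2f} FDR={row.fdr:.2e}")

    aa = enrichment.amino_acid_tests(
        labeled[labeled.functional_class == "stop_gain"], "SBS13"
    )
    aa.round(6).to_csv(RESULTS / "04_amino_acid_enrichment.tsv", sep="\t", index=False)
    top = aa.sort_values("p").head(3)
    print("\ntop amino acids among SBS13 stop-gains:")
    for row in top.itertuples(index=False):
        print(f"   {row.target}: {100*row.frac_signature:.1f}% of SBS13 SGMs vs "
              f"{100*row.frac_other:.1f}% in other signatures (FDR={row.fdr:.2e})")

    catalog = signatures.read_catalog(SCRATCH / "catalog.tsv")
    exposures = signatures.fit_cohort_exposures(labeled, catalog)
    rep = enrichment.probabilistic_replication(
        labeled, exposures, catalog, config, seed=SEED, iterations=10
    )
    rep.round(6).to_csv(RESULTS / "04_probabilistic.tsv", sep="\t", index=False)
    if not rep.empty:
        frac = rep[rep.signature == "SBS13"].groupby("iteration")["significant"].any().mean()
        print(f"\nSBS13 stop-gain enrichment significant in {100*frac:.0f}% of "
              f"{rep['iteration'].nunique()} probabilistic label draws")


if __name__ == "__main__":
    main()
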