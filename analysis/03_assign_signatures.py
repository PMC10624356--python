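#!/usr/bin/env python
"""Refit per-sample signature exposures and label each SNV.

Exposures come from non-negative least squares against the catalog with
iterative pruning of <1% signatures; each SNV is then assigned its most
probable signature given the sample's exposures. Because the cohort is
synthetic, the fitted exposures can be compared against the true Dirichlet
draws — the per-signature mean absolute error is the key quality metric.
"""

from pathlib import Path

import pandas as pd

from sgmsig import annotate, signatures

SCRATCH = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    catalog = signatures.read_catalog(SCRATCH / "catalog.tsv")
    annotated = pd.read_csv(SCRATCH / "annotated.tsv", sep="\t", dtype={"chrom": str})
    exposures = signatures.fit_cohort_exposures(annotated, catalog)
    labeled = signatures.assign_top_table(annotated, exposures, catalog)

    truth = annotated.merge(
        pd.read_csv(SCRATCH / "ground_truth.tsv", sep="\t", dtype={"chrom": str}),
        on=["sample_id", "chrom", "pos", "ref", "alt"],
    )
    labeled["true_signature"] = truth["true_signature"]
    labeled.to_csv(SCRATCH / "labeled.tsv", sep="\t", index=False)

    true_expo = pd.read_csv(SCRATCH / "exposures_true.tsv", sep="\t").set_index("sample_id")
    fitted = pd.DataFrame(
        {s: ev.weights for s, ev in exposures.items()}
    ).T.reindex(true_expo.index).fillna(0.0)
    mae = (fitted.reindex(columns=true_expo.columns).fillna(0.0) - true_expo).abs().mean()
    mae.round(4).to_frame("mean_abs_error").to_csv(
        RESULTS / "03_exposure_recovery.tsv", sep="\t"
    )

    agree = (labeled["signature_label"] == labeled["true_signature"]).mean()
    print(f"fitted exposures for {len(exposures)} samples; "
          f"exposure MAE per signature:\n{mae.round(3).to_string()}")
    print(f"top-assignment agrees with the generating signature for {100*agree:.1f}% of SNVs")
    print(f"labeled table -> {SCRATCH}/labeled.tsv")


if __name__ == "__main__":
    main()
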