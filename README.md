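# sgmsig — stop-gain mutations and SBS mutational signatures

Somatic mutational processes leave trinucleotide-context fingerprints in
cancer genomes — the single-base-substitution (SBS) signatures. Because the
genetic code reaches its stop codons (TAA, TAG, TGA) from only a few sense
codons, processes with the right context preferences — tobacco smoking
(SBS4-like C>A), APOBEC cytidine deaminases (SBS13-like C>G/C>A at TCN), and
reactive oxygen species (SBS18-like C>A) — disproportionately convert serine
and glutamic-acid codons into stop codons, producing protein-truncating
stop-gain mutations (SGMs) far more often than expected by chance.

`sgmsig` is a toolkit for quantifying this effect. It is written for cancer
genomics researchers who have a MAF-like somatic SNV table, a reference
genome with a coding model, and a 96-channel signature catalog, and want to
ask: *which mutational processes are generating the truncating mutations in
this cohort, in which genes, and with which molecular and clinical
correlates?* Because the real pan-cancer inputs are access-controlled, the
package also ships a full synthetic-study generator with ground truth, so
every analysis is exercisable (and statistically testable) end to end.

## The model

Mutations are described by their **trinucleotide channel**: the substituted
base with its 5′ and 3′ neighbours, reverse-complemented so the reference
base is a pyrimidine — 96 channels in total, ordered as in the COSMIC
catalogs. A signature *s* is a probability profile *p_s* over channels; a
sample's mutation spectrum is modelled as a non-negative mixture
Σ_s w_s·p_s, with exposures *w* refit per sample by non-negative least
squares and <1% pruning. Each SNV is assigned the signature maximising
w_s·p_s(channel), or sampled from that posterior in the probabilistic
replication mode.

Enrichment of a signature in a functional class (stop-gain, missense,
silent, start-loss, stop-loss) is tested with a one-tailed Fisher's exact
test on the 2×2 table {signature vs not} × {class vs not} over the cohort's
exonic SNVs, with Benjamini–Hochberg FDR per analysis family and expected
counts (±95% CI) from 10,000 binomial draws under the product of the
marginal frequencies. Gene-level driver tests condition on SGMs
({in gene vs exome-wide} × {signature vs not}), are merged across cohorts
with Brown's method (Fisher's combination with empirically estimated
covariance of −2·ln p across genes), and are FDR-adjusted. The mechanism
itself is modelled directly: for any signature profile and coding model,
`signature_stop_distribution` enumerates every codon→stop substitution path
and returns the induced distribution over truncated amino acids.

## Worked example

The codon-level machinery is self-contained:

```python
>>> from sgmsig import genetic_code as gc
>>> gc.stop_paths("TCA")
[StopPath(codon='TCA', position=2, ref_base='C', alt_base='A', stop_codon='TAA'),
 StopPath(codon='TCA', position=2, ref_base='C', alt_base='G', stop_codon='TGA')]
```

i.e. the serine codon TCA becomes a stop codon through exactly the middle-C
transversions characteristic of APOBEC mutagenesis. Feeding an APOBEC-like
profile concentrated on T[C>G]A, T[C>A]A and T[C>A]G to a simulated coding
model shows where its truncations land:

```python
>>> from sgmsig import simdata
>>> model, _ = simdata.simulate_coding_model(simdata.SimConfig(seed=1, n_genes=10))
>>> gc.signature_stop_distribution(
...     {"T[C>G]A": 0.5, "T[C>A]A": 0.3, "T[C>A]G": 0.2}, model, three_letter=True)
{'Ser': 0.808, 'Glu': 0.192}
```

— 81% of the stop-gains this process can generate replace serines, the rest
glutamic acids (reached by C>A substitutions spanning two adjacent codons on
the opposite strand).

The full pipeline is a chain of numbered drivers over the same library:

```bash
python analysis/01_simulate.py        # synthetic 150-sample cohort + spiked driver
python analysis/02_annotate.py        # functional classes, channels, motifs
python analysis/03_assign_signatures.py
python analysis/04_enrichment.py      # signature x class and amino-acid tests
python analysis/05_gene_drivers.py    # per-gene tests, Brown merge, gene-set checks
python analysis/06_associations.py    # CN loss, YTCA motif, expression, smoking
```

On the default cohort (seed 2026), the chain prints, among other things:

```
annotated 16511 SNVs across 60 genes
  missense      11457  (69.39%)
  silent         3845  (23.29%)
  stop_gain       942  (5.71%)
...
 * SBS13  observed= 112 expected=   56.0 FC= 2.00 FDR=6.53e-12
...
   S: 73.2% of SBS13 SGMs vs 17.8% in other signatures (FDR=8.13e-31)
...
1 genes at FDR<0.05; spiked driver recovered: True (overlap p=0.0167)
YTCA motif: 46.4% of SBS13 SGMs vs 17.4% of non-SGMs (p=5.7e-11)
high vs low APOBEC3A: SBS13 SGM burden one-tailed p=4.09e-05
```

Read: the APOBEC-like signature carries twice the stop-gains expected under
independence; those stop-gains hit serines at 4× the rate of other
signatures' stop-gains; the gene spiked with 20 selection-like truncations is
the one gene recovered at FDR < 0.05; and the APOBEC stop-gains concentrate
in YTCA motifs and track APOBEC3A expression — each the synthetic analogue
of a finding the statistics are designed to detect. Tables land in
`results/`, intermediate data in `scratch/`. The same stages are available
as a CLI (`sgmsig simulate|annotate|assign|enrich|genes|associations|report`),
each writing a manifest with its inputs, seed and config hash.

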