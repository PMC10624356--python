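# Methods

This note documents the models, conventions, parameter choices and known
limitations of `sgmsig`, in the order the pipeline runs.

## Channels, codons, and the stop-gain mechanism

All substitutions are represented on the 96-channel trinucleotide grid with
pyrimidine reference bases: a purine-reference substitution is
reverse-complemented (flanks swap and complement) before lookup, so a
mutation and its opposite-strand description always map to the same channel.
Channel order follows the COSMIC convention (C>A, C>G, C>T, T>A, T>C, T>G;
within each substitution, 5′ A,C,G,T × 3′ A,C,G,T).

`genetic_code` enumerates, for every sense codon of the standard genetic
code (translation table 1 only), the single-base substitutions that yield
TAA, TAG or TGA. Paths are ordered deterministically by (codon position,
alt base). `signature_stop_distribution` converts a signature profile into a
distribution over truncated amino acids by summing profile mass over every
stop-inducing substitution at every CDS position of a coding model. Two
conventions matter here:

- **Context comes from the genome, not the codon.** The 5′/3′ flanks of a
  substitution are its genomic neighbours, which may belong to the adjacent
  codon (this is precisely how glutamic-acid truncations arise: the C>A
  channel spans the last base of one codon and the first two of the GAA/GAG
  codon on the opposite strand) or, at a splice junction, to the intron.
- **CDS positions are weighted uniformly.** The distribution conditions on a
  stop-gain having occurred and does not weight genes by expression or
  per-gene mutation rate; it answers "given this process causes a
  truncation somewhere in this coding model, which residue does it remove?"

## Annotation

A coding model is one canonical transcript per gene (isoform choice is the
caller's): 1-based inclusive genomic CDS intervals, strand, and the spliced
coding sequence, validated as an ORF (ATG start, terminal stop, no internal
stop; violations are errors by default and warnings with `strict=False` for
real annotation sets). Functional classes are assigned by translating the
mutated codon, with precedence: stop_loss and stop_gain are determined
purely by the amino acids (so an ATG→TAG first-codon change is a
stop-gain), then any other non-synonymous change in codon 1 is a
start-loss, then silent/missense. An SNV covered by several genes is
annotated per gene, and tables deduplicate to the alphabetically first
gene — an arbitrary but deterministic rule.

The APOBEC quadnucleotide motif is read at positions (−2,−1,0,+1) on the
strand where the mutated base is C: [CT]TCA → YTCA (APOBEC3A-like),
[AG]TCA → RTCA (APOBEC3B-like), anything else → other. Substitutions whose
pyrimidine-normalised reference is T are classed "other" (the motif is
meaningful only for C-reference mutations); missing flanks give
not_applicable, and such SNVs are excluded from signature-conditional
analyses but retained in totals.

## Exposure refitting and assignment

Per-sample exposures are refit by non-negative least squares of the
normalised 96-channel spectrum on the catalog, iteratively dropping
signatures below 1% weight and refitting until stable, then renormalising.
This is a deliberately simple refitting scheme: the downstream analyses
consume only per-SNV labels, and on the shipped catalog (all pairwise
cosines < 0.5) it recovers Dirichlet-drawn exposures with mean absolute
error ≈ 0.005 at 10,000 SNVs/sample (asserted at < 0.05 in the tests).
Per-SNV assignment takes argmax over w_s·p_s(channel) with alphabetical
tie-breaking; when every exposed signature has zero mass on the channel the
SNV is `unassigned`. The probabilistic mode draws labels from the
normalised posterior instead; iteration *i* of a replication uses the child
seed `(master*100003 + i) mod 2^31`, a fixed arithmetic so runs are
bit-reproducible. Related COSMIC labels are merged for analysis
(SBS5/SBS40→SBS5/40, SBS7a–d→SBS7, SBS10a/b→SBS10, SBS17a/b→SBS17); the
artifact set used by QC defaults to {SBS27, SBS43, SBS45..SBS60}.

## Enrichment statistics

Cohort QC applies, in order: hypermutator removal (>90,000 SNVs for WGS,
>1,800 for WES, ≈30 SNVs/Mbp), low-confidence WES removal (<20 SNVs),
removal of WGS samples with >20% of SNVs on artifact signatures,
per-patient deduplication keeping the highest-purity sample, and dropping
cancer types with <25 samples. Every removal is logged with its rule.

Signature×class tests use one-tailed (enrichment) Fisher's exact tests on
exonic SNVs only; a signature is eligible with ≥100 SNVs in the analysis
family and each test requires ≥1 SNV of the class carrying the signature.
The FDR family is all signature×class tests of one cohort×cancer-type
analysis (a per-analysis family matches how results are reported per cancer
type; pan-cancer pooling re-adjusts within the pooled family). Expected
counts use 10,000 Binomial(n, p_sig·p_class) draws with empirical marginal
frequencies, reporting the mean and the 2.5/97.5 percentiles. Amino-acid
enrichment conditions on stop-gains and compares, per reference residue,
the signature's SGMs against all other signatures' SGMs; the reported fold
change is the ratio of the two residue fractions. Depletion testing is out
of scope — the one-tailed direction is always enrichment.

## Gene-level driver analysis

The default gene test conditions on SGMs: {SGMs in gene vs exome-wide} ×
{assigned to the signature vs not}, so the expected count is the gene's SGM
count times the exome-wide signature fraction among SGMs. The alternative
conditioning (among the signature's mutations, {in gene} × {SGM vs other
class}) is available via `mode="all"`; the SGM conditioning is the default
because it reproduces the observed/expected logic of the per-gene counts
the enrichment analysis reports. Genes are tested only with ≥1
signature-assigned SGM.

Per-cohort p values are merged with the empirical Brown method: Fisher's
statistic referred to a scaled χ² whose scale/df derive from the covariance
of −2·ln p across genes tested in every contributing cohort. With one
cohort the p value passes through; with <20 complete genes, or a
non-positive covariance estimate, the method falls back to Fisher's
combination (logged). p values are floored at 1e-300 before logs.
Positional skew normalises truncation positions to (0,1] and runs one-sample
Wilcoxon signed-rank tests against 0.5 in both directions (midpoint
positions dropped per the standard zero-handling; all-midpoint input
returns p = 1 by convention), reporting the smaller-p direction. Residue
content uses one-tailed Mann–Whitney U on per-protein residue counts versus
the rest of the proteome.

## Copy-number, motif, expression, smoking and knockout associations

WGD is called when the segment-length-weighted mean CN exceeds 2.5. Gene CN
is the minimum CN among overlapping segments ≥1000 bp; no qualifying
segment means "no CNA data", which is treated as no loss. Loss thresholds:
TCGA-style relative calls, CN < 0.0; WGS autosomes and female X, CN < 1.5
(non-WGD) / < 2.0 (WGD); male X, CN < 1.0 / < 1.5. Samples on X without a
sex annotation use the autosome rule with a warning.

Expression association median-dichotomises one gene's expression (ties to
the low group — a deterministic rule; the choice matters only with heavily
tied expression values) and applies one-tailed Wilcoxon rank-sum tests of
SGM counts, including zero-count samples; constant expression or groups
below 2 samples skip the test (NaN). Smoking-history comparisons are
two-sided rank-sum tests over all category pairs, BH-adjusted jointly
across pairs and count categories. The knockout test is a two-model
likelihood-ratio χ² (df 1) between intercept-only and group-indicator
negative-binomial regressions (NB2, log link, dispersion estimated by MLE
per fit); if the dispersion collapses toward the Poisson limit or the NB
fit fails to converge, the equivalent Poisson LRT is used and the result is
flagged with `method="poisson"`.

## The synthetic-study generator

`simdata` generates everything the pipeline reads. Design points:

- **Sequence-constrained placement.** Each SNV first draws its generating
  signature from the sample's exposures, then a channel from that
  signature's profile, then a genomic position uniformly among positions
  whose pyrimidine-normalised context matches the channel (gene bodies plus
  a 5 bp flank; no position is mutated twice per sample). Annotation, motif
  and genetic-code analyses therefore run against real sequence
  constraints rather than detached channel draws. The no-repeat rule means
  spectra are faithful only while the burden is small relative to the
  per-channel site inventory; simulations here keep the genome large
  relative to the burden.
- **Catalog.** Five synthetic profiles shaped after the relevant processes
  (broad C>A with 5′-C/T preference; C>G+C>A at TCN peaking at T[C>G]A;
  C>T at TCN; C>A concentrated at G/T/A-flanked contexts; flat). They use
  the COSMIC names of the processes they mimic for readability but are
  synthetic constructions, chosen so all pairwise cosines stay below 0.5
  and exposure refitting is well-posed.
- **Defaults as study conditions.** Dirichlet(1,…,1) exposures, log-normal
  burden with median 200 exonic SNVs/sample, uniform codon usage, 40%
  minus-strand genes. The analysis chain and the driver-recovery tests use
  a variant with a dominant flat clock-like process and a minor APOBEC
  component, so that the APOBEC share of stop-gains is ≈10% — the regime
  in which gene-level driver detection is the interesting question.
- **Driver spikes model selection on process-generated mutations.** Spiked
  SGMs are placed at stop-reachable sites of the target gene compatible
  with the signature (sites drawn proportionally to profile mass), in
  distinct samples drawn proportionally to the samples' true exposure of
  that signature — positive selection retains mutations the active process
  actually generated, and without this coupling a large share of spiked
  SGMs would be attributed to other signatures.
- **Covariate links.** Expression of the designated gene (APOBEC3A by
  default) increases with the sample's true APOBEC-like mutation load;
  smoking category couples to the tobacco-like load; CN losses are focal
  over genes at a configurable rate with a configurable WGD fraction.
  Everything derives from the single config seed; identical configs give
  byte-identical outputs.

What passing tests on these cohorts do **not** show: robustness to
replication-timing/chromatin covariates of mutation rate, subclonal
structure, isoform ambiguity, indels/MNVs, or real signature catalogs with
near-collinear members (flat SBS5 vs SBS40 refitting is genuinely hard and
is the reason those labels are merged for analysis).

## Problem sizes

Simulation-based checks run at deliberately modest scale, chosen to make
their statistical assertions decisive while keeping the suite quick: null
calibration uses 200 cohorts of 2,000 SNVs; mechanism recovery one
60-sample cohort at ~300 SNVs/sample; driver recovery 20 replicates of two
150-sample cohorts (20 spiked SGMs against an ≈10% background signature
fraction); exposure recovery 20 samples at 10,000 SNVs. The exhaustive
Fisher check covers every 2×2 table with total ≤ 60.

## Known limitations

- One transcript per gene; overlapping-gene deduplication is alphabetical.
- The refitting stand-in is not a re-implementation of single-sample
  SigProfiler; per-SNV labels, not exposure point estimates, are the
  supported output.
- Brown merging needs a reasonable panel of genes tested in all cohorts for
  a stable covariance estimate; below 20 it degrades (intentionally) to
  Fisher's method, which is anti-conservative under positive dependence.
- The generator's intergenic sequence is i.i.d. uniform; context frequencies
  of real genomes (e.g. CpG depletion) are not reproduced, so absolute
  channel-site inventories differ from real exomes.
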