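"""Synthetic study generator with ground truth.

Produces every input the pipeline consumes — a genome FASTA with embedded
ORFs, a gene-model table, a signature catalog, a mutation table, CN segments,
expression, and clinical covariates — under a generative model that mirrors
the assumed structure of real cohorts: per-sample signature exposures drawn
from a Dirichlet prior, per-SNV channels drawn from the generating signature's
profile, and mutations placed at genomic positions whose pyrimidine-normalised
trinucleotide context matches the drawn channel, so that annotation, motif,
and genetic-code analyses run against real sequence constraints.

The shipped catalog holds five synthetic profiles shaped after the processes
the analyses target (tobacco-smoking-like C>A, two APOBEC-like TCN profiles,
a ROS-like C>A profile, and a flat clock-like control), under the COSMIC
names of those processes for readability; they are synthetic, not COSMIC data.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sgmsig import genetic_code as gc
from sgmsig.annotate import CodingModel, Gene, build_gene
from sgmsig.exceptions import InputError
from sgmsig.signatures import SignatureCatalog

SMOKING_CATEGORIES = ("never", "reformed_long", "reformed_recent", "current")


def _profile_from_weights(weights: Mapping[str, float]) -> pd.Series:
    s = pd.Series(0.0, index=list(gc.COSMIC_CHANNELS))
    for ch, w in weights.items():
        s[ch] = w
    return s / s.sum()


def default_catalog() -> SignatureCatalog:
    """Five synthetic signature profiles shaped after known processes.

    - SBS4: broad C>A with 5'-C/T preference (tobacco-smoking-like)
    - SBS13: C>G and C>A at TCN, strongest at T[C>G]A (APOBEC-like)
    - SBS2: C>T at TCN (the companion APOBEC profile)
    - SBS18: C>A concentrated at G/T/A[C>A]A|T contexts (ROS-like)
    - SBS5: flat over all 96 channels (clock-like control)
    """
    bases = gc.BASES
    sbs4 = {}
    five_w = {"A": 0.8, "C": 1.4, "G": 0.4, "T": 1.2}
    three_w = {"A": 1.2, "C": 1.0, "G": 0.5, "T": 0.8}
    for f in bases:
        for t in bases:
            sbs4[f"{f}[C>A]{t}"] = 0.85 * five_w[f] * three_w[t]
            sbs4[f"{f}[C>G]{t}"] = 0.08 * five_w[f] * three_w[t]
            sbs4[f"{f}[T>A]{t}"] = 0.07

    sbs13 = {}
    three_13 = {"A": 0.40, "C": 0.12, "G": 0.18, "T": 0.30}
    for t in bases:
        sbs13[f"T[C>G]{t}"] = 0.62 * three_13[t]
        sbs13[f"T[C>A]{t}"] = 0.30 * three_13[t]
        sbs13[f"T[C>T]{t}"] = 0.08 * three_13[t]

    sbs2 = {}
    for t in bases:
        sbs2[f"T[C>T]{t}"] = {"A": 0.35, "C": 0.15, "G": 0.20, "T": 0.30}[t]

    sbs18 = {}
    for f, t, w in [
        ("G", "A", 0.28), ("T", "T", 0.20), ("G", "T", 0.16),
        ("A", "A", 0.14), ("A", "T", 0.10), ("T", "A", 0.12),
    ]:
        sbs18[f"{f}[C>A]{t}"] = w

    flat = {ch: 1.0 for ch in gc.COSMIC_CHANNELS}

    profiles = pd.DataFrame(
        {
            "SBS2": _profile_from_weights(sbs2),
            "SBS4": _profile_from_weights(sbs4),
            "SBS5": _profile_from_weights(flat),
            "SBS13": _profile_from_weights(sbs13),
            "SBS18": _profile_from_weights(sbs18),
        }
    )
    return SignatureCatalog(profiles)


@dataclass
class SimConfig:
    """Full specification of one synthetic study; the seed is mandatory.

    Gene lengths (codons) follow a log-normal law; per-sample exposures a
    Dirichlet over the catalog signatures; per-sample exonic SNV burden a
    log-normal.  ``driver_spikes`` lists (gene_id, signature, n_sgms) to add
    as positively selected truncations.
    """

    seed: int
    n_genes: int = 60
    mean_codons: float = 300.0
    sigma_codons: float = 0.35
    min_codons: int = 60
    intergenic: int = 100
    flank: int = 5
    codon_usage: str = "uniform"
    minus_strand_fraction: float = 0.4
    n_samples: int = 50
    exposure_alpha: dict[str, float] = field(
        default_factory=lambda: {"SBS2": 1.0, "SBS4": 1.0, "SBS5": 1.0, "SBS13": 1.0, "SBS18": 1.0}
    )
    burden_mu: float = float(np.log(200.0))
    burden_sigma: float = 0.4
    min_burden: int = 20
    driver_spikes: tuple[tuple[str, str, int], ...] = ()
    cn_loss_rate: float = 0.05
    wgd_fraction: float = 0.2
    baseline_cn: float = 2.0
    loss_cn: float = 1.0
    expression_link: float = 0.0
    expression_link_gene: str = "APOBEC3A"
    expression_link_signature: str = "SBS13"
    smoking_link: float = 0.0
    smoking_link_signature: str = "SBS4"
    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise InputError("n_genes and n_samples must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["driver_spikes"] = [list(t) for t in self.driver_spikes]
        return json.dumps(d, indent=2, sort_keys=True)


def simulate_coding_model(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[CodingModel, dict[str, str]]:
    """Random ORFs (ATG ... stop, no internal stops) in intergenic sequence.

    Codon usage is uniform over the 61 sense codons by default; a mapping
    codon->weight can be supplied via ``config.codon_usage`` to control e.g.
    Ser/Glu content.  Gene order, strand, and sequence are fully determined
    by the config seed.
    """
    rng = rng or np.random.default_rng(config.seed)
    if config.codon_usage == "uniform":
        codons = list(gc.SENSE_CODONS)
        weights = np.ones(len(codons))
    else:
        usage = dict(config.codon_usage)
        codons = sorted(usage)
        if set(codons) - set(gc.SENSE_CODONS):
            raise InputError("codon_usage contains stop or invalid codons")
        weights = np.array([usage[c] for c in codons], dtype=float)
    weights = weights / weights.sum()
    stop_codons = sorted(gc.STOP_CODONS)

    parts: list[str] = []
    rows = []
    cursor = 0
    for gi in range(config.n_genes):
        inter = "".join(rng.choice(list(gc.BASES), size=config.intergenic))
        parts.append(inter)
        cursor += len(inter)
        n_codons = max(config.min_codons, int(rng.lognormal(np.log(config.mean_codons), config.sigma_codons)))
        body = "".join(rng.choice(codons, size=n_codons, p=weights))
        cds = "ATG" + body + stop_codons[rng.integers(len(stop_codons))]
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        genomic = cds if strand == "+" else gc.reverse_complement(cds)
        start = cursor + 1
        parts.append(genomic)
        cursor += len(genomic)
        rows.append(
            {
                "gene_id": f"G{gi + 1:04d}",
                "chrom": "chr1",
                "strand": strand,
                "cds_starts": str(start),
                "cds_ends": str(cursor),
            }
        )
    parts.append("".join(rng.choice(list(gc.BASES), size=config.intergenic)))
    genome = {"chr1": "".join(parts)}
    genes = [
        build_gene(
            r["gene_id"], r["chrom"], r["strand"],
            [(int(r["cds_starts"]), int(r["cds_ends"]))], genome,
        )
        for r in rows
    ]
    model = CodingModel(genes)
    model.gene_table = pd.DataFrame(rows)
    return model, genome


class ChannelSiteIndex:
    """Maps each of the 96 channels to its matching genomic sites.

    A site matches a channel when its pyrimidine-normalised trinucleotide
    context equals the channel context; the stored alt base is on the genomic
    plus strand.  Sites are restricted to gene bodies plus a flank.
    """

    def __init__(self, genome: Mapping[str, str], model: CodingModel, flank: int = 5):
        regions: dict[str, set[int]] = {}
        for gene in model.genes:
            lo = int(gene.positions.min()) - flank
            hi = int(gene.positions.max()) + flank
            regions.setdefault(gene.chrom, set()).update(range(max(2, lo), hi + 1))
        sites: dict[str, list[tuple[str, int, str]]] = {ch: [] for ch in gc.COSMIC_CHANNELS}
        for chrom, positions in regions.items():
            seq = genome[chrom]
            for pos in sorted(positions):
                if pos >= len(seq):  # need a 3' flank
                    continue
                ref = seq[pos - 1]
                five, three = seq[pos - 2], seq[pos]
                for alt in gc.BASES:
                    if alt == ref:
                        continue
                    label = gc.channel_label(five, ref, alt, three)
                    sites[label].append((chrom, pos, alt))
        self.sites = {ch: lst for ch, lst in sites.items() if lst}

    def draw(self, channel: str, rng: np.random.Generator) -> tuple[str, int, str] | None:
        lst = self.sites.get(channel)
        if not lst:
            return None
        return lst[rng.integers(len(lst))]


def simulate_cohort(
    model: CodingModel,
    genome: Mapping[str, str],
    config: SimConfig,
    catalog: SignatureCatalog | None = None,
    rng: np.random.Generator | None = None,
    site_index: ChannelSiteIndex | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of signature-driven SNVs with ground truth.

    Returns (mutations, exposures): the mutation table carries the true
    generating signature per SNV in a ``true_signature`` column; the exposure
    table the true per-sample Dirichlet draws.  No position is mutated twice
    in the same sample.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    catalog = catalog or default_catalog()
    sigs = [s for s in catalog.names if s in config.exposure_alpha]
    if not sigs:
        raise InputError("exposure_alpha shares no signatures with the catalog")
    alpha = np.array([config.exposure_alpha[s] for s in sigs], dtype=float)
    index = site_index or ChannelSiteIndex(genome, model, flank=config.flank)

    profiles = {s: catalog.profile(s) for s in sigs}
    channel_arr = np.array(gc.COSMIC_CHANNELS)
    mut_rows = []
    exp_rows = []
    warned: set[str] = set()
    for si in range(config.n_samples):
        sample = f"S{si + 1:04d}"
        expo = rng.dirichlet(alpha)
        exp_rows.append({"sample_id": sample, **dict(zip(sigs, expo.tolist()))})
        burden = max(config.min_burden, int(rng.lognormal(config.burden_mu, config.burden_sigma)))
        sig_draws = rng.choice(len(sigs), size=burden, p=expo)
        used: set[tuple[str, int]] = set()
        for sd in sig_draws:
            sig = sigs[sd]
            for _ in range(200):  # resample channel/site on collision or no match
                ch = channel_arr[rng.choice(96, p=profiles[sig])]
                hit = index.draw(ch, rng)
                if hit is None:
                    if ch not in warned:
                        warnings.warn(f"channel {ch} has no matching genomic site; resampling")
                        warned.add(ch)
                    continue
                chrom, pos, alt = hit
                if (chrom, pos) in used:
                    continue
                used.add((chrom, pos))
                mut_rows.append(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "pos": pos,
                        "ref": genome[chrom][pos - 1],
                        "alt": alt,
                        "true_signature": sig,
                    }
                )
                break
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "true_signature"])
    exposures = pd.DataFrame(exp_rows)
    return mutations, exposures


def spike_driver_sgms(
    mutations: pd.DataFrame,
    model: CodingModel,
    genome: Mapping[str, str],
    gene_id: str,
    signature: str,
    n_sgms: int,
    catalog: SignatureCatalog | None = None,
    rng: np.random.Generator | None = None,
    min_profile_mass: float = 1e-4,
    sample_weights: pd.Series | None = None,
) -> pd.DataFrame:
    """Add positively selected stop-gain mutations to one gene.

    ``n_sgms`` SGMs are placed at stop-reachable sites of the gene whose
    channel carries non-negligible mass under the signature profile (sites
    drawn proportionally to that mass), each in a distinct sample that does
    not already mutate the chosen position.  Because selection acts on
    mutations the process generates, carrier samples are drawn proportionally
    to ``sample_weights`` when given (typically the true exposure of the
    signature), otherwise uniformly.  Returns the augmented table; spiked
    rows carry ``true_signature == signature`` and ``spiked == True``.
    """
    rng = rng or np.random.default_rng(0)
    catalog = catalog or default_catalog()
    prof = catalog.profile_dict(signature)
    gene = model.by_id.get(gene_id)
    if gene is None:
        raise InputError(f"unknown gene {gene_id}")
    sites = []
    for idx, path, label in gc.iter_stop_sites(gene):
        mass = prof.get(label, 0.0)
        if mass > min_profile_mass:
            gpos = int(gene.positions[idx])
            if gene.strand == "+":
                ref, alt = path.ref_base, path.alt_base
            else:
                ref, alt = gc.COMPLEMENT[path.ref_base], gc.COMPLEMENT[path.alt_base]
            sites.append((gene.chrom, gpos, ref, alt, mass))
    if not sites:
        raise InputError(
            f"gene {gene_id} has no stop-reachable site compatible with {signature}"
        )
    samples = sorted(mutations["sample_id"].unique())
    if n_sgms > len(samples):
        raise InputError(
            f"cannot place {n_sgms} SGMs across {len(samples)} distinct samples"
        )
    if sample_weights is not None:
        w = sample_weights.reindex(samples).fillna(0.0).to_numpy(dtype=float)
        if w.sum() <= 0:
            raise InputError("sample_weights must have positive sum")
        p = w / w.sum()
    else:
        p = None
    chosen_samples = rng.choice(samples, size=n_sgms, replace=False, p=p)
    mass = np.array([s[4] for s in sites])
    mass = mass / mass.sum()
    taken = {(r.sample_id, r.chrom, r.pos) for r in mutations.itertuples(index=False)}
    new_rows = []
    for sample in chosen_samples:
        for _ in range(100):
            chrom, pos, ref, alt, _m = sites[rng.choice(len(sites), p=mass)]
            if (sample, chrom, pos) not in taken:
                taken.add((sample, chrom, pos))
                new_rows.append(
                    {
                        "sample_id": sample, "chrom": chrom, "pos": pos,
                        "ref": ref, "alt": alt, "true_signature": signature,
                        "spiked": True,
                    }
                )
                break
        else:
            raise InputError(f"could not place a spiked SGM in sample {sample}")
    out = pd.concat([mutations.assign(spiked=False), pd.DataFrame(new_rows)], ignore_index=True)
    return out


def simulate_covariates(
    model: CodingModel,
    samples: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    expression_counts: pd.Series | None = None,
    smoking_counts: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """CN segments, expression, and clinical covariates for a sample list.

    CN: per sample, a WGD indicator (baseline CN doubled) and focal losses
    over genes at ``cn_loss_rate``; segments tile each chromosome without
    overlap.  Expression: log-normal per gene; when ``expression_link > 0``
    the designated gene's expression increases with ``expression_counts``
    (the sample's mutation load of the linked signature).  Clinical: smoking
    categories, optionally coupled to ``smoking_counts`` via
    ``smoking_link``; sex and purity are random.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    samples = list(samples)

    def _series(s: pd.Series | None) -> pd.Series:
        if s is None:
            return pd.Series(0.0, index=samples)
        return s.reindex(samples).fillna(0.0)

    expr_counts = _series(expression_counts)
    smoke_counts = _series(smoking_counts)

    chrom_len = {}
    gene_ivs: dict[str, list[tuple[int, int, str]]] = {}
    for gene in model.genes:
        lo, hi = int(gene.positions.min()), int(gene.positions.max())
        gene_ivs.setdefault(gene.chrom, []).append((lo, hi, gene.gene_id))
        chrom_len[gene.chrom] = max(chrom_len.get(gene.chrom, 0), hi + config.intergenic)

    cn_rows = []
    clin_rows = []
    for sample in samples:
        wgd = rng.random() < config.wgd_fraction
        base = config.baseline_cn * (2.0 if wgd else 1.0)
        loss = config.loss_cn * (2.0 if wgd else 1.0) * 0.9
        for chrom, ivs in gene_ivs.items():
            cursor = 1
            for lo, hi, _gid in sorted(ivs):
                # pad focal losses to the minimum segment length
                pad = max(0, (1000 - (hi - lo + 1) + 1) // 2)
                s, e = max(1, lo - pad), hi + pad
                if rng.random() < config.cn_loss_rate and s > cursor:
                    cn_rows.append({"sample_id": sample, "chrom": chrom, "start": cursor, "end": s - 1, "cn": base})
                    cn_rows.append({"sample_id": sample, "chrom": chrom, "start": s, "end": e, "cn": loss})
                    cursor = e + 1
            cn_rows.append({"sample_id": sample, "chrom": chrom, "start": cursor, "end": max(cursor, chrom_len[chrom]), "cn": base})
        if config.smoking_link > 0:
            z = config.smoking_link * (smoke_counts[sample] - smoke_counts.mean()) / (smoke_counts.std() + 1e-9)
            level = int(np.clip(np.round(1.5 + z + rng.normal(0, 0.7)), 0, 3))
        else:
            level = int(rng.integers(4))
        clin_rows.append(
            {
                "sample_id": sample,
                "smoking_category": SMOKING_CATEGORIES[level],
                "sex": "female" if rng.random() < 0.5 else "male",
                "purity": float(np.round(rng.uniform(0.3, 1.0), 3)),
            }
        )

    expr_genes = ["APOBEC3A", "APOBEC3B", "APOBEC3C"]
    expr = {}
    std = expr_counts.std()
    for g in expr_genes:
        base_expr = rng.normal(5.0, 1.0, size=len(samples))
        if config.expression_link > 0 and g == config.expression_link_gene and std > 0:
            base_expr = base_expr + config.expression_link * (expr_counts.to_numpy() - expr_counts.mean()) / std
        expr[g] = np.round(base_expr, 4)
    expression = pd.DataFrame(expr, index=samples)
    expression.index.name = "sample_id"
    return pd.DataFrame(cn_rows), expression, pd.DataFrame(clin_rows)


@dataclass
class SimulatedStudy:
    config: SimConfig
    model: CodingModel
    genome: dict[str, str]
    catalog: SignatureCatalog
    mutations: pd.DataFrame
    exposures_true: pd.DataFrame
    cn_segments: pd.DataFrame
    expression: pd.DataFrame
    clinical: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Write every pipeline input format plus ground truth to a directory."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        self.model.gene_table.to_csv(out / "gene_model.tsv", sep="\t", index=False)
        from sgmsig.signatures import write_catalog

        write_catalog(self.catalog, out / "catalog.tsv")
        self.mutations.drop(columns=[c for c in ("true_signature", "spiked") if c in self.mutations], errors="ignore").to_csv(
            out / "mutations.tsv", sep="\t", index=False
        )
        self.mutations.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        self.exposures_true.to_csv(out / "exposures_true.tsv", sep="\t", index=False)
        self.cn_segments.to_csv(out / "cn_segments.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t")
        self.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        (out / "sim_config.json").write_text(self.config.to_json())


def simulate_study(config: SimConfig, catalog: SignatureCatalog | None = None) -> SimulatedStudy:
    """End-to-end generation of one synthetic study from a single seed."""
    rng = np.random.default_rng(config.seed)
    catalog = catalog or default_catalog()
    model, genome = simulate_coding_model(config, rng)
    mutations, exposures = simulate_cohort(model, genome, config, catalog, rng)
    for gene_id, signature, n in config.driver_spikes:
        weights = (
            exposures.set_index("sample_id")[signature]
            if signature in exposures.columns
            else None
        )
        mutations = spike_driver_sgms(
            mutations, model, genome, gene_id, signature, n, catalog, rng,
            sample_weights=weights,
        )
    # covariates couple to signature-specific mutation loads: expression to
    # the APOBEC-like load (the enzyme drives the process) and smoking
    # category to the tobacco-like load
    def _sig_counts(sig_name: str) -> pd.Series:
        sub = mutations[mutations["true_signature"] == sig_name]
        return sub.groupby("sample_id").size().astype(float)

    cn, expr, clin = simulate_covariates(
        model,
        sorted(mutations["sample_id"].unique()),
        config,
        rng,
        expression_counts=_sig_counts(config.expression_link_signature),
        smoking_counts=_sig_counts(config.smoking_link_signature),
    )
    return SimulatedStudy(config, model, genome, catalog, mutations, exposures, cn, expr, clin)
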