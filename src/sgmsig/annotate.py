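"""Coding model construction and functional annotation of somatic SNVs.

A coding model is one canonical transcript per gene: ordered genomic CDS
intervals plus the spliced, strand-corrected coding sequence.  Each SNV is
annotated by translating the mutated codon (missense / silent / stop_gain /
stop_loss / start_loss / noncoding), by its pyrimidine-normalised
trinucleotide channel from the genomic +/-1 context, and by its APOBEC
quadnucleotide motif class (YTCA / RTCA / other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from sgmsig import genetic_code as gc
from sgmsig.exceptions import DataIntegrityError, FormatError, InputError

FUNCTIONAL_CLASSES = (
    "missense",
    "silent",
    "stop_gain",
    "stop_loss",
    "start_loss",
    "noncoding",
)

MUTATION_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class SNV:
    sample_id: str
    chrom: str
    pos: int  # 1-based genomic
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in gc.BASES or self.alt not in gc.BASES:
            raise InputError(f"invalid ref/alt {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise InputError("ref and alt must differ")


@dataclass(frozen=True)
class AnnotatedSNV:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    functional_class: str
    ref_aa: str | None
    alt_aa: str | None
    protein_position: int | None
    channel: str | None
    motif_class: str
    signature_label: str = "unassigned"


@dataclass
class Gene:
    """One canonical transcript with genomic context arrays.

    ``intervals`` are 1-based inclusive genomic (start, end) pairs ordered
    5'->3' in transcript orientation.  ``positions[i]`` is the genomic
    coordinate of CDS base ``i``; ``prev``/``next`` give the coding-strand
    genomic neighbour of each CDS base (crossing exon boundaries these are the
    intronic neighbours, since mutational context lives on the genome).
    """

    gene_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    cds: str
    positions: np.ndarray = field(repr=False)
    prev: str = field(repr=False)
    next: str = field(repr=False)

    @property
    def protein_length(self) -> int:
        return len(self.cds) // 3 - 1  # excluding the terminal stop


@dataclass
class CodingModel:
    genes: list[Gene]

    def __post_init__(self) -> None:
        self.by_id = {g.gene_id: g for g in self.genes}
        # (chrom, genomic pos) -> [(gene, cds index)], gene_id-sorted
        lookup: dict[tuple[str, int], list[tuple[Gene, int]]] = {}
        for g in sorted(self.genes, key=lambda g: g.gene_id):
            for i, p in enumerate(g.positions):
                lookup.setdefault((g.chrom, int(p)), []).append((g, i))
        self._lookup = lookup

    def genes_at(self, chrom: str, pos: int) -> list[tuple[Gene, int]]:
        return self._lookup.get((chrom, pos), [])

    def __len__(self) -> int:
        return len(self.genes)


def load_genome(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Load a genome as an in-memory dict of upper-case sequences.

    Accepts a FASTA path (via pyfaidx) or an already-loaded mapping.
    """
    if isinstance(source, Mapping):
        return {str(k): str(v).upper() for k, v in source.items()}
    fa = Fasta(str(source))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _genome_base(genome: Mapping[str, str], chrom: str, pos: int) -> str:
    """Base at 1-based ``pos``; 'N' outside the contig."""
    seq = genome[chrom]
    if pos < 1 or pos > len(seq):
        return "N"
    return seq[pos - 1]


def read_gene_model(path: str | Path) -> pd.DataFrame:
    """Read the gene-model TSV: gene_id, chrom, strand, cds_starts, cds_ends."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chrom", "strand", "cds_starts", "cds_ends"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene model table missing columns: {sorted(missing)}")
    return df


def build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    intervals: list[tuple[int, int]],
    genome: Mapping[str, str],
    strict: bool = True,
) -> Gene:
    """Assemble one gene: splice, strand-correct, and validate the CDS."""
    if strand not in "+-":
        raise FormatError(f"{gene_id}: invalid strand {strand!r}")
    if chrom not in genome:
        raise FormatError(f"{gene_id}: unknown chromosome {chrom!r}")
    seq = genome[chrom]
    ivs = sorted(intervals)
    for (s, e) in ivs:
        if s > e:
            raise FormatError(f"{gene_id}: interval start {s} > end {e}")
        if s < 1 or e > len(seq):
            raise FormatError(f"{gene_id}: interval ({s},{e}) outside {chrom}")
    for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
        if s1 <= e0:
            raise FormatError(f"{gene_id}: overlapping CDS intervals")
    # transcript order: ascending for +, descending for -
    ordered = ivs if strand == "+" else ivs[::-1]

    positions: list[int] = []
    for (s, e) in ordered:
        rng = range(s, e + 1) if strand == "+" else range(e, s - 1, -1)
        positions.extend(rng)
    pos_arr = np.asarray(positions, dtype=np.int64)

    comp = gc.COMPLEMENT
    if strand == "+":
        cds = "".join(seq[p - 1] for p in positions)
        prev = "".join(_genome_base(genome, chrom, p - 1) for p in positions)
        nxt = "".join(_genome_base(genome, chrom, p + 1) for p in positions)
    else:
        cds = "".join(comp[seq[p - 1]] for p in positions)
        prev = "".join(comp.get(_genome_base(genome, chrom, p + 1), "N") for p in positions)
        nxt = "".join(comp.get(_genome_base(genome, chrom, p - 1), "N") for p in positions)

    problems = []
    if len(cds) % 3 != 0:
        raise FormatError(f"{gene_id}: CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        problems.append("does not start with ATG")
    if cds[-3:] not in gc.STOP_CODONS:
        problems.append("does not end with a stop codon")
    internal = [
        i for i in range(0, len(cds) - 3, 3) if cds[i : i + 3] in gc.STOP_CODONS
    ]
    if internal:
        problems.append(f"internal stop codon at codon {internal[0] // 3 + 1}")
    if problems:
        msg = f"{gene_id}: CDS {'; '.join(problems)}"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg)
    return Gene(gene_id, chrom, strand, ordered, cds, pos_arr, prev, nxt)


def build_coding_model(
    genome: str | Path | Mapping[str, str],
    gene_model: str | Path | pd.DataFrame,
    strict: bool = True,
) -> CodingModel:
    """Build a :class:`CodingModel` from a genome FASTA and gene-model TSV.

    With ``strict=False``, ORF violations (start/stop/internal stop) warn
    instead of raising, for real-world annotation sets.
    """
    genome_d = load_genome(genome)
    table = gene_model if isinstance(gene_model, pd.DataFrame) else read_gene_model(gene_model)
    genes = []
    for row in table.itertuples(index=False):
        starts = [int(x) for x in str(row.cds_starts).split(",")]
        ends = [int(x) for x in str(row.cds_ends).split(",")]
        if len(starts) != len(ends):
            raise FormatError(f"{row.gene_id}: cds_starts/cds_ends length mismatch")
        intervals = list(zip(starts, ends))
        genes.append(
            build_gene(str(row.gene_id), str(row.chrom), str(row.strand), intervals, genome_d, strict)
        )
    return CodingModel(genes)


def _classify(codon_index: int, ref_aa: str, alt_aa: str) -> str:
    if ref_aa == "*" and alt_aa != "*":
        return "stop_loss"
    if alt_aa == "*" and ref_aa != "*":
        return "stop_gain"
    if ref_aa == "*" and alt_aa == "*":
        return "silent"
    if codon_index == 0 and alt_aa != ref_aa:
        return "start_loss"
    return "silent" if alt_aa == ref_aa else "missense"


def snv_channel(genome: Mapping[str, str], chrom: str, pos: int, ref: str, alt: str) -> str | None:
    """Pyrimidine-normalised channel label from the genomic +/-1 context.

    Returns None when a flanking base is unavailable (contig edge)."""
    five = _genome_base(genome, chrom, pos - 1)
    three = _genome_base(genome, chrom, pos + 1)
    if five == "N" or three == "N":
        return None
    return gc.channel_label(five, ref, alt, three)


def quad_motif_class(
    genome: Mapping[str, str], chrom: str, pos: int, ref: str, alt: str
) -> str:
    """APOBEC tetranucleotide motif class of a mutated cytosine.

    The 4-mer is read at positions (-2,-1,0,+1) on the strand where the
    mutated base is C; [CT]TCA -> YTCA, [AG]TCA -> RTCA, anything else ->
    other.  Mutations whose pyrimidine-normalised reference is T are classed
    "other" (the motif is specific to C-reference APOBEC substitutions);
    missing flanking sequence -> not_applicable.
    """
    if ref == "C":
        bases = [_genome_base(genome, chrom, pos + d) for d in (-2, -1, 0, 1)]
        quad = "".join(bases)
    elif ref == "G":  # mutated C is on the minus strand
        bases = [_genome_base(genome, chrom, pos + d) for d in (-1, 0, 1, 2)]
        if "N" in bases:
            return "not_applicable"
        quad = gc.reverse_complement("".join(bases))
    else:
        return "other"
    if "N" in quad:
        return "not_applicable"
    if quad[1:] == "TCA":
        return "YTCA" if quad[0] in "CT" else "RTCA"
    return "other"


def annotate_snv_all(
    snv: SNV, model: CodingModel, genome: Mapping[str, str]
) -> list[AnnotatedSNV]:
    """Annotate one SNV against every gene whose CDS covers it.

    Returns one record per overlapping gene (gene_id-sorted), or a single
    noncoding record when no CDS covers the position.
    """
    actual = _genome_base(genome, snv.chrom, snv.pos)
    if actual != snv.ref:
        raise DataIntegrityError(
            f"{snv.chrom}:{snv.pos} ref {snv.ref} does not match genome base {actual}"
        )
    channel = snv_channel(genome, snv.chrom, snv.pos, snv.ref, snv.alt)
    motif = quad_motif_class(genome, snv.chrom, snv.pos, snv.ref, snv.alt)
    hits = model.genes_at(snv.chrom, snv.pos)
    if not hits:
        return [
            AnnotatedSNV(
                snv.sample_id, snv.chrom, snv.pos, snv.ref, snv.alt,
                None, "noncoding", None, None, None, channel, motif,
            )
        ]
    out = []
    for gene, cds_idx in hits:
        # map ref/alt into transcript space
        if gene.strand == "+":
            t_ref, t_alt = snv.ref, snv.alt
        else:
            t_ref, t_alt = gc.COMPLEMENT[snv.ref], gc.COMPLEMENT[snv.alt]
        assert gene.cds[cds_idx] == t_ref
        ci = cds_idx // 3
        codon = gene.cds[3 * ci : 3 * ci + 3]
        within = cds_idx - 3 * ci
        mutated = codon[:within] + t_alt + codon[within + 1 :]
        ref_aa = gc.CODON_TO_AA[codon]
        alt_aa = gc.CODON_TO_AA[mutated]
        out.append(
            AnnotatedSNV(
                snv.sample_id, snv.chrom, snv.pos, snv.ref, snv.alt,
                gene.gene_id, _classify(ci, ref_aa, alt_aa),
                ref_aa, alt_aa, ci + 1, channel, motif,
            )
        )
    return out


def annotate_snv(snv: SNV, model: CodingModel, genome: Mapping[str, str]) -> AnnotatedSNV:
    """Annotate one SNV; among overlapping genes the alphabetically first wins."""
    return annotate_snv_all(snv, model, genome)[0]


def annotate_table(
    mutations: pd.DataFrame, model: CodingModel, genome: Mapping[str, str]
) -> pd.DataFrame:
    """Annotate a MAF-like mutation table (sample_id, chrom, pos, ref, alt).

    Returns one row per input SNV (overlapping genes deduplicated to the
    alphabetically first) with annotation columns appended.
    """
    missing = set(MUTATION_COLUMNS) - set(mutations.columns)
    if missing:
        raise FormatError(f"mutation table missing columns: {sorted(missing)}")
    records = []
    for row in mutations.itertuples(index=False):
        snv = SNV(str(row.sample_id), str(row.chrom), int(row.pos), str(row.ref), str(row.alt))
        records.append(annotate_snv(snv, model, genome).__dict__)
    out = pd.DataFrame.from_records(records)
    if out.empty:
        out = pd.DataFrame(columns=list(AnnotatedSNV.__dataclass_fields__))
    # labels are produced by the assignment step, not annotation
    out = out.drop(columns=["signature_label"])
    extra = [c for c in mutations.columns if c not in out.columns]
    for c in extra:
        out[c] = mutations[c].to_numpy()
    return out


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like mutation TSV (header required)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"mutation table missing columns: {sorted(missing)}")
    df["pos"] = df["pos"].astype(int)
    return df
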