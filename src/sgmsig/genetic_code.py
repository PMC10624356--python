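"""Codon-level machinery linking SBS signatures to stop-gain mutations.

The standard genetic code reaches its three stop codons (TAA, TAG, TGA) from a
limited set of sense codons by a single base substitution, and each such
substitution corresponds to one of the 96 trinucleotide mutation channels once
its sequence context is attached.  Because SBS signatures are probability
profiles over those channels, a signature induces a well-defined distribution
over the amino acids it can replace with stop codons.  This module enumerates
the codon->stop paths, normalises substitution contexts to the
pyrimidine-reference channel convention, and computes that induced amino-acid
distribution for an arbitrary coding model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from sgmsig.exceptions import DegenerateResultError, DomainError, InputError

BASES = ("A", "C", "G", "T")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, with '*' for the three stop codons.
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] != "*"))

#: Three-letter names for reporting (one-letter codes are used internally).
AA_THREE = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr", "*": "Stop",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise InputError(f"invalid base in {seq!r}") from exc


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str) or len(codon) != 3:
        raise InputError(f"codon must be a 3-letter string, got {codon!r}")
    codon = codon.upper()
    if any(b not in BASES for b in codon):
        raise InputError(f"codon {codon!r} contains bases outside A/C/G/T")
    return codon


@dataclass(frozen=True, order=True)
class StopPath:
    """One single-base substitution converting a sense codon to a stop codon.

    ``position`` is 1-based within the codon; ``ref_base`` is the codon base at
    that position and ``alt_base`` the substituted base yielding ``stop_codon``.
    """

    codon: str
    position: int
    ref_base: str
    alt_base: str
    stop_codon: str


@dataclass(frozen=True)
class TrinucleotideChannel:
    """A pyrimidine-reference SBS channel: 5' flank, ref>alt, 3' flank.

    Purine-reference substitutions are stored reverse-complemented so the
    mutated base is always C or T; there are exactly 96 distinct channels.
    """

    five_prime: str
    ref: str
    alt: str
    three_prime: str

    def __post_init__(self) -> None:
        for b in (self.five_prime, self.ref, self.alt, self.three_prime):
            if b not in BASES:
                raise InputError(f"invalid base {b!r} in channel")
        if self.ref not in PYRIMIDINES:
            raise InputError("channel reference base must be a pyrimidine")
        if self.alt == self.ref:
            raise InputError("channel alt must differ from ref")

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.ref}>{self.alt}]{self.three_prime}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def normalize_channel(
    five_prime: str, ref: str, alt: str, three_prime: str
) -> TrinucleotideChannel:
    """Map a substitution with context onto its pyrimidine-reference channel.

    If ``ref`` is already a pyrimidine the channel is the identity; if it is a
    purine the whole trinucleotide and the alt base are reverse-complemented,
    so the 5' and 3' flanks swap and complement.
    """
    for b in (five_prime, ref, alt, three_prime):
        if b not in BASES:
            raise InputError(f"invalid base {b!r}")
    if alt == ref:
        raise InputError("alt must differ from ref")
    if ref in PYRIMIDINES:
        return TrinucleotideChannel(five_prime, ref, alt, three_prime)
    return TrinucleotideChannel(
        COMPLEMENT[three_prime], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[five_prime]
    )


def channel_label(five_prime: str, ref: str, alt: str, three_prime: str) -> str:
    """Shorthand for ``normalize_channel(...).label``."""
    return normalize_channel(five_prime, ref, alt, three_prime).label


def _cosmic_channel_order() -> tuple[str, ...]:
    labels = []
    for ref, alts in (("C", "AGT"), ("T", "ACG")):
        for alt in alts:
            for five in BASES:
                for three in BASES:
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(labels)


#: The 96 channels in COSMIC catalog order: substitution type outermost
#: (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank A,C,G,T, then 3' flank.
COSMIC_CHANNELS: tuple[str, ...] = _cosmic_channel_order()
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(COSMIC_CHANNELS)}


def stop_paths(codon: str) -> list[StopPath]:
    """Enumerate every single-base substitution converting ``codon`` to a stop.

    Results are ordered deterministically by (position, alt base).  A codon
    with no such substitution yields an empty list; stop-codon input raises
    :class:`DomainError`.
    """
    codon = _check_codon(codon)
    if codon in STOP_CODONS:
        raise DomainError(f"{codon} is itself a stop codon")
    paths: list[StopPath] = []
    for pos in range(3):
        ref = codon[pos]
        for alt in BASES:
            if alt == ref:
                continue
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if mutated in STOP_CODONS:
                paths.append(StopPath(codon, pos + 1, ref, alt, mutated))
    paths.sort(key=lambda p: (p.position, p.alt_base))
    return paths


def stop_reachable_codons() -> dict[str, int]:
    """Sense codons that can become a stop codon by one substitution.

    Returns a mapping codon -> number of distinct codon->stop paths.
    """
    out: dict[str, int] = {}
    for codon in SENSE_CODONS:
        n = len(stop_paths(codon))
        if n:
            out[codon] = n
    return out


def _profile_as_mapping(
    profile: Mapping[str, float] | Sequence[float] | np.ndarray,
) -> dict[str, float]:
    if isinstance(profile, Mapping):
        prof = {str(k): float(v) for k, v in profile.items()}
    else:
        arr = np.asarray(profile, dtype=float)
        if arr.shape != (96,):
            raise InputError(
                f"array profile must have shape (96,), got {arr.shape}"
            )
        prof = dict(zip(COSMIC_CHANNELS, arr.tolist()))
    vals = np.array(list(prof.values()))
    if (vals < 0).any():
        raise InputError("profile has negative entries")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise InputError(f"profile must sum to 1, got {vals.sum()!r}")
    unknown = set(prof) - set(COSMIC_CHANNELS)
    if unknown:
        raise InputError(f"unknown channels in profile: {sorted(unknown)[:3]}")
    return prof


def iter_stop_sites(gene) -> Iterable[tuple[int, StopPath, str]]:
    """Yield (cds_index, stop_path, channel_label) for every stop-inducing
    substitution in a gene's CDS.

    ``gene`` needs attributes ``cds`` (spliced coding sequence), ``prev`` and
    ``next`` (strings giving, for each CDS position, the genomic base
    immediately 5' / 3' of that position on the coding strand).  Contexts
    therefore span adjacent codons — and splice junctions use genomic, not
    spliced, neighbours.  The terminal stop codon is excluded.
    """
    cds = gene.cds
    n_codons = len(cds) // 3
    for ci in range(n_codons):
        codon = cds[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            continue
        for path in stop_paths(codon):
            idx = 3 * ci + path.position - 1
            five = gene.prev[idx]
            three = gene.next[idx]
            if five not in BASES or three not in BASES:
                continue  # flank unavailable (contig edge)
            yield idx, path, channel_label(five, path.ref_base, path.alt_base, three)


def signature_stop_distribution(
    profile: Mapping[str, float] | Sequence[float] | np.ndarray,
    model,
    three_letter: bool = False,
) -> dict[str, float]:
    """Distribution of amino acids replaced by stop codons under a signature.

    Every stop-inducing substitution at every CDS position of ``model``
    contributes the signature probability of its (pyrimidine-normalised,
    genomic-context) channel to the amino acid encoded by the affected codon.
    The result is normalised to sum to 1, i.e. it conditions on a stop-gain
    mutation having occurred; amino acids with zero mass are omitted.  CDS
    positions are weighted uniformly.
    """
    prof = _profile_as_mapping(profile)
    genes = list(getattr(model, "genes", model))
    if not genes:
        raise InputError("coding model is empty")
    mass: dict[str, float] = {}
    for gene in genes:
        for idx, path, label in iter_stop_sites(gene):
            aa = CODON_TO_AA[path.codon]
            mass[aa] = mass.get(aa, 0.0) + prof.get(label, 0.0)
    total = sum(mass.values())
    if total <= 0.0:
        raise DegenerateResultError(
            "signature places no mass on any stop-inducing channel of the model"
        )
    out = {aa: m / total for aa, m in mass.items() if m > 0.0}
    if three_letter:
        out = {AA_THREE[aa]: p for aa, p in out.items()}
    return out
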