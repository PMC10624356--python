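"""SBS signature catalogs, exposure refitting, and per-SNV assignment.

A catalog is a set of named probability profiles over the 96 trinucleotide
channels in COSMIC order.  Per-sample exposures are refit by non-negative
least squares with iterative pruning of signatures below 1% weight — a
deliberately simple refitting scheme whose output (per-SNV signature labels)
is all the downstream enrichment analyses consume.  Individual SNVs are
assigned either to the most probable signature given the sample's exposures
(``assign_top``) or by multinomial sampling from the full posterior
(``sample_assignments``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from sgmsig.exceptions import FormatError, InputError
from sgmsig.genetic_code import CHANNEL_INDEX, COSMIC_CHANNELS

#: Sequencing-artifact signatures excluded from biological analyses (COSMIC).
ARTIFACT_SIGNATURES = frozenset(
    {"SBS27", "SBS43"} | {f"SBS{i}" for i in range(45, 61)}
)

_MERGE_MAP = {
    "SBS5": "SBS5/40",
    "SBS40": "SBS5/40",
    "SBS7a": "SBS7",
    "SBS7b": "SBS7",
    "SBS7c": "SBS7",
    "SBS7d": "SBS7",
    "SBS10a": "SBS10",
    "SBS10b": "SBS10",
    "SBS17a": "SBS17",
    "SBS17b": "SBS17",
}

UNASSIGNED = "unassigned"


class SignatureCatalog:
    """Named 96-channel signature profiles, each normalised to sum to 1."""

    def __init__(self, profiles: pd.DataFrame):
        if list(profiles.index) != list(COSMIC_CHANNELS):
            profiles = profiles.reindex(list(COSMIC_CHANNELS))
            if profiles.isna().any().any():
                raise FormatError("catalog is missing one or more of the 96 channels")
        if (profiles.to_numpy() < 0).any():
            raise FormatError("catalog contains negative values")
        sums = profiles.sum(axis=0)
        if (np.abs(sums - 1.0) > 1e-3).any():
            bad = sums[np.abs(sums - 1.0) > 1e-3].index.tolist()
            raise FormatError(f"catalog columns do not sum to 1: {bad}")
        if profiles.columns.duplicated().any():
            raise FormatError("duplicate signature names in catalog")
        self.profiles = profiles / sums

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy()

    def profile(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy()

    def profile_dict(self, name: str) -> dict[str, float]:
        return self.profiles[name].to_dict()

    def __contains__(self, name: str) -> bool:
        return name in self.profiles.columns

    def __len__(self) -> int:
        return self.profiles.shape[1]


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a catalog TSV: 96 rows keyed by channel label, one column per signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"catalog must have 96 channel rows, got {df.shape[0]}")
    missing = set(COSMIC_CHANNELS) - set(df.index)
    if missing:
        raise FormatError(f"catalog missing channels, e.g. {sorted(missing)[:3]}")
    return SignatureCatalog(df)


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    out = catalog.profiles.copy()
    out.index.name = "channel"
    out.to_csv(path, sep="\t", float_format="%.12g")


@dataclass
class ExposureVector:
    sample_id: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if total <= 0:
            raise InputError("exposure weights must have positive sum")
        if any(w < 0 for w in self.weights.values()):
            raise InputError("exposure weights must be non-negative")
        self.weights = {k: v / total for k, v in self.weights.items()}


def spectrum(snvs: pd.DataFrame | Iterable) -> np.ndarray:
    """96-channel mutation spectrum of annotated SNVs (channel-undefined skipped)."""
    if isinstance(snvs, pd.DataFrame):
        channels = snvs["channel"].dropna()
    else:
        channels = [s.channel for s in snvs if getattr(s, "channel", None)]
    counts = np.zeros(96, dtype=float)
    for ch in channels:
        counts[CHANNEL_INDEX[ch]] += 1
    return counts


def cosine(spec_a: Sequence[float], spec_b: Sequence[float]) -> float:
    """Cosine similarity of two 96-channel spectra (scale-invariant)."""
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise InputError("cosine undefined for zero-norm spectrum")
    return float(np.dot(a, b) / (na * nb))


def fit_exposures(
    spec: Sequence[float],
    catalog: SignatureCatalog,
    sample_id: str = "",
    prune_below: float = 0.01,
) -> ExposureVector:
    """Refit signature exposures by NNLS with iterative pruning.

    The normalised spectrum is regressed on the catalog profiles under a
    non-negativity constraint; signatures whose normalised weight falls below
    ``prune_below`` are dropped and the remainder refit, until stable.  The
    returned weights sum to 1.
    """
    counts = np.asarray(spec, dtype=float)
    if counts.shape != (96,):
        raise InputError(f"spectrum must have 96 channels, got {counts.shape}")
    total = counts.sum()
    if total < 1:
        raise InputError("spectrum must contain at least one mutation")
    target = counts / total
    active = list(catalog.names)
    while True:
        mat = catalog.profiles[active].to_numpy()
        coef, _ = nnls(mat, target)
        s = coef.sum()
        if s <= 0:
            raise InputError("NNLS fit degenerate: all coefficients zero")
        norm = coef / s
        keep = [sig for sig, w in zip(active, norm) if w >= prune_below]
        if not keep:  # keep the single best signature rather than none
            keep = [active[int(np.argmax(norm))]]
        if keep == active:
            return ExposureVector(sample_id, dict(zip(active, norm.tolist())))
        active = keep


def _posterior(channel: str, exposures: ExposureVector, catalog: SignatureCatalog) -> dict[str, float]:
    idx = CHANNEL_INDEX[channel]
    return {
        sig: w * float(catalog.profiles[sig].iloc[idx])
        for sig, w in exposures.weights.items()
        if sig in catalog
    }


def assign_top(channel: str, exposures: ExposureVector, catalog: SignatureCatalog) -> str:
    """Most probable signature for one SNV channel; ties break alphabetically.

    Returns ``unassigned`` when every exposed signature has zero mass on the
    channel.
    """
    post = _posterior(channel, exposures, catalog)
    if not post:
        return UNASSIGNED
    best_val = max(post.values())
    if best_val <= 0:
        return UNASSIGNED
    return min(sig for sig, p in post.items() if p == best_val)


def assign_top_table(
    annotated: pd.DataFrame,
    exposures: dict[str, ExposureVector],
    catalog: SignatureCatalog,
) -> pd.DataFrame:
    """Append a ``signature_label`` column via per-sample top assignment.

    Precomputes, per sample, the argmax signature for each of the 96 channels,
    so the per-SNV work is a lookup.  SNVs without a channel or without an
    exposure vector are labelled ``unassigned``.
    """
    out = annotated.copy()
    labels = np.full(len(out), UNASSIGNED, dtype=object)
    mat = catalog.matrix  # (96, k)
    names = np.array(catalog.names)
    order = np.argsort(names)  # alphabetical tie-break via stable ordering
    for sample, idx in out.groupby("sample_id").groups.items():
        ev = exposures.get(sample)
        if ev is None:
            continue
        w = np.array([ev.weights.get(sig, 0.0) for sig in names])
        post = mat * w  # (96, k)
        post_sorted = post[:, order]
        best = np.argmax(post_sorted, axis=1)  # first (alphabetical) max
        best_name = names[order][best]
        best_val = post_sorted[np.arange(96), best]
        per_channel = np.where(best_val > 0, best_name, UNASSIGNED)
        sub = out.loc[idx, "channel"]
        ok = sub.notna()
        ch_idx = sub[ok].map(CHANNEL_INDEX).to_numpy(dtype=int)
        lab = np.full(len(sub), UNASSIGNED, dtype=object)
        lab[np.where(ok)[0]] = per_channel[ch_idx]
        labels[out.index.get_indexer(idx)] = lab
    out["signature_label"] = labels
    return out


def sample_assignments(
    annotated: pd.DataFrame,
    exposures: dict[str, ExposureVector],
    catalog: SignatureCatalog,
    seed: int,
) -> pd.Series:
    """One multinomial draw of per-SNV signature labels.

    Each SNV receives signature ``s`` with probability proportional to
    ``weight(s) * profile_s(channel)``; reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    labels = pd.Series(UNASSIGNED, index=annotated.index, dtype=object)
    names = np.array(catalog.names)
    mat = catalog.matrix
    for sample, idx in annotated.groupby("sample_id").groups.items():
        ev = exposures.get(sample)
        if ev is None:
            continue
        w = np.array([ev.weights.get(sig, 0.0) for sig in names])
        post = mat * w  # (96, k)
        totals = post.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(totals[:, None] > 0, post / np.where(totals[:, None] > 0, totals[:, None], 1.0), 0.0)
        cum = np.cumsum(probs, axis=1)
        sub = annotated.loc[idx, "channel"]
        ok = sub.notna()
        ch_idx = sub[ok].map(CHANNEL_INDEX).to_numpy(dtype=int)
        u = rng.random(len(ch_idx))
        pick = (u[:, None] > cum[ch_idx]).sum(axis=1)
        drawn = np.where(totals[ch_idx] > 0, names[np.minimum(pick, len(names) - 1)], UNASSIGNED)
        labels.loc[idx[ok.to_numpy()]] = drawn
    return labels


def merge_labels(label: str) -> str:
    """Collapse related COSMIC signatures to their merged analysis labels.

    SBS5/SBS40 -> SBS5/40, SBS7a-d -> SBS7, SBS10a/b -> SBS10,
    SBS17a/b -> SBS17; anything else is returned unchanged.
    """
    return _MERGE_MAP.get(label, label)


def fit_cohort_exposures(
    annotated: pd.DataFrame, catalog: SignatureCatalog
) -> dict[str, ExposureVector]:
    """Refit exposures for every sample in an annotated mutation table."""
    out: dict[str, ExposureVector] = {}
    for sample, sub in annotated.groupby("sample_id"):
        spec = spectrum(sub)
        if spec.sum() < 1:
            continue
        out[sample] = fit_exposures(spec, catalog, sample_id=str(sample))
    return out


def artifact_fraction(labels: pd.Series, artifact_set: frozenset[str] = ARTIFACT_SIGNATURES) -> float:
    """Fraction of labelled SNVs assigned to artifact signatures."""
    if len(labels) == 0:
        return 0.0
    return float(labels.isin(artifact_set).mean())
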