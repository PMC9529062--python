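"""Cohort-level statistics: group comparisons, VAF fractions, mutation spectra.

Two-group comparisons use the Mann-Whitney U test: an exact-enumeration
p-value for small cohorts (combined n <= 12 by default) and a tie-corrected
normal approximation otherwise. Spectra are tallied over the 96 canonical
trinucleotide channels (pyrimidine-strand convention) and can be refit as a
non-negative combination of reference mutational signatures.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .seq import revcomp
from .simulate import TargetPanel

__all__ = [
    "GroupComparison",
    "VafFraction",
    "Spectrum96",
    "SignatureExposure",
    "SPECTRUM_CHANNELS",
    "load_cohort_table",
    "compare_groups",
    "mann_whitney_u",
    "vaf_fraction",
    "spectrum_96",
    "refit_signatures",
]

COHORT_COLUMNS = ("patient", "group", "total_mutations", "nonsynonymous",
                  "cancer_associated", "relapse")
GROUP_LABELS = ("infant", "child")


def load_cohort_table(path) -> pd.DataFrame:
    """Load and validate a per-patient cohort TSV."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(table["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    for col in ("total_mutations", "nonsynonymous", "cancer_associated"):
        if (table[col] < 0).any():
            raise ValueError(f"negative counts in column {col!r}")
    return table


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    groups: Tuple[str, str]
    n: Tuple[int, int]
    means: Tuple[float, float]
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of the first sample: pairs (x, y) with x > y, ties counting half."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 12,
) -> Tuple[float, float, str]:
    """Two-sided Mann-Whitney U test.

    For combined n <= ``exact_limit`` the p-value is computed by full
    enumeration of group assignments (the definitional null); larger samples
    use the normal approximation with midrank tie correction and continuity
    correction. Returns (U of first sample, p, method).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        total = 0
        extreme = 0
        target = abs(u_obs - mu)
        for comb in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= target - 1e-12:
                extreme += 1
        return u_obs, extreme / total, "exact"

    # tie-corrected normal approximation with continuity correction
    pooled = np.concatenate([x, y])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0, "normal"
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * float(sps.norm.sf(max(z, 0.0))))
    return u_obs, p, "normal"


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    groups: Tuple[str, str] = GROUP_LABELS,
    group_col: str = "group",
    exact_limit: int = 12,
) -> GroupComparison:
    """Compare a cohort metric between two groups (e.g. infants vs children)."""
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    vals = [table.loc[table[group_col] == g, metric].to_numpy(dtype=float) for g in groups]
    for g, v in zip(groups, vals):
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    u, p, method = mann_whitney_u(vals[0], vals[1], exact_limit=exact_limit)
    return GroupComparison(
        groups=tuple(groups), n=(vals[0].size, vals[1].size),
        means=(float(vals[0].mean()), float(vals[1].mean())),
        u_statistic=u, p_value=p, method=method)


# ---------------------------------------------------------------------------
# VAF threshold fractions
# ---------------------------------------------------------------------------

@dataclass
class VafFraction:
    n: int
    n_above: int
    fraction_above: Optional[float]
    fraction_below: Optional[float]
    defined: bool


def vaf_fraction(vafs: Sequence[float], threshold: float) -> VafFraction:
    """Fraction of calls with VAF strictly above ``threshold`` (and complement)."""
    vals = np.asarray(list(vafs), dtype=float)
    if vals.size == 0:
        return VafFraction(0, 0, None, None, False)
    above = int((vals > threshold).sum())
    return VafFraction(
        n=int(vals.size), n_above=above,
        fraction_above=above / vals.size,
        fraction_below=1.0 - above / vals.size,
        defined=True)


# ---------------------------------------------------------------------------
# 96-channel trinucleotide spectra and signature refitting
# ---------------------------------------------------------------------------

_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
SPECTRUM_CHANNELS: Tuple[str, ...] = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in _SUBSTITUTIONS for f5 in "ACGT" for f3 in "ACGT"
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(SPECTRUM_CHANNELS)}


@dataclass
class Spectrum96:
    """SNV counts over the 96 trinucleotide channels plus an edge bucket.

    SNVs at region edges (no flanking base available) are counted in ``edge``
    and excluded from the channels, so channels + edge always equals the
    number of input SNVs.
    """

    counts: np.ndarray
    edge: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.edge

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(SPECTRUM_CHANNELS), name="count")

    def to_tsv(self, path) -> None:
        self.to_series().to_csv(path, sep="\t", index_label="channel")


def _channel(ref: str, alt: str, five: str, three: str) -> str:
    if ref in "AG":  # purine strand: fold to the pyrimidine convention
        ref, alt = revcomp(ref), revcomp(alt)
        five, three = revcomp(three), revcomp(five)
    return f"{five}[{ref}>{alt}]{three}"


def spectrum_96(variants: Sequence, panel: TargetPanel) -> Spectrum96:
    """Tally SNVs into the 96-channel trinucleotide spectrum.

    ``variants`` may be any objects with ``contig``, ``position``, ``ref``
    and ``alt`` attributes; flanking bases come from the panel reference.
    """
    counts = np.zeros(96, dtype=np.int64)
    edge = 0
    for v in variants:
        region = panel.region_for(v.contig, v.position)
        if region is None:
            raise KeyError(f"variant at {v.contig}:{v.position} outside panel")
        off = v.position - region.start
        if off == 0 or off == region.length - 1:
            edge += 1
            continue
        five = region.sequence[off - 1]
        three = region.sequence[off + 1]
        counts[_CHANNEL_INDEX[_channel(v.ref, v.alt, five, three)]] += 1
    return Spectrum96(counts=counts, edge=edge)


@dataclass
class SignatureExposure:
    exposures: pd.Series  # non-negative weight per signature
    residual: float       # L2 norm of spectrum - signatures @ exposures

    def as_fractions(self) -> pd.Series:
        s = float(self.exposures.sum())
        return self.exposures / s if s > 0 else self.exposures


def refit_signatures(
    spectrum: Spectrum96,
    signatures: pd.DataFrame,
    normalize: bool = False,
) -> SignatureExposure:
    """Non-negative least-squares refit of a spectrum onto reference signatures.

    ``signatures`` must be indexed by the 96 channel labels in canonical
    order with columns summing to 1. Returns exposures (mutation counts
    attributed to each signature, or fractions when ``normalize``) and the
    reconstruction residual.
    """
    if list(signatures.index) != list(SPECTRUM_CHANNELS):
        raise ValueError("signature matrix index must match the 96 canonical channels")
    colsums = signatures.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    w, rnorm = optimize.nnls(signatures.to_numpy(dtype=float),
                             spectrum.counts.astype(float))
    exposures = pd.Series(w, index=signatures.columns, name="exposure")
    result = SignatureExposure(exposures=exposures, residual=float(rnorm))
    if normalize:
        result = SignatureExposure(exposures=result.as_fractions(), residual=result.residual)
    return result
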