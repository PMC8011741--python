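"""Metagene-style profiles: scaled feature body plus fixed-width flanks.

Each feature is split into ``body_bins`` equal-width windows (remainder
bases spread over the leading bins) with ``flank_bins`` fixed-width windows
on each side. Every signal exposes per-base numerator and denominator
arrays, so one binning rule serves all three signal families:

* coverage-type signals (siRNA RPM, H3K27me3): numerator = per-base signal,
  denominator = 1 inside the chromosome — the bin value is the mean
  per-base signal;
* methylation: numerator = mC, denominator = mC + umC at cytosine sites —
  the bin value is the read-weighted level.

Minus-strand features are reversed so bin 0 is always the 5' end. Flanks
truncated at a chromosome edge contribute no denominator there; bins with
zero denominator are NaN and are ignored when averaging across features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .methylation import CytosineIndex
from .models import SmallRNAAlignment


@dataclass(frozen=True)
class ProfileSpec:
    body_bins: int = 40
    flank_bp: int = 2_000
    flank_bins: int = 20

    def __post_init__(self) -> None:
        if self.body_bins < 1 or self.flank_bins < 1:
            raise ValueError("body_bins and flank_bins must be >= 1")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins

    @property
    def sections(self) -> Tuple[str, ...]:
        return (
            ("5p_flank",) * self.flank_bins
            + ("body",) * self.body_bins
            + ("3p_flank",) * self.flank_bins
        )


@dataclass
class MetaProfile:
    values: np.ndarray
    sections: Tuple[str, ...]
    n_features: int
    spec: ProfileSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(len(self.values)),
                "section": list(self.sections),
                "value": self.values,
                "n_features": self.n_features,
            }
        )


class DenseSignal:
    """Per-base numerator/denominator arrays held per chromosome."""

    def __init__(self, num: Dict[str, np.ndarray], den: Dict[str, np.ndarray]):
        self._num = num
        self._den = den

    def window(self, chrom: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        """Arrays of length end-start; bases outside the chromosome get
        denominator 0 (they drop out of every bin)."""
        width = end - start
        num = np.zeros(width)
        den = np.zeros(width)
        arr_n = self._num.get(chrom)
        if arr_n is None:
            return num, den
        arr_d = self._den[chrom]
        lo = max(start, 0)
        hi = min(end, len(arr_n))
        if lo < hi:
            num[lo - start : hi - start] = arr_n[lo:hi]
            den[lo - start : hi - start] = arr_d[lo:hi]
        return num, den


class CoverageSignal(DenseSignal):
    """Mean-per-base coverage signal built from intervals or reads."""

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[GenomicInterval],
        chrom_sizes: Dict[str, int],
        scale: float = 1.0,
    ) -> "CoverageSignal":
        num = {c: np.zeros(size) for c, size in chrom_sizes.items()}
        den = {c: np.ones(size) for c, size in chrom_sizes.items()}
        for iv in intervals:
            arr = num.get(iv.chrom)
            if arr is not None:
                arr[iv.start : iv.end] += scale
        return cls(num, den)

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[SmallRNAAlignment],
        chrom_sizes: Dict[str, int],
        rpm_library: Optional[int] = None,
    ) -> "CoverageSignal":
        """Read-depth signal; with ``rpm_library`` the depth is scaled to
        reads per million."""
        scale = 1e6 / rpm_library if rpm_library else 1.0
        return cls.from_intervals((r.interval for r in reads), chrom_sizes, scale=scale)

    @classmethod
    def from_bedgraph(
        cls,
        entries: Iterable[Tuple[GenomicInterval, float]],
        chrom_sizes: Dict[str, int],
    ) -> "CoverageSignal":
        num = {c: np.zeros(size) for c, size in chrom_sizes.items()}
        den = {c: np.ones(size) for c, size in chrom_sizes.items()}
        for iv, value in entries:
            arr = num.get(iv.chrom)
            if arr is not None:
                arr[iv.start : iv.end] = value
        return cls(num, den)


class MethylationSignal:
    """Read-weighted methylation signal for one cytosine context."""

    def __init__(self, index: CytosineIndex, context: str):
        self._index = index
        self._context = context

    def window(self, chrom: str, start: int, end: int) -> Tuple[np.ndarray, np.ndarray]:
        width = end - start
        num = np.zeros(width)
        den = np.zeros(width)
        lo = max(start, 0)
        if lo < end:
            pos, mc, tot = self._index.window_counts(chrom, lo, end, self._context)
            num[pos - start] = mc
            den[pos - start] = tot
        return num, den


def _bin_slices(offset: int, n_bases: int, n_bins: int) -> List[slice]:
    """Contiguous windows covering [offset, offset+n_bases), remainder
    spread over the leading bins (np.array_split semantics)."""
    base, rem = divmod(n_bases, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    out = []
    cursor = offset
    for size in sizes:
        out.append(slice(cursor, cursor + size))
        cursor += size
    return out


def feature_profile(
    feature: GenomicInterval, signal, spec: ProfileSpec = ProfileSpec()
) -> np.ndarray:
    """Per-bin signal vector for one feature (NaN where no denominator)."""
    w_start = feature.start - spec.flank_bp
    w_end = feature.end + spec.flank_bp
    num, den = signal.window(feature.chrom, w_start, w_end)
    body_len = feature.length
    slices = (
        _bin_slices(0, spec.flank_bp, spec.flank_bins)
        + _bin_slices(spec.flank_bp, body_len, spec.body_bins)
        + _bin_slices(spec.flank_bp + body_len, spec.flank_bp, spec.flank_bins)
    )
    values = np.empty(spec.n_bins)
    for i, sl in enumerate(slices):
        d = den[sl].sum()
        values[i] = num[sl].sum() / d if d > 0 else np.nan
    if feature.strand == "-":
        values = values[::-1]
    return values


def aggregate_profiles(
    features: Sequence[GenomicInterval], signal, spec: ProfileSpec = ProfileSpec()
) -> MetaProfile:
    """Per-bin mean over features, ignoring NaN (uncovered) bins."""
    if not features:
        raise ValueError("aggregate_profiles requires >= 1 feature")
    matrix = np.vstack([feature_profile(f, signal, spec) for f in features])
    if np.isnan(matrix).all():
        raise ValueError("all bins undefined: no signal overlaps any feature")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(matrix, axis=0)
    return MetaProfile(values, spec.sections, len(features), spec)


def plot_profiles(profiles: Dict[str, MetaProfile], path) -> None:
    """Line plot of one or more metaprofiles (optional convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for name, profile in profiles.items():
        ax.plot(profile.values, label=name)
        nb = profile.spec.flank_bins
        ax.axvline(nb - 0.5, color="grey", lw=0.5)
        ax.axvline(nb + profile.spec.body_bins - 0.5, color="grey", lw=0.5)
    ax.set_xlabel("bin (5' flank | body | 3' flank)")
    ax.set_ylabel("signal")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
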