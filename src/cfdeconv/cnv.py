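"""Shallow copy-number profiling from binned read counts.

Counts in fixed genomic bins (default 400 kb) are scaled to a common
autosomal total, normalized against a panel of healthy references via
per-bin median and scaled MAD, and runs of consistently aberrant z-scores
are called as gain/loss segments. The panel normalization is deliberately
simple and fully specified (median/MAD rather than a learned model) so its
behaviour is testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ValidationError

DEFAULT_BINSIZE = 400_000
SEX_CHROMS = {"chrX", "chrY", "X", "Y"}
_MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates a Gaussian sigma
_SPREAD_FLOOR = 1e-6

_BIN_COLUMNS = ["chrom", "start", "end"]


def make_bins(genome: Mapping[str, int], binsize: int = DEFAULT_BINSIZE) -> pd.DataFrame:
    """Tile each chromosome with fixed-size bins (last bin may be short)."""
    if binsize <= 0:
        raise ValidationError("binsize must be positive")
    rows = []
    for chrom, length in genome.items():
        if length <= 0:
            raise ValidationError(f"chromosome {chrom!r} has non-positive length")
        starts = np.arange(0, length, binsize, dtype=np.int64)
        ends = np.minimum(starts + binsize, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class BinCounts:
    """Read counts over a fixed bin grid for one sample."""

    bins: pd.DataFrame
    counts: np.ndarray
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.bins = pd.DataFrame(self.bins, columns=_BIN_COLUMNS).reset_index(drop=True)
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bins):
            raise ValidationError("counts and bins differ in length")
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")

    def __len__(self) -> int:
        return len(self.bins)

    def same_grid(self, other: "BinCounts") -> bool:
        return self.bins.equals(other.bins)

    def to_csv(self, path) -> None:
        out = self.bins.copy()
        out["count"] = self.counts
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, sample_id: str = "sample") -> "BinCounts":
        df = pd.read_csv(path, dtype={"chrom": str})
        return cls(df[_BIN_COLUMNS], df["count"].to_numpy(), sample_id)


def bin_reads(
    positions: pd.DataFrame,
    genome: Mapping[str, int],
    binsize: int = DEFAULT_BINSIZE,
    sample_id: str = "sample",
) -> BinCounts:
    """Count read starts per bin (half-open bins, deterministic).

    ``positions`` needs columns ``chrom`` and ``pos`` (0-based read start).
    """
    bins = make_bins(genome, binsize)
    counts = np.zeros(len(bins), dtype=np.int64)
    offsets = {}
    cursor = 0
    for chrom, length in genome.items():
        n = int(np.ceil(length / binsize))
        offsets[chrom] = (cursor, length)
        cursor += n
    for chrom, grp in positions.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise ValidationError(f"read on unknown chromosome {chrom!r}")
        offset, length = offsets[chrom]
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if (pos < 0).any() or (pos >= length).any():
            raise ValidationError(f"read position beyond {chrom!r} bounds")
        idx = offset + pos // binsize
        np.add.at(counts, idx, 1)
    return BinCounts(bins, counts, sample_id)


class PanelNormalizer(BaseEstimator):
    """Panel-of-normals normalization of bin counts.

    fit() learns per-bin reference level (median) and spread (scaled MAD)
    from healthy panel profiles after scaling every profile to the same
    autosomal total; transform() returns per-bin log2 ratios and z-scores
    for a sample on the identical grid. Bins with panel median below
    ``min_panel_median`` (after scaling) and sex-chromosome bins are masked.

    Attributes (after fit)
    ----------------------
    bins_ : the bin grid
    median_, spread_ : per-bin panel statistics on the scaled counts
    mask_ : bins excluded from calling
    """

    def __init__(self, min_panel_median: float = 10.0, exclude_sex_chroms: bool = True,
                 target_total: float = 1e6):
        self.min_panel_median = min_panel_median
        self.exclude_sex_chroms = exclude_sex_chroms
        self.target_total = target_total

    def _autosomal(self, bins: pd.DataFrame) -> np.ndarray:
        if not self.exclude_sex_chroms:
            return np.ones(len(bins), dtype=bool)
        return ~bins["chrom"].isin(SEX_CHROMS).to_numpy()

    def _scale(self, counts: np.ndarray, autosomal: np.ndarray) -> np.ndarray:
        total = counts[autosomal].sum()
        if total <= 0:
            raise ValidationError("profile has zero autosomal counts; cannot scale")
        return counts * (self.target_total / total)

    def fit(self, panel: Sequence[BinCounts], y=None):
        panel = list(panel)
        if len(panel) < 3:
            raise ValidationError("panel of normals needs >= 3 profiles")
        grid = panel[0].bins
        for p in panel[1:]:
            if not p.bins.equals(grid):
                raise ValidationError("panel profiles are on different bin grids")
        autosomal = self._autosomal(grid)
        scaled = np.vstack(
            [self._scale(p.counts.astype(float), autosomal) for p in panel]
        )
        self.bins_ = grid
        self.median_ = np.median(scaled, axis=0)
        mad = np.median(np.abs(scaled - self.median_), axis=0)
        self.spread_ = np.maximum(_MAD_SCALE * mad, _SPREAD_FLOOR)
        self.mask_ = (~autosomal) | (self.median_ < self.min_panel_median)
        self.n_features_in_ = len(grid)
        return self

    def transform(self, sample: BinCounts) -> pd.DataFrame:
        """Per-bin normalized profile: columns chrom, start, end, count,
        log2_ratio, z, masked."""
        if not sample.bins.equals(self.bins_):
            raise ValidationError("sample is on a different bin grid than the panel")
        autosomal = self._autosomal(sample.bins)
        scaled = self._scale(sample.counts.astype(float), autosomal)
        out = self.bins_.copy()
        out["count"] = sample.counts
        with np.errstate(divide="ignore", invalid="ignore"):
            log2r = np.log2(scaled / self.median_)
        z = (scaled - self.median_) / self.spread_
        masked = self.mask_.copy()
        log2r[masked] = np.nan
        z[masked] = np.nan
        out["log2_ratio"] = log2r
        out["z"] = z
        out["masked"] = masked
        return out


def normalize_against_panel(
    sample: BinCounts,
    panel: Sequence[BinCounts],
    min_panel_median: float = 10.0,
) -> pd.DataFrame:
    """One-shot panel normalization (see :class:`PanelNormalizer`)."""
    return PanelNormalizer(min_panel_median=min_panel_median).fit(panel).transform(sample)


@dataclass
class CNVProfile:
    """Normalized per-bin profile plus called segments."""

    bins: pd.DataFrame  # chrom, start, end, count, log2_ratio, z, masked
    segments: pd.DataFrame  # chrom, start, end, n_bins, mean_log2, call
    sample_id: str = "sample"

    def to_csv(self, prefix: str) -> None:
        self.bins.to_csv(f"{prefix}.bins.csv", index=False)
        self.segments.to_csv(f"{prefix}.segments.csv", index=False)

    @classmethod
    def read_csv(cls, prefix: str, sample_id: str = "sample") -> "CNVProfile":
        bins = pd.read_csv(f"{prefix}.bins.csv", dtype={"chrom": str})
        segments = pd.read_csv(f"{prefix}.segments.csv", dtype={"chrom": str})
        return cls(bins, segments, sample_id)


_SEG_COLUMNS = ["chrom", "start", "end", "n_bins", "mean_log2", "call"]


def call_segments(
    normalized: pd.DataFrame,
    z_threshold: float = 3.0,
    min_bins: int = 5,
    sample_id: str = "sample",
) -> CNVProfile:
    """Call gain/loss segments as maximal same-sign z-score runs.

    A segment is a maximal run of >= ``min_bins`` consecutive unmasked bins
    on one chromosome whose z-scores all exceed +``z_threshold`` (gain) or
    all fall below -``z_threshold`` (loss). Everything else is neutral.
    Deterministic.
    """
    if z_threshold <= 0 or min_bins <= 0:
        raise ValidationError("thresholds must be positive")
    segs = []
    for chrom, grp in normalized.groupby("chrom", sort=False):
        z = grp["z"].to_numpy(dtype=float)
        masked = grp["masked"].to_numpy(dtype=bool)
        sign = np.zeros(len(z), dtype=np.int8)
        with np.errstate(invalid="ignore"):
            sign[(~masked) & (z > z_threshold)] = 1
            sign[(~masked) & (z < -z_threshold)] = -1
        start = 0
        while start < len(sign):
            if sign[start] == 0:
                start += 1
                continue
            end = start
            while end + 1 < len(sign) and sign[end + 1] == sign[start]:
                end += 1
            if end - start + 1 >= min_bins:
                block = grp.iloc[start : end + 1]
                segs.append(
                    {
                        "chrom": chrom,
                        "start": int(block["start"].iloc[0]),
                        "end": int(block["end"].iloc[-1]),
                        "n_bins": end - start + 1,
                        "mean_log2": float(block["log2_ratio"].mean()),
                        "call": "gain" if sign[start] > 0 else "loss",
                    }
                )
            start = end + 1
    segments = pd.DataFrame(segs, columns=_SEG_COLUMNS)
    return CNVProfile(normalized, segments, sample_id)


def compare_profiles(profile_a: CNVProfile, profile_b: CNVProfile) -> pd.DataFrame:
    """Classify segments as shared / a_only / b_only.

    Two same-call segments are shared when their overlap covers at least
    half of the shorter segment (reciprocal-overlap rule). Requires both
    profiles on the same bin grid.
    """
    if not profile_a.bins[_BIN_COLUMNS].equals(profile_b.bins[_BIN_COLUMNS]):
        raise ValidationError("profiles are on different bin grids")
    rows = []

    def overlaps(seg, others) -> bool:
        for _, o in others.iterrows():
            if o["chrom"] != seg["chrom"] or o["call"] != seg["call"]:
                continue
            ov = min(seg["end"], o["end"]) - max(seg["start"], o["start"])
            shorter = min(seg["end"] - seg["start"], o["end"] - o["start"])
            if ov > 0 and ov >= 0.5 * shorter:
                return True
        return False

    for _, seg in profile_a.segments.iterrows():
        status = "shared" if overlaps(seg, profile_b.segments) else "a_only"
        rows.append({**seg.to_dict(), "source": "a", "status": status})
    for _, seg in profile_b.segments.iterrows():
        status = "shared" if overlaps(seg, profile_a.segments) else "b_only"
        rows.append({**seg.to_dict(), "source": "b", "status": status})
    return pd.DataFrame(rows, columns=_SEG_COLUMNS + ["source", "status"])
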