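"""Per-sample quantification: cluster beta vectors and QC metrics.

Turns per-CpG bisulfite methylation calls (Bismark coverage format) into the
per-cluster median-beta observation vector used for deconvolution, and
computes the sample QC metrics: cfDNA fraction from a fragment-length mass
profile (cfDNA defined as fragments of 70-700 bp; longer fragments are
high-molecular-weight contamination) and bisulfite conversion rate from an
unmethylated lambda-phage spike-in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import RegionSet
from .exceptions import ParseError, ValidationError

CALL_COLUMNS = ["chrom", "pos", "count_meth", "count_unmeth"]

#: chromosome names under which lambda spike-in alignments are reported
LAMBDA_CHROMS = ("lambda", "J02459.1")


def read_bismark_coverage(path) -> pd.DataFrame:
    """Parse a Bismark coverage file into methylation calls.

    Expected format: six tab-separated columns
    ``chrom  start  end  pct_methylated  count_meth  count_unmeth`` with
    1-based inclusive positions. The percentage column is ignored (betas are
    recomputed from counts). Records with zero total count are dropped with
    a warning; malformed lines raise :class:`ParseError` with the line
    number.
    """
    records = []
    n_zero = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            try:
                pos = int(parts[1])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos < 1 or meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative count or position < 1")
            if meth + unmeth == 0:
                n_zero += 1
                continue
            records.append((parts[0], pos, meth, unmeth))
    if n_zero:
        warnings.warn(f"{path}: dropped {n_zero} record(s) with zero total count",
                      stacklevel=2)
    if not records:
        warnings.warn(f"{path}: no usable methylation calls", stacklevel=2)
    return pd.DataFrame(records, columns=CALL_COLUMNS)


def write_bismark_coverage(calls: pd.DataFrame, path) -> None:
    """Write methylation calls in Bismark coverage format (round-trips with
    :func:`read_bismark_coverage`)."""
    total = calls["count_meth"] + calls["count_unmeth"]
    pct = np.where(total > 0, 100.0 * calls["count_meth"] / np.maximum(total, 1), 0.0)
    out = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["pos"],
            "end": calls["pos"],
            "pct": np.round(pct, 6),
            "meth": calls["count_meth"],
            "unmeth": calls["count_unmeth"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class ClusterBetaVector:
    """Per-cluster beta observations for one sample (deconvolution's b).

    ``values`` is indexed by cluster_id with columns ``beta`` (median of
    per-CpG betas), ``n_cpgs`` and ``total_reads``.
    """

    sample_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if not {"beta", "n_cpgs", "total_reads"}.issubset(v.columns):
            raise ValidationError("values needs columns beta, n_cpgs, total_reads")
        if len(v) and (v["beta"].lt(0).any() or v["beta"].gt(1).any()):
            raise ValidationError("beta values must lie in [0, 1]")
        if len(v) and v["n_cpgs"].lt(1).any():
            raise ValidationError("present clusters must have n_cpgs >= 1")

    def __len__(self) -> int:
        return len(self.values)

    def beta_series(self) -> pd.Series:
        return self.values["beta"]

    def to_csv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "cluster_id"
        out.to_csv(path)

    @classmethod
    def read_csv(cls, path, sample_id: str) -> "ClusterBetaVector":
        df = pd.read_csv(path, index_col="cluster_id")
        df.index = df.index.astype(str)
        return cls(sample_id, df)


def cluster_betas(
    calls: pd.DataFrame,
    regions: RegionSet,
    min_depth_per_cpg: int = 1,
    min_cpgs_per_cluster: int = 3,
    sample_id: str = "sample",
    pooled: bool = False,
) -> ClusterBetaVector:
    """Summarise per-CpG calls into per-cluster betas.

    Duplicate-position records (e.g. strand-split coverage files) are merged
    by summing counts before betas are computed, making the result invariant
    to record order and row splitting. CpGs with depth below
    ``min_depth_per_cpg`` are ignored; clusters with fewer than
    ``min_cpgs_per_cluster`` qualifying CpGs are absent from the vector.

    With ``pooled=True`` the cluster beta is the pooled-count ratio
    Σmeth/Σtotal instead of the default median of per-CpG betas.
    """
    if min_depth_per_cpg < 1 or min_cpgs_per_cluster < 1:
        raise ValidationError("thresholds must be >= 1")
    if calls.empty:
        return ClusterBetaVector(
            sample_id,
            pd.DataFrame(columns=["beta", "n_cpgs", "total_reads"],
                         index=pd.Index([], name="cluster_id")),
        )
    merged = calls.groupby(["chrom", "pos"], as_index=False, sort=False)[
        ["count_meth", "count_unmeth"]
    ].sum()
    depth = merged["count_meth"] + merged["count_unmeth"]
    merged = merged[depth >= min_depth_per_cpg].copy()
    merged["depth"] = merged["count_meth"] + merged["count_unmeth"]
    # Bismark positions are 1-based; clusters are 0-based half-open.
    merged["cluster_id"] = regions.assign(merged["chrom"], merged["pos"] - 1)
    merged = merged[merged["cluster_id"].notna()]
    if merged.empty:
        return ClusterBetaVector(
            sample_id,
            pd.DataFrame(columns=["beta", "n_cpgs", "total_reads"],
                         index=pd.Index([], name="cluster_id")),
        )
    merged["cpg_beta"] = merged["count_meth"] / merged["depth"]
    grouped = merged.groupby("cluster_id", sort=False)
    if pooled:
        beta = grouped["count_meth"].sum() / grouped["depth"].sum()
    else:
        beta = grouped["cpg_beta"].median()
    out = pd.DataFrame(
        {
            "beta": beta,
            "n_cpgs": grouped.size(),
            "total_reads": grouped["depth"].sum(),
        }
    )
    out = out[out["n_cpgs"] >= min_cpgs_per_cluster]
    order = [c for c in regions.cluster_ids if c in out.index]
    out = out.loc[order]
    out.index.name = "cluster_id"
    return ClusterBetaVector(sample_id, out)


def read_fragment_profile(path) -> pd.DataFrame:
    """Read a fragment-length mass profile CSV (length_bp, mass_ng)."""
    df = pd.read_csv(path)
    if not {"length_bp", "mass_ng"}.issubset(df.columns):
        raise ParseError(f"{path}: fragment profile needs columns length_bp, mass_ng")
    return df[["length_bp", "mass_ng"]]


def cfdna_fraction(profile: pd.DataFrame, low: int = 70, high: int = 700) -> float:
    """Fraction of DNA mass in the cfDNA size range (bounds inclusive).

    cfDNA is defined as fragments of ``low``-``high`` bp (default 70-700);
    mass above ``high`` bp is high-molecular-weight contamination. The
    fraction is scale-invariant in total mass.
    """
    lengths = profile["length_bp"].to_numpy(dtype=float)
    mass = profile["mass_ng"].to_numpy(dtype=float)
    if (mass < 0).any():
        raise ValidationError("fragment masses must be >= 0")
    total = mass.sum()
    if total <= 0:
        raise ValidationError("total fragment mass is zero; cfDNA fraction undefined")
    in_range = (lengths >= low) & (lengths <= high)
    return float(mass[in_range].sum() / total)


def bisulfite_conversion_rate(
    lambda_calls: pd.DataFrame, lambda_chroms: Sequence[str] = LAMBDA_CHROMS
) -> float | None:
    """Bisulfite conversion rate from the unmethylated lambda spike-in.

    The lambda genome carries no methylation, so every methylated call on it
    is a conversion failure: rate = unmeth / (meth + unmeth) over lambda
    records. Returns None (missing-QC) when no lambda cytosine was observed.
    """
    sub = lambda_calls[lambda_calls["chrom"].isin(set(lambda_chroms))]
    meth = int(sub["count_meth"].sum())
    unmeth = int(sub["count_unmeth"].sum())
    if meth + unmeth == 0:
        return None
    return unmeth / (meth + unmeth)


@dataclass
class SampleQC:
    """Per-sample QC record."""

    sample_id: str
    cfdna_fraction: float | None = None
    total_dna_mass: float | None = None
    bisulfite_conversion: float | None = None
    n_clusters_covered: int = 0

    def __post_init__(self) -> None:
        for name in ("cfdna_fraction", "bisulfite_conversion"):
            val = getattr(self, name)
            if val is not None and not (0.0 <= val <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "SampleQC":
        with open(path) as fh:
            return cls(**json.load(fh))
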