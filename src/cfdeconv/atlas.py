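"""Reference-atlas construction for methylation deconvolution.

The deconvolution design matrix pairs genomic *clusters* — MspI restriction
fragments of a reduced-representation bisulfite assay that overlap
methylation-array probes — with reference methylation profiles (one column
per reference sample, each labelled with a tumor entity or a non-tumoral
background such as healthy plasma cfDNA or white blood cells).

Coordinates are 0-based half-open internally; 1-based inputs (array probe
manifests, Bismark coverage) are converted at the reader boundary.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError

_REGION_COLUMNS = ["chrom", "start", "end", "cluster_id"]

# MspI recognises CCGG and cuts between the first and second C (C^CGG), so a
# fragment boundary sits one base into each site.
_MSPI_SITE = re.compile(r"(?=CCGG)")
_CUT_OFFSET = 1

_VALID_SEQ = re.compile(r"^[ACGTNacgtn]*$")


@dataclass
class RegionSet:
    """Ordered, non-overlapping genomic clusters with unique identifiers.

    ``regions`` holds columns ``chrom, start, end, cluster_id`` with 0-based
    half-open intervals. Regions are sorted by (chrom, start) on construction.
    """

    regions: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.regions, columns=_REGION_COLUMNS).copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["cluster_id"] = df["cluster_id"].astype(str)
        if (df["start"] >= df["end"]).any():
            raise ValidationError("regions must satisfy start < end")
        if df["cluster_id"].duplicated().any():
            dup = df.loc[df["cluster_id"].duplicated(), "cluster_id"].iloc[0]
            raise ValidationError(f"duplicate cluster_id {dup!r}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for _, grp in df.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValidationError("regions within a chromosome must not overlap")
        self.regions = df

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def cluster_ids(self) -> list[str]:
        return self.regions["cluster_id"].tolist()

    def assign(self, chroms: Iterable[str], positions: Iterable[int]) -> np.ndarray:
        """Map 0-based positions to the cluster_id containing them (else None).

        Containment is half-open: ``start <= pos < end``.
        """
        chroms = np.asarray(list(chroms), dtype=object)
        positions = np.asarray(list(positions), dtype=np.int64)
        out = np.full(len(positions), None, dtype=object)
        for chrom, grp in self.regions.groupby("chrom", sort=False):
            mask = chroms == chrom
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            ids = grp["cluster_id"].to_numpy()
            pos = positions[mask]
            idx = np.searchsorted(starts, pos, side="right") - 1
            inside = idx >= 0
            idx_c = np.clip(idx, 0, None)
            inside &= pos < ends[idx_c]
            vals = np.full(len(pos), None, dtype=object)
            vals[inside] = ids[idx_c[inside]]
            out[mask] = vals
        return out

    def to_bed(self, path) -> None:
        self.regions.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path) -> "RegionSet":
        df = pd.read_csv(
            path, sep="\t", header=None, names=_REGION_COLUMNS, dtype={0: str, 3: str}
        )
        return cls(df)


def insilico_mspi_digest(sequences, min_len: int = 20, max_len: int = 200) -> RegionSet:
    """In-silico MspI digest, keeping internal fragments within a size window.

    Parameters
    ----------
    sequences
        Mapping ``name -> sequence`` or an iterable of ``(name, sequence)``
        pairs (Bio.SeqIO records also work: ``{r.id: str(r.seq)}``).
    min_len, max_len
        Size-selection window in bp, inclusive at both ends. The assay
        enriches short CpG-rich fragments, so only fragments between two
        consecutive CCGG cut sites are retained (terminal fragments lack a
        second cut site and are discarded).

    Returns
    -------
    RegionSet with 0-based half-open fragment intervals and cluster ids of
    the form ``{chrom}:{start}-{end}``.
    """
    if not (0 < min_len < max_len):
        raise ValidationError("require 0 < min_len < max_len")
    rows = []
    for chrom, seq in _iter_sequences(sequences):
        s = str(seq).upper()
        if not _VALID_SEQ.match(s):
            raise ValidationError(f"sequence {chrom!r} contains non-ACGTN characters")
        cuts = [m.start() + _CUT_OFFSET for m in _MSPI_SITE.finditer(s)]
        for a, b in zip(cuts, cuts[1:]):
            if min_len <= b - a <= max_len:
                rows.append((chrom, a, b, f"{chrom}:{a}-{b}"))
    return RegionSet(pd.DataFrame(rows, columns=_REGION_COLUMNS))


def _iter_sequences(sequences):
    if isinstance(sequences, Mapping):
        return sequences.items()
    return iter(sequences)


def read_probe_manifest(path) -> pd.DataFrame:
    """Read a probe manifest CSV (probe_id, chrom, pos[, strand]; pos 1-based).

    Returns a DataFrame with 0-based ``pos``.
    """
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise ParseError(f"{path}: probe manifest missing column {col!r}")
    bad = df.index[~df["pos"].apply(lambda v: isinstance(v, (int, np.integer)) and v >= 1)]
    if len(bad):
        raise ParseError(f"{path}: line {bad[0] + 2}: malformed probe coordinate")
    out = df[["probe_id", "chrom", "pos"]].copy()
    out["pos"] = out["pos"].astype(np.int64) - 1
    return out


def assign_probes_to_clusters(
    probes: pd.DataFrame, regions: RegionSet
) -> tuple[dict[str, str], int]:
    """Assign array probes (0-based ``pos``) to containing clusters.

    Each probe maps to at most one cluster (regions are non-overlapping);
    probes outside every region are dropped and counted.

    Returns ``(probe_id -> cluster_id, n_dropped)``.
    """
    assigned = regions.assign(probes["chrom"], probes["pos"])
    mapping = {
        pid: cid
        for pid, cid in zip(probes["probe_id"], assigned)
        if cid is not None
    }
    return mapping, int(sum(c is None for c in assigned))


@dataclass
class Atlas:
    """Clusters × reference-columns beta matrix with entity annotations.

    ``beta`` is indexed by cluster_id with one column per reference sample
    (NaN marks clusters not covered by that sample). ``columns`` is indexed
    by column_id with fields ``entity`` and ``is_tumoral``. Missing values
    are propagated, never imputed.
    """

    beta: pd.DataFrame
    columns: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.beta.columns) != list(self.columns.index):
            raise ValidationError("atlas beta columns and column annotations disagree")
        if (self.columns["entity"].astype(str) == "").any():
            raise ValidationError("entity labels must be non-empty")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                raise ValidationError("atlas beta values must lie in [0, 1]")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def n_columns(self) -> int:
        return self.beta.shape[1]

    def entity_of(self) -> pd.Series:
        return self.columns["entity"]

    def collapse_to_entity_medians(self) -> "Atlas":
        """Optional per-entity collapse: one column per entity, median over
        that entity's reference samples (NaN-aware)."""
        groups = self.columns.groupby("entity", sort=False)
        cols, meta = {}, []
        for entity, grp in groups:
            cols[entity] = self.beta[grp.index].median(axis=1, skipna=True)
            meta.append((entity, entity, bool(grp["is_tumoral"].iloc[0])))
        beta = pd.DataFrame(cols)
        columns = pd.DataFrame(
            [(e, t) for _, e, t in meta],
            index=[c for c, _, _ in meta],
            columns=["entity", "is_tumoral"],
        )
        columns.index.name = "column_id"
        return Atlas(beta, columns)

    def to_csv(self, prefix: str) -> None:
        """Write ``{prefix}.csv`` (beta, first column cluster_id, empty cells
        for missing) and ``{prefix}.columns.csv`` (column annotations)."""
        out = self.beta.copy()
        out.index.name = "cluster_id"
        out.to_csv(f"{prefix}.csv")
        cols = self.columns.copy()
        cols.index.name = "column_id"
        cols.to_csv(f"{prefix}.columns.csv")

    @classmethod
    def read_csv(cls, prefix: str) -> "Atlas":
        beta = pd.read_csv(f"{prefix}.csv", index_col="cluster_id")
        beta.index = beta.index.astype(str)
        columns = pd.read_csv(f"{prefix}.columns.csv", index_col="column_id")
        columns.index = columns.index.astype(str)
        columns["is_tumoral"] = columns["is_tumoral"].astype(bool)
        return cls(beta, columns)


def build_atlas(
    reference_profiles: pd.DataFrame,
    probe_cluster_map: Mapping[str, str],
    entity_labels: Mapping[str, str],
    min_probes_per_cluster: int = 1,
) -> Atlas:
    """Summarise per-probe reference betas into a cluster-level atlas.

    Each atlas cell is the median of that sample's probe betas within the
    cluster; clusters backed by fewer than ``min_probes_per_cluster``
    observed probes in a sample are missing (NaN) for that column. Column
    order follows ``reference_profiles`` and is stable; the result is
    invariant to probe order within a cluster.
    """
    if min_probes_per_cluster < 1:
        raise ValidationError("min_probes_per_cluster must be >= 1")
    missing_labels = [s for s in reference_profiles.columns if s not in entity_labels]
    if missing_labels:
        raise ValidationError(f"reference samples without entity label: {missing_labels}")

    keep = reference_profiles.index[reference_profiles.index.isin(probe_cluster_map)]
    sub = reference_profiles.loc[keep]
    clusters = pd.Index([probe_cluster_map[p] for p in sub.index], name="cluster_id")
    grouped = sub.groupby(clusters, sort=True)
    med = grouped.median()
    counts = grouped.count()
    med = med.where(counts >= min_probes_per_cluster)

    kept_cols = []
    for sample in reference_profiles.columns:
        if sample in med.columns and med[sample].notna().any():
            kept_cols.append(sample)
        else:
            warnings.warn(
                f"reference sample {sample!r} has no cluster with enough probes; excluded",
                stacklevel=2,
            )
    med = med[kept_cols]
    columns = pd.DataFrame(
        {"entity": [entity_labels[s] for s in kept_cols],
         "is_tumoral": [True] * len(kept_cols)},
        index=pd.Index(kept_cols, name="column_id"),
    )
    return Atlas(med, columns)


def append_background_columns(atlas: Atlas, background_profiles, labels) -> Atlas:
    """Append non-tumoral background columns (e.g. healthy cfDNA, WBC).

    ``background_profiles`` is a list of per-cluster beta vectors
    (:class:`~cfdeconv.quant.ClusterBetaVector`) measured on the same
    RegionSet as the atlas; clusters absent from a background profile become
    NaN, and a profile naming unknown clusters is a validation error.
    Cluster ordering is unchanged.
    """
    background_profiles = list(background_profiles)
    labels = list(labels)
    if len(background_profiles) != len(labels):
        raise ValidationError("one label per background profile required")
    if not background_profiles:
        return Atlas(atlas.beta.copy(), atlas.columns.copy())

    beta = atlas.beta.copy()
    meta = atlas.columns.copy()
    for profile, label in zip(background_profiles, labels):
        series = profile.beta_series()
        unknown = series.index.difference(beta.index)
        if len(unknown):
            raise ValidationError(
                f"background {profile.sample_id!r} covers clusters outside the atlas "
                f"RegionSet (e.g. {unknown[0]!r})"
            )
        col_id = profile.sample_id
        if col_id in beta.columns:
            raise ValidationError(f"duplicate column id {col_id!r}")
        beta[col_id] = series.reindex(beta.index)
        meta.loc[col_id] = {"entity": label, "is_tumoral": False}
    return Atlas(beta, meta)
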