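"""Nonnegative least-squares deconvolution of methylation beta vectors.

A sample's per-cluster beta vector b is modelled as a nonnegative mixture of
reference profiles (the atlas columns A): solve min ||Ax - b||_2 subject to
x >= 0, then normalize x by its sum so the weights read as relative
contributions. Column weights are aggregated to entity fractions; the
estimated tumor fraction (ETF) is the summed weight of tumoral entities, and
the predicted entity is the tumoral entity with the highest fraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator

from .atlas import Atlas
from .exceptions import InsufficientOverlapError, ValidationError
from .quant import ClusterBetaVector

_TIE_ATOL = 1e-12


@dataclass
class DeconvolutionResult:
    """Normalized mixture estimate for one sample.

    ``entity_fractions`` sums to 1 over all entities; ``etf`` is the summed
    fraction of tumoral entities. ``tumor_relative_fractions`` re-normalizes
    the tumoral weights among themselves (the alternative reporting
    convention); it is empty when no tumoral signal was estimated.
    """

    sample_id: str
    column_weights: dict[str, float]
    entity_fractions: dict[str, float]
    etf: float
    predicted_entity: str | None
    n_clusters_used: int
    residual_norm: float
    tumor_relative_fractions: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    tie: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def read_json(cls, path) -> "DeconvolutionResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def aggregate_entities(
    column_weights: Mapping[str, float], column_entities: Mapping[str, str]
) -> dict[str, float]:
    """Sum per-column weights into per-entity fractions.

    The atlas keeps one column per reference sample, so several columns can
    share an entity label. Fractions conserve the total weight.
    """
    unmapped = [c for c in column_weights if c not in column_entities]
    if unmapped:
        raise ValidationError(f"columns without entity mapping: {unmapped}")
    out: dict[str, float] = {}
    for col, w in column_weights.items():
        out[column_entities[col]] = out.get(column_entities[col], 0.0) + float(w)
    return out


def estimated_tumor_fraction(
    entity_fractions: Mapping[str, float], is_tumoral: Mapping[str, bool]
) -> float:
    """ETF = summed tumoral fractions = 1 - summed non-tumoral fractions."""
    missing = [e for e in entity_fractions if e not in is_tumoral]
    if missing:
        raise ValidationError(f"entities without tumoral flag: {missing}")
    return float(sum(f for e, f in entity_fractions.items() if is_tumoral[e]))


def classify(
    entity_fractions: Mapping[str, float], is_tumoral: Mapping[str, bool]
) -> tuple[str | None, bool]:
    """Predicted entity: argmax over tumoral entities only.

    Non-tumoral signal never drives the call. Exact ties are broken
    lexicographically and flagged; if every tumoral fraction is 0 the
    prediction is None. Returns ``(entity_or_None, tie_flag)``.
    """
    tumoral = {e: f for e, f in entity_fractions.items() if is_tumoral.get(e, False)}
    if not any(is_tumoral.get(e, False) for e in entity_fractions):
        raise ValidationError("atlas contains no tumoral entities")
    best = max(tumoral.values())
    if best <= 0.0:
        return None, False
    tied = sorted(e for e, f in tumoral.items() if abs(f - best) <= _TIE_ATOL)
    return tied[0], len(tied) > 1


class MethylationDeconvolver(BaseEstimator):
    """NNLS mixture estimator over a methylation reference atlas.

    Fits on reference profiles (rows = reference columns, features =
    clusters, NaN = missing) with entity labels and tumoral flags; then
    deconvolves sample beta vectors into normalized component weights,
    entity fractions, estimated tumor fraction and a predicted entity.

    Parameters
    ----------
    min_clusters : int
        Floor on the number of clusters jointly covered by the sample and
        every retained atlas column; below it deconvolution refuses to run.
    unknown_component : bool
        Append a uniform-beta (0.5) non-tumoral column that can absorb
        unmodeled signal.

    Attributes (after fit)
    ----------------------
    components_ : ndarray (n_columns, n_clusters) reference betas (NaN ok)
    column_ids_, entities_, is_tumoral_ : per-column annotations
    cluster_ids_ : feature names (cluster ids)
    entity_names_ : unique entity labels, first-appearance order
    """

    def __init__(self, min_clusters: int = 50, unknown_component: bool = False):
        self.min_clusters = min_clusters
        self.unknown_component = unknown_component

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, *, tumoral=None, column_ids=None, cluster_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2d (n_reference_columns, n_clusters)")
        y = np.asarray(y, dtype=object)
        if len(y) != X.shape[0]:
            raise ValidationError("one entity label per reference row required")
        if tumoral is None:
            warnings.warn("no tumoral flags given; assuming every column is tumoral",
                          stacklevel=2)
            tumoral = np.ones(X.shape[0], dtype=bool)
        tumoral = np.asarray(tumoral, dtype=bool)
        if not tumoral.any():
            raise ValidationError("atlas contains no tumoral columns")

        if column_ids is None:
            column_ids = [f"ref{i}" for i in range(X.shape[0])]
        if cluster_ids is None:
            cluster_ids = [f"c{i}" for i in range(X.shape[1])]

        if self.unknown_component:
            X = np.vstack([X, np.full((1, X.shape[1]), 0.5)])
            y = np.append(y, "unknown")
            tumoral = np.append(tumoral, False)
            column_ids = list(column_ids) + ["unknown"]

        self.components_ = X
        self.column_ids_ = list(map(str, column_ids))
        self.entities_ = [str(e) for e in y]
        self.is_tumoral_ = tumoral
        self.cluster_ids_ = list(map(str, cluster_ids))
        self.entity_names_ = list(dict.fromkeys(self.entities_))
        self.entity_is_tumoral_ = {}
        for ent, flag in zip(self.entities_, self.is_tumoral_):
            if ent in self.entity_is_tumoral_ and self.entity_is_tumoral_[ent] != bool(flag):
                raise ValidationError(f"entity {ent!r} has inconsistent tumoral flags")
            self.entity_is_tumoral_[ent] = bool(flag)
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_atlas(cls, atlas: Atlas, **params) -> "MethylationDeconvolver":
        est = cls(**params)
        return est.fit(
            atlas.beta.to_numpy(dtype=float).T,
            atlas.columns["entity"].to_numpy(),
            tumoral=atlas.columns["is_tumoral"].to_numpy(),
            column_ids=list(atlas.beta.columns),
            cluster_ids=list(atlas.beta.index),
        )

    # -- solving -----------------------------------------------------------

    def _solve(self, b: np.ndarray, sample_id: str) -> DeconvolutionResult:
        A = self.components_.T  # (n_clusters, n_columns)
        # complete-case filtering: a cluster enters only if observed in the
        # sample and in every atlas column (missing is never imputed)
        keep = np.isfinite(b) & np.all(np.isfinite(A), axis=1)
        n_used = int(keep.sum())
        if n_used < self.min_clusters:
            raise InsufficientOverlapError(
                f"sample {sample_id!r}: only {n_used} clusters jointly covered "
                f"(floor {self.min_clusters})"
            )
        x, rnorm = nnls(A[keep], b[keep])
        total = float(x.sum())
        degenerate = total <= 0.0
        weights = x / total if not degenerate else x
        column_weights = dict(zip(self.column_ids_, map(float, weights)))
        entity_fractions = aggregate_entities(
            column_weights, dict(zip(self.column_ids_, self.entities_))
        )
        if degenerate:
            return DeconvolutionResult(
                sample_id=sample_id,
                column_weights=column_weights,
                entity_fractions=entity_fractions,
                etf=0.0,
                predicted_entity=None,
                n_clusters_used=n_used,
                residual_norm=float(rnorm),
                degenerate=True,
            )
        etf = estimated_tumor_fraction(entity_fractions, self.entity_is_tumoral_)
        predicted, tie = classify(entity_fractions, self.entity_is_tumoral_)
        tumor_rel = {}
        if etf > 0:
            tumor_rel = {
                e: f / etf
                for e, f in entity_fractions.items()
                if self.entity_is_tumoral_[e]
            }
        return DeconvolutionResult(
            sample_id=sample_id,
            column_weights=column_weights,
            entity_fractions=entity_fractions,
            etf=etf,
            predicted_entity=predicted,
            n_clusters_used=n_used,
            residual_norm=float(rnorm),
            tumor_relative_fractions=tumor_rel,
            tie=tie,
        )

    def _align(self, sample) -> tuple[np.ndarray, str]:
        if isinstance(sample, ClusterBetaVector):
            series = sample.beta_series()
            sid = sample.sample_id
        elif isinstance(sample, pd.Series):
            series = sample
            sid = str(sample.name) if sample.name is not None else "sample"
        else:
            arr = np.asarray(sample, dtype=float)
            if arr.shape != (self.n_features_in_,):
                raise ValidationError("sample vector length does not match atlas clusters")
            return arr, "sample"
        return series.reindex(self.cluster_ids_).to_numpy(dtype=float), sid

    def deconvolve(self, sample) -> DeconvolutionResult:
        """Full deconvolution of one sample (ClusterBetaVector, Series
        indexed by cluster_id, or a plain aligned vector)."""
        b, sid = self._align(sample)
        return self._solve(b, sid)

    def transform(self, X) -> np.ndarray:
        """Entity-fraction matrix (n_samples, n_entities), columns ordered
        as ``entity_names_``."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        out = np.zeros((X.shape[0], len(self.entity_names_)))
        for i, row in enumerate(X):
            res = self._solve(row, f"sample{i}")
            for j, ent in enumerate(self.entity_names_):
                out[i, j] = res.entity_fractions.get(ent, 0.0)
        return out

    def fit_transform(self, X, y=None, **fit_params):  # pragma: no cover - sklearn API
        raise NotImplementedError("fit on a reference atlas, then transform samples")

    def predict(self, X) -> np.ndarray:
        """Predicted tumor entity per sample (None where degenerate or no
        tumoral signal)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.array(
            [self._solve(row, f"sample{i}").predicted_entity for i, row in enumerate(X)],
            dtype=object,
        )


def nnls_deconvolve(
    atlas: Atlas,
    sample: ClusterBetaVector,
    min_clusters: int = 50,
    unknown_component: bool = False,
) -> DeconvolutionResult:
    """One-shot deconvolution of a sample against an atlas."""
    est = MethylationDeconvolver.from_atlas(
        atlas, min_clusters=min_clusters, unknown_component=unknown_component
    )
    return est.deconvolve(sample)
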