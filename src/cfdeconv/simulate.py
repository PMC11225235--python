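"""Synthetic-data generators with known ground truth.

Every downstream stage (atlas construction, quantification, deconvolution,
gating, CNV calling) is testable without access-controlled sequencing data:
the generators emulate entity-distinct methylation profiles over thousands
of clusters, binomial read sampling at low coverage, mixtures of one tumor
entity with non-tumoral background (healthy cfDNA and white blood cells),
dilution of tumor signal by high-molecular-weight DNA, and segmental
copy-number aberrations on a 400-kb bin grid. All generators are pure
functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import Atlas, RegionSet
from .cnv import BinCounts, make_bins
from .exceptions import ValidationError
from .quant import ClusterBetaVector, write_bismark_coverage

BACKGROUND_ENTITIES = ("healthy_cfDNA", "WBC")

_FRAC_TOL = 1e-9

# cfDNA fragment-length model: mononucleosomal mode ~167 bp inside the
# 70-700 bp window; HMW contamination placed well above 700 bp.
_CFDNA_MODE, _CFDNA_SD = 167.0, 40.0
_CFDNA_RANGE = (70, 700)
_HMW_MODE, _HMW_SD = 1500.0, 300.0
_HMW_RANGE = (701, 3000)


@dataclass(frozen=True)
class TrueAtlas:
    """Ground-truth reference: per-region betas for each entity.

    The last two entities are the non-tumoral backgrounds (healthy cfDNA and
    WBC). Each entity owns a disjoint set of marker regions where its beta
    differs from the shared baseline by at least ``margin``; elsewhere all
    entities share a common per-region baseline.
    """

    entities: tuple[str, ...]
    beta: np.ndarray  # (n_regions, n_entities)
    marker_map: dict[str, np.ndarray]
    margin: float
    seed: int

    @property
    def n_regions(self) -> int:
        return self.beta.shape[0]

    @property
    def tumor_entities(self) -> tuple[str, ...]:
        return tuple(e for e in self.entities if e not in BACKGROUND_ENTITIES)

    def is_tumoral(self, entity: str) -> bool:
        return entity not in BACKGROUND_ENTITIES

    def cluster_ids(self) -> list[str]:
        return [f"cluster_{r:05d}" for r in range(self.n_regions)]

    def region_set(self, chrom: str = "chr1", spacing: int = 1000,
                   region_length: int = 200) -> RegionSet:
        """Lay the regions out on a synthetic chromosome."""
        starts = np.arange(self.n_regions, dtype=np.int64) * spacing
        df = pd.DataFrame(
            {
                "chrom": chrom,
                "start": starts,
                "end": starts + region_length,
                "cluster_id": self.cluster_ids(),
            }
        )
        return RegionSet(df)

    def to_reference_atlas(self) -> Atlas:
        """Deconvolution-ready atlas (one column per entity, no noise)."""
        beta = pd.DataFrame(
            self.beta, index=pd.Index(self.cluster_ids(), name="cluster_id"),
            columns=list(self.entities),
        )
        columns = pd.DataFrame(
            {
                "entity": list(self.entities),
                "is_tumoral": [self.is_tumoral(e) for e in self.entities],
            },
            index=pd.Index(list(self.entities), name="column_id"),
        )
        return Atlas(beta, columns)


def simulate_atlas(
    n_entities: int,
    n_regions: int,
    markers_per_entity: int,
    margin: float = 0.5,
    seed: int = 0,
) -> TrueAtlas:
    """Generate a ground-truth atlas with disjoint marker architecture.

    ``n_entities`` counts all components including the two non-tumoral
    backgrounds (so it must be >= 3). Marker regions flip the owning
    entity's beta away from the shared baseline by exactly ``margin``
    (hyper- or hypomethylated at random); non-marker regions share one
    baseline beta drawn per region. Deterministic given ``seed``.
    """
    if n_entities < 3:
        raise ValidationError("need >= 3 entities (>= 1 tumoral + 2 backgrounds)")
    if not 0 < margin <= 1:
        raise ValidationError("margin must lie in (0, 1]")
    if markers_per_entity < 1:
        raise ValidationError("markers_per_entity must be >= 1")
    if markers_per_entity * n_entities > n_regions:
        raise ValidationError(
            f"infeasible marker allocation: {markers_per_entity} x {n_entities} "
            f"> {n_regions} regions"
        )
    rng = np.random.default_rng(seed)
    entities = tuple(
        [f"TUM{i + 1:02d}" for i in range(n_entities - 2)] + list(BACKGROUND_ENTITIES)
    )
    baseline = rng.uniform(0.0, 1.0, size=n_regions)
    perm = rng.permutation(n_regions)
    beta = np.tile(baseline[:, None], (1, n_entities))
    marker_map: dict[str, np.ndarray] = {}
    for k, entity in enumerate(entities):
        idx = np.sort(perm[k * markers_per_entity : (k + 1) * markers_per_entity])
        marker_map[entity] = idx
        hyper = rng.random(len(idx)) < 0.5
        base = np.where(
            hyper,
            rng.uniform(0.0, 1.0 - margin, size=len(idx)),
            rng.uniform(margin, 1.0, size=len(idx)),
        )
        marker = np.where(hyper, base + margin, base - margin)
        beta[idx, :] = base[:, None]
        beta[idx, k] = marker
    return TrueAtlas(entities, beta, marker_map, margin, seed)


def simulate_sample(
    atlas: TrueAtlas,
    fractions: Mapping[str, float],
    mean_coverage: float,
    seed: int = 0,
    dispersion: float = 0.0,
) -> pd.DataFrame:
    """Binomial read sampling of a mixture over the atlas regions.

    Per region r the mixed beta is m_r = sum_k w_k * beta[r, k]; the total
    read count is Poisson(``mean_coverage``) and the methylated count is
    Binomial(total, m_r). With ``dispersion`` > 0 the per-region success
    probability is drawn from Beta(m_r/dispersion, (1-m_r)/dispersion)
    (beta-binomial overdispersion; mean preserved, extra variance grows with
    dispersion). Returns a DataFrame with columns ``region``,
    ``count_meth``, ``count_total``.
    """
    w = _validate_fractions(atlas, fractions)
    if mean_coverage < 0:
        raise ValidationError("mean_coverage must be >= 0")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    mixed = np.clip(atlas.beta @ w, 0.0, 1.0)
    total = rng.poisson(mean_coverage, size=atlas.n_regions)
    if dispersion > 0:
        interior = (mixed > 0) & (mixed < 1)
        p = mixed.copy()
        p[interior] = rng.beta(
            mixed[interior] / dispersion, (1.0 - mixed[interior]) / dispersion
        )
    else:
        p = mixed
    meth = rng.binomial(total, p)
    return pd.DataFrame(
        {"region": np.arange(atlas.n_regions), "count_meth": meth, "count_total": total}
    )


def _validate_fractions(atlas: TrueAtlas, fractions: Mapping[str, float]) -> np.ndarray:
    if set(fractions) != set(atlas.entities):
        raise ValidationError("fractions must name exactly the atlas entities")
    w = np.array([fractions[e] for e in atlas.entities], dtype=float)
    if (w < 0).any():
        raise ValidationError("fractions must be nonnegative")
    if abs(w.sum() - 1.0) > _FRAC_TOL:
        raise ValidationError(f"fractions sum to {w.sum()}, not 1")
    return w


def region_counts_to_beta_vector(
    counts: pd.DataFrame, atlas: TrueAtlas, sample_id: str = "sample"
) -> ClusterBetaVector:
    """Turn per-region simulated counts into a deconvolution observation."""
    covered = counts[counts["count_total"] > 0]
    ids = np.array(atlas.cluster_ids(), dtype=object)[covered["region"].to_numpy()]
    values = pd.DataFrame(
        {
            "beta": covered["count_meth"].to_numpy()
            / covered["count_total"].to_numpy(),
            "n_cpgs": 1,
            "total_reads": covered["count_total"].to_numpy(),
        },
        index=pd.Index(ids, name="cluster_id"),
    )
    return ClusterBetaVector(sample_id, values)


def simulate_fragment_profile(
    cfdna_mass: float, hmw_mass: float, seed: int = 0
) -> pd.DataFrame:
    """Fragment-length mass table (1-bp bins) for a cfDNA / HMW mixture.

    cfDNA mass follows a truncated Gaussian centred at ~167 bp entirely
    inside the 70-700 bp window; HMW mass sits entirely above 700 bp.
    Total mass is conserved exactly (weights are normalized per component).
    The length densities are deterministic; ``seed`` is accepted for API
    uniformity across generators.
    """
    if cfdna_mass < 0 or hmw_mass < 0:
        raise ValidationError("masses must be >= 0")
    if cfdna_mass == 0 and hmw_mass == 0:
        raise ValidationError("at least one of cfdna_mass/hmw_mass must be positive")
    frames = []
    if cfdna_mass > 0:
        frames.append(_gaussian_mass(_CFDNA_RANGE, _CFDNA_MODE, _CFDNA_SD, cfdna_mass))
    if hmw_mass > 0:
        frames.append(_gaussian_mass(_HMW_RANGE, _HMW_MODE, _HMW_SD, hmw_mass))
    return pd.concat(frames, ignore_index=True)


def _gaussian_mass(length_range, mode, sd, mass) -> pd.DataFrame:
    lengths = np.arange(length_range[0], length_range[1] + 1)
    w = np.exp(-0.5 * ((lengths - mode) / sd) ** 2)
    w = w / w.sum() * mass
    keep = w > 0
    return pd.DataFrame({"length_bp": lengths[keep], "mass_ng": w[keep]})


def simulate_cnv_bins(
    genome: Mapping[str, int],
    binsize: int,
    segments: Sequence[tuple[str, int, int, float]],
    tumor_fraction: float,
    depth: float,
    n_panel: int,
    seed: int = 0,
) -> tuple[BinCounts, list[BinCounts]]:
    """Poisson bin counts for a sample with segmental CNAs plus a panel.

    Bins overlapping an aberrant segment have expectation
    ``depth * (1 + tumor_fraction * (copy_ratio - 1))``; all other bins and
    every panel bin have expectation ``depth``.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValidationError("tumor_fraction must lie in [0, 1]")
    if depth <= 0:
        raise ValidationError("depth must be positive")
    if n_panel < 0:
        raise ValidationError("n_panel must be >= 0")
    bins = make_bins(genome, binsize)
    expected = np.full(len(bins), float(depth))
    for chrom, start, end, ratio in segments:
        if ratio <= 0:
            raise ValidationError("copy_ratio must be positive")
        if chrom not in genome or start < 0 or end > genome[chrom] or start >= end:
            raise ValidationError(f"segment {chrom}:{start}-{end} outside genome")
        hit = (
            (bins["chrom"] == chrom)
            & (bins["start"] < end)
            & (bins["end"] > start)
        ).to_numpy()
        expected[hit] = depth * (1.0 + tumor_fraction * (ratio - 1.0))
    rng = np.random.default_rng(seed)
    sample = BinCounts(bins, rng.poisson(expected), "tumor_sample")
    panel = [
        BinCounts(bins, rng.poisson(depth, size=len(bins)), f"normal{i:02d}")
        for i in range(n_panel)
    ]
    return sample, panel


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated sample."""

    fractions: dict[str, float]
    cfdna_fraction_true: float
    coverage: float
    cnv_segments: tuple = ()

    def __post_init__(self) -> None:
        w = np.array(list(self.fractions.values()), dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValidationError("true fractions must be >= 0 and sum to 1")
        for seg in self.cnv_segments:
            if seg[3] <= 0:
                raise ValidationError("copy_ratio must be positive")


@dataclass
class CohortSample:
    """One simulated sample with its ground truth."""

    sample_id: str
    entity: str
    tumor_fraction: float
    truth: SimTruth
    counts: pd.DataFrame
    fragment_profile: pd.DataFrame
    seed: int


def simulate_mixture_cohort(
    atlas: TrueAtlas,
    fractions_grid: Sequence[float],
    samples_per_fraction: int,
    mean_coverage: float,
    total_mass_ng: float = 10.0,
    seed: int = 0,
) -> list[CohortSample]:
    """Cohort of one-tumor-entity mixtures spanning a tumor-fraction grid.

    Each sample mixes one tumor entity at weight f with the two backgrounds.
    The cfDNA fraction c is coupled to f as c = f + (1 - f) * U(0, 1): the
    HMW-derived share (1 - c) is carried by the WBC background and the
    remaining c - f by healthy cfDNA, so poor-quality samples (low c)
    necessarily carry weak tumor signal — the regime the confidence gate is
    designed to flag. Tumor entities rotate round-robin across samples.
    """
    if not fractions_grid:
        raise ValidationError("fractions_grid must be non-empty")
    if samples_per_fraction < 1:
        raise ValidationError("samples_per_fraction must be >= 1")
    bad = [f for f in fractions_grid if not 0.0 <= f <= 1.0]
    if bad:
        raise ValidationError(f"tumor fractions outside [0, 1]: {bad}")
    rng = np.random.default_rng(seed)
    tumor_entities = atlas.tumor_entities
    cohort: list[CohortSample] = []
    i = 0
    for f in fractions_grid:
        for _ in range(samples_per_fraction):
            entity = tumor_entities[i % len(tumor_entities)]
            u = rng.uniform()
            c = f + (1.0 - f) * u
            fractions = {e: 0.0 for e in atlas.entities}
            fractions[entity] = f
            fractions["healthy_cfDNA"] = c - f
            fractions["WBC"] = 1.0 - c
            sample_seed = int(rng.integers(2**31))
            counts = simulate_sample(atlas, fractions, mean_coverage, seed=sample_seed)
            profile = simulate_fragment_profile(
                c * total_mass_ng, (1.0 - c) * total_mass_ng, seed=sample_seed
            )
            cohort.append(
                CohortSample(
                    sample_id=f"sim{i:03d}",
                    entity=entity,
                    tumor_fraction=f,
                    truth=SimTruth(fractions, c, mean_coverage),
                    counts=counts,
                    fragment_profile=profile,
                    seed=sample_seed,
                )
            )
            i += 1
    return cohort


DEFAULT_COHORT_CONFIG: dict = {
    "n_tumor_entities": 8,
    "n_regions": 2000,
    "markers_per_entity": 40,
    "margin": 0.5,
    "mean_coverage": 30,
    "cpgs_per_region": 4,
    "fractions": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9],
    "samples_per_fraction": 10,
    "total_mass_ng": 10.0,
    "seed": 0,
}


def simulate_cohort(config: Mapping, outdir) -> pd.DataFrame:
    """Write a fully reproducible synthetic cohort to ``outdir``.

    Produces per-sample Bismark coverage files (per-region counts expanded
    over ``cpgs_per_region`` CpGs), fragment-profile CSVs, the regions BED,
    the reference atlas CSV pair, a samples manifest and a machine-readable
    truth table. Byte-identical given the same config (the seed drives all
    randomness). Returns the truth table.
    """
    cfg = dict(DEFAULT_COHORT_CONFIG)
    cfg.update(config or {})
    if not cfg["fractions"]:
        raise ValidationError("fractions grid must be non-empty")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    atlas = simulate_atlas(
        cfg["n_tumor_entities"] + 2,
        cfg["n_regions"],
        cfg["markers_per_entity"],
        cfg["margin"],
        cfg["seed"],
    )
    regions = atlas.region_set()
    regions.to_bed(outdir / "regions.bed")
    atlas.to_reference_atlas().to_csv(str(outdir / "atlas"))

    cohort = simulate_mixture_cohort(
        atlas,
        cfg["fractions"],
        cfg["samples_per_fraction"],
        cfg["mean_coverage"],
        cfg["total_mass_ng"],
        cfg["seed"],
    )

    n_cpgs = int(cfg["cpgs_per_region"])
    region_df = regions.regions.set_index("cluster_id")
    offsets = np.linspace(10, 180, n_cpgs).astype(np.int64)
    truth_rows, manifest_rows = [], []
    for samp in cohort:
        rng = np.random.default_rng(samp.seed + 1)
        mixed = np.clip(
            atlas.beta @ np.array([samp.truth.fractions[e] for e in atlas.entities]),
            0.0,
            1.0,
        )
        starts = region_df["start"].to_numpy()
        chrom = region_df["chrom"].to_numpy()
        pos = (starts[:, None] + offsets[None, :]).ravel() + 1  # 1-based
        per_cpg_m = np.repeat(mixed, n_cpgs)
        totals = rng.poisson(cfg["mean_coverage"] / n_cpgs, size=len(pos))
        meth = rng.binomial(totals, per_cpg_m)
        keep = totals > 0
        calls = pd.DataFrame(
            {
                "chrom": np.repeat(chrom, n_cpgs)[keep],
                "pos": pos[keep],
                "count_meth": meth[keep],
                "count_unmeth": (totals - meth)[keep],
            }
        )
        cov_path = outdir / f"{samp.sample_id}.cov"
        frag_path = outdir / f"{samp.sample_id}.fragments.csv"
        write_bismark_coverage(calls, cov_path)
        samp.fragment_profile.to_csv(frag_path, index=False)
        row = {
            "sample_id": samp.sample_id,
            "entity": samp.entity,
            "tumor_fraction": samp.tumor_fraction,
            "cfdna_fraction_true": samp.truth.cfdna_fraction_true,
            "seed": samp.seed,
        }
        row.update({f"frac_{e}": samp.truth.fractions[e] for e in atlas.entities})
        truth_rows.append(row)
        manifest_rows.append(
            {
                "sample_id": samp.sample_id,
                "coverage_path": cov_path.name,
                "fragment_profile_path": frag_path.name,
                "bin_counts_path": "",
                "truth": samp.entity,
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    return truth
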