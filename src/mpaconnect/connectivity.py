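"""Connectivity statistics: recruitment, retention, transition matrices,
survivorship-weighted trajectory density, and field-evaluation metrics.

A larva recruits at a site when it is alive at the end of its pelagic
duration *and* its final position falls inside that site's footprint.
With cᵢⱼ the count spawned at i recruiting at j, Nᵢ the eggs spawned at i
and N_s the total spawned over all sites, pooled over simulations t:

    recruitment rate   Rᵢ  = (Σ_t Σ_{j≠i} cᵢⱼ + Σ_t cᵢᵢ) / Σ_t N_s
    local retention    LRᵢ = Σ_t cᵢᵢ / Σ_t Nᵢ
    transition matrix  P[i,j] = Σ_t cᵢⱼ / Σ_t Nᵢ   (diagonal = LRᵢ)

Note R is normalized by the *network-wide* spawn count N_s, so Σᵢ Rᵢ is
bounded by the surviving-recruited fraction of the whole network, while
TPM rows are source-normalized so the diagonal reproduces LR exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy.ndimage import gaussian_filter

from .errors import IntegrityError, ValidationError
from .fields import GridSpec
from .mortality import Fate
from .sites import MPARegistry, locate_points

__all__ = [
    "RecruitmentRecord",
    "TransitionProbabilityMatrix",
    "DensityMap",
    "DensityAccumulator",
    "detect_recruitment",
    "combine_records",
    "recruitment_rate",
    "local_retention",
    "build_tpm",
    "density_map",
    "rmse",
    "bias",
]


@dataclass
class RecruitmentRecord:
    """Recruit counts for one simulation (one season–year–window run).

    ``counts[i, j]`` = particles spawned at site i that recruited at j
    (diagonal = retained at home); ``spawned[i]`` = Nᵢ eggs released at i.
    """

    site_ids: tuple[str, ...]
    counts: np.ndarray
    spawned: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        k = len(self.site_ids)
        self.counts = np.asarray(self.counts, dtype=float)
        self.spawned = np.asarray(self.spawned, dtype=float)
        if self.counts.shape != (k, k) or self.spawned.shape != (k,):
            raise ValidationError("record shapes inconsistent with site list")
        if np.any(self.counts < 0) or np.any(self.spawned < 0):
            raise ValidationError("counts must be non-negative")
        if np.any(self.counts.sum(axis=1) > self.spawned + 1e-9):
            raise IntegrityError("recruits from a site exceed its spawn count")

    @property
    def n_spawned_total(self) -> float:
        """N_s: eggs spawned over all sites."""
        return float(self.spawned.sum())


def detect_recruitment(trajectories, registry: MPARegistry) -> RecruitmentRecord:
    """Count recruits from a finished trajectory set.

    Competence is restricted to the end of the simulation: only particles
    alive at the final timestep count, and only if their final position
    locates to a site footprint; survivors outside every footprint recruit
    nowhere.
    """
    ids = registry.ids
    k = len(ids)
    pos = {sid: i for i, sid in enumerate(ids)}
    sources = np.asarray(trajectories.source)
    unknown = set(np.unique(sources)) - set(ids)
    if unknown:
        raise IntegrityError(f"unknown source site(s): {sorted(unknown)}")
    src_idx = np.array([pos[s] for s in sources])
    spawned = np.bincount(src_idx, minlength=k).astype(float)
    counts = np.zeros((k, k))
    alive = trajectories.fate == Fate.ALIVE
    if alive.any():
        sink = locate_points(registry, trajectories.lon[alive], trajectories.lat[alive])
        recruited = sink >= 0
        np.add.at(counts, (src_idx[alive][recruited], sink[recruited]), 1.0)
    return RecruitmentRecord(site_ids=ids, counts=counts, spawned=spawned,
                             meta=dict(getattr(trajectories, "meta", {})))


def _as_records(records) -> list[RecruitmentRecord]:
    recs = records if isinstance(records, (list, tuple)) else [records]
    if not recs:
        raise ValidationError("no recruitment records given")
    ids = recs[0].site_ids
    for r in recs:
        if r.site_ids != ids:
            raise IntegrityError("records cover different site lists")
    return list(recs)


def combine_records(records) -> RecruitmentRecord:
    """Pool counts and spawn totals over simulations (the Σ_t sums)."""
    recs = _as_records(records)
    return RecruitmentRecord(
        site_ids=recs[0].site_ids,
        counts=sum(r.counts for r in recs),
        spawned=sum(r.spawned for r in recs),
        meta={"pooled": len(recs)},
    )


def recruitment_rate(records) -> pd.Series:
    """Per-site recruitment rate Rᵢ, normalized by the network spawn total."""
    rec = combine_records(records)
    n_s = rec.n_spawned_total
    if n_s == 0:
        raise ValidationError("recruitment rate undefined: no eggs spawned")
    return pd.Series(rec.counts.sum(axis=1) / n_s, index=list(rec.site_ids), name="R")


def local_retention(records) -> pd.Series:
    """Per-site local retention LRᵢ = retained / spawned-at-site."""
    rec = combine_records(records)
    if np.any(rec.spawned == 0):
        empty = [s for s, n in zip(rec.site_ids, rec.spawned) if n == 0]
        raise ValidationError(f"local retention undefined for unspawned site(s): {empty}")
    return pd.Series(np.diag(rec.counts) / rec.spawned, index=list(rec.site_ids), name="LR")


@dataclass
class TransitionProbabilityMatrix:
    """Source×sink recruitment probabilities; diagonal = local retention."""

    site_ids: tuple[str, ...]
    P: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.site_ids),) * 2:
            raise ValidationError("matrix shape inconsistent with site list")
        if np.any(self.P < -1e-12) or np.any(self.P > 1 + 1e-12):
            raise IntegrityError("transition probabilities outside [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.P, index=list(self.site_ids), columns=list(self.site_ids))
        df.index.name = "source"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @property
    def local_retention(self) -> pd.Series:
        return pd.Series(np.diag(self.P), index=list(self.site_ids), name="LR")


def build_tpm(records, registry: MPARegistry, meta: dict | None = None) -> TransitionProbabilityMatrix:
    """Source-normalized transition matrix from pooled records.

    P[i, j] = Σ_t cᵢⱼ / Σ_t Nᵢ.  Rows of sites with no spawn are zero.  The
    diagonal equals :func:`local_retention` exactly.
    """
    rec = combine_records(records)
    if rec.site_ids != registry.ids:
        raise IntegrityError("record site order does not match registry")
    denom = np.where(rec.spawned > 0, rec.spawned, 1.0)
    P = rec.counts / denom[:, None]
    return TransitionProbabilityMatrix(site_ids=rec.site_ids, P=P, meta=meta or {})


# ---------------------------------------------------------------------------
# survivorship-weighted trajectory density


@dataclass
class DensityMap:
    """Likelihood of larval crossing per grid cell, summing to 1 over water."""

    lons: np.ndarray
    lats: np.ndarray
    values: np.ndarray  # (lat, lon)
    bandwidth_deg: float
    empty: bool = False
    meta: dict = dc_field(default_factory=dict)

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"density": (("lat", "lon"), self.values)},
            coords={"lat": self.lats, "lon": self.lons},
            attrs={"bandwidth_deg": self.bandwidth_deg, "empty": int(self.empty)},
        )

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path)


def _cell_edges(nodes: np.ndarray) -> np.ndarray:
    mid = 0.5 * (nodes[1:] + nodes[:-1])
    first = nodes[0] - (mid[0] - nodes[0])
    last = nodes[-1] + (nodes[-1] - mid[-1])
    return np.concatenate([[first], mid, [last]])


def _alive_position_histogram(ts, lon_edges, lat_edges) -> np.ndarray:
    if ts.log_lon is None:
        raise ValidationError("trajectory set carries no position log")
    x = ts.log_lon.ravel()
    y = ts.log_lat.ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    h, _, _ = np.histogram2d(y[ok], x[ok], bins=[lat_edges, lon_edges])
    return h


class DensityAccumulator:
    """Streaming builder for survivorship-weighted density maps.

    Each added trajectory set contributes the histogram of its logged
    living-particle positions, normalized within the set and weighted by
    the set's living-particle count at the end, so low-survivorship runs
    do not inflate the pooled map.
    """

    def __init__(
        self,
        grid: GridSpec,
        bandwidth_deg: float | None = None,
        land_mask: np.ndarray | None = None,
    ):
        dlat, dlon = grid.cell_width_deg
        if bandwidth_deg is None:
            bandwidth_deg = dlon  # default: one grid-cell width
        if bandwidth_deg <= 0:
            raise ValidationError("bandwidth must be positive")
        self.grid = grid
        self.bandwidth_deg = float(bandwidth_deg)
        self.land_mask = land_mask
        self._sigma = (bandwidth_deg / dlat, bandwidth_deg / dlon)
        self._lon_edges = _cell_edges(grid.lons)
        self._lat_edges = _cell_edges(grid.lats)
        self._acc = np.zeros((grid.n_lat, grid.n_lon))
        self._total_w = 0.0
        self._n_sets = 0

    def add(self, ts) -> None:
        self._n_sets += 1
        w = float(ts.n_alive)
        if w == 0:
            return
        h = _alive_position_histogram(ts, self._lon_edges, self._lat_edges)
        s = h.sum()
        if s > 0:
            self._acc += w * (h / s)
            self._total_w += w

    def finalize(self) -> DensityMap:
        g = self.grid
        if self._total_w == 0:
            return DensityMap(g.lons, g.lats, np.zeros_like(self._acc),
                              self.bandwidth_deg, empty=True)
        acc = self._acc / self._total_w
        acc = gaussian_filter(acc, sigma=self._sigma, mode="constant")
        if self.land_mask is not None:
            acc = np.where(self.land_mask, 0.0, acc)
        acc /= acc.sum()
        return DensityMap(g.lons, g.lats, acc, self.bandwidth_deg,
                          meta={"n_sets": self._n_sets, "total_weight": self._total_w})


def density_map(
    trajectory_sets,
    grid: GridSpec,
    bandwidth_deg: float | None = None,
    land_mask: np.ndarray | None = None,
) -> DensityMap:
    """Gaussian-kernel density of living-particle positions.

    Every logged position of particles while alive contributes; simulations
    are pooled with weight proportional to their living-particle count at
    the end.  The kernel bandwidth defaults to one grid-cell width.  Output
    is normalized to sum to one over water cells; with no living particles
    anywhere the map is flagged ``empty``.
    """
    sets = trajectory_sets if isinstance(trajectory_sets, (list, tuple)) else [trajectory_sets]
    if not sets:
        raise ValidationError("need at least one trajectory set")
    acc = DensityAccumulator(grid, bandwidth_deg, land_mask)
    for ts in sets:
        acc.add(ts)
    return acc.finalize()


# ---------------------------------------------------------------------------
# field-evaluation statistics


def _paired(model, reference):
    m = np.asarray(model, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if m.size != r.size:
        raise ValidationError(f"length mismatch: model {m.size} vs reference {r.size}")
    if m.size == 0:
        raise ValidationError("need at least one pair of values")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(r))):
        raise ValidationError("inputs must be finite")
    return m, r


def rmse(model_values, reference_values) -> float:
    """Root mean square error sqrt(mean((model − reference)²))."""
    m, r = _paired(model_values, reference_values)
    return float(np.sqrt(np.mean((m - r) ** 2)))


def bias(model_values, reference_values) -> float:
    """Mean error mean(model − reference)."""
    m, r = _paired(model_values, reference_values)
    return float(np.mean(m - r))
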