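"""Lagrangian egg/larva transport through gridded ocean fields.

Particles are advected with a classical 4th-order Runge–Kutta scheme at an
hourly step, sampling velocity by bilinear interpolation in lon/lat and
linear interpolation in time (and between depth levels in layered mode).
Metres↔degrees conversion uses the local equirectangular metric
(1° lat = 111.32 km, 1° lon = 111.32·cos(lat) km) at each stage evaluation;
along-track distance accumulates as the haversine length of every step.

Life cycle: particles spawn as eggs, become larvae after the egg phase
(24 h by default) and drift until the pelagic larval duration (60 days)
elapses or a fate intervenes — lethal temperature (see
:mod:`mpaconnect.mortality`) or advection out of the model domain.  Step
order is advect → out-of-domain check → temperature check; once a fate is
set, position and distance are frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FieldCoverageError, ValidationError
from .fields import GriddedOceanField
from .mortality import Fate, ToleranceWindow, classify_temperature
from .scenarios import M_PER_DEG

__all__ = [
    "TransportConfig",
    "Release",
    "TrajectorySet",
    "FieldSampler",
    "AnalyticSampler",
    "sample_field",
    "rk4_step",
    "run_transport",
    "travelled_distance_summary",
    "haversine_km",
]

EARTH_RADIUS_KM = 6371.0

#: egg specific gravity carried from the source literature as metadata only;
#: the value is not physically interpretable as a seawater-relative density
#: and no buoyancy dynamics are driven by it (surface-layer mode instead).
EGG_DENSITY_G_CM3 = 0.0089

VERTICAL_MODES = ("surface_layer", "fixed_depth", "layered")


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (sphere of radius 6371 km)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


@dataclass(frozen=True)
class TransportConfig:
    """Integration and life-cycle parameters.

    time_step_h       RK4 step, hours (default 1 h).
    pld_days          pelagic larval duration, days (default 60).
    egg_phase_h       egg stage duration, hours (default 24).
    release_depth_max eggs spawn uniformly in [0, this] metres (default 5).
    vertical_mode     surface_layer (default) | fixed_depth | layered;
                      advection is horizontal in all modes, the mode only
                      selects which depth the fields are sampled at.
    log_every_h       trajectory position logging cadence, hours.
    rng_seed          reserved for stochastic extensions; transport itself
                      is deterministic.
    """

    time_step_h: float = 1.0
    pld_days: float = 60.0
    egg_phase_h: float = 24.0
    release_depth_max: float = 5.0
    vertical_mode: str = "surface_layer"
    fixed_depth: float = 0.0
    log_every_h: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.time_step_h <= 0:
            raise ValidationError("time_step_h must be > 0")
        if self.pld_days <= 0:
            raise ValidationError("pld_days must be > 0")
        if self.egg_phase_h < 0:
            raise ValidationError("egg_phase_h must be >= 0")
        if self.vertical_mode not in VERTICAL_MODES:
            raise ValidationError(f"vertical_mode must be one of {VERTICAL_MODES}")
        if self.log_every_h < self.time_step_h:
            raise ValidationError("log_every_h must be >= time_step_h")

    @property
    def pld_h(self) -> float:
        return self.pld_days * 24.0


@dataclass
class Release:
    """One spawning event: initial particle positions and provenance."""

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    source: np.ndarray        # site id per particle
    spawn_time_h: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.lon)
        for name in ("lat", "depth", "source"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"release arrays must share length (bad: {name})")

    def __len__(self) -> int:
        return len(self.lon)


# ---------------------------------------------------------------------------
# field sampling


class FieldSampler:
    """Interpolating view of a :class:`GriddedOceanField`.

    Bilinear in lon/lat, linear in time; depth handling per vertical mode
    (surface level, nearest fixed level, or linear between levels).  Queries
    outside the space-time domain return NaN, the out-of-domain signal.  On
    land cells the NaN velocity sentinels are replaced by zero for
    interpolation so flow decays smoothly to rest at the coast.
    """

    def __init__(
        self,
        field: GriddedOceanField,
        vertical_mode: str = "surface_layer",
        fixed_depth: float = 0.0,
    ):
        from scipy.interpolate import RegularGridInterpolator

        if vertical_mode not in VERTICAL_MODES:
            raise ValidationError(f"vertical_mode must be one of {VERTICAL_MODES}")
        self.field = field
        self.mode = vertical_mode
        g = field.grid
        self.grid = g
        u = np.nan_to_num(field.u, nan=0.0) if field.land_mask is not None else field.u
        v = np.nan_to_num(field.v, nan=0.0) if field.land_mask is not None else field.v
        t = field.temperature
        if vertical_mode == "layered" and g.n_depth > 1:
            axes = (g.times_h, g.depths, g.lats, g.lons)
            uv = np.stack([u, v], axis=-1)
            self._uv = RegularGridInterpolator(axes, uv, bounds_error=False, fill_value=np.nan)
            self._t = RegularGridInterpolator(axes, t, bounds_error=False, fill_value=np.nan)
            self._layered = True
        else:
            if vertical_mode == "fixed_depth":
                k = int(np.argmin(np.abs(g.depths - fixed_depth)))
            else:
                k = 0  # surface layer (also layered mode on a single level)
            axes = (g.times_h, g.lats, g.lons)
            uv = np.stack([u[:, k], v[:, k]], axis=-1)
            self._uv = RegularGridInterpolator(axes, uv, bounds_error=False, fill_value=np.nan)
            self._t = RegularGridInterpolator(axes, t[:, k], bounds_error=False, fill_value=np.nan)
            self._layered = False

    def _points(self, lon, lat, depth, time_h):
        lon = np.asarray(lon, dtype=float)
        n = lon.shape[0] if lon.ndim else 1
        t = np.broadcast_to(np.asarray(time_h, dtype=float), (n,))
        if self._layered:
            d = np.broadcast_to(np.asarray(depth, dtype=float), (n,))
            d = np.clip(d, self.grid.depths[0], self.grid.depths[-1])
            return np.column_stack([t, d, np.atleast_1d(lat), np.atleast_1d(lon)])
        return np.column_stack([t, np.atleast_1d(lat), np.atleast_1d(lon)])

    def velocity(self, lon, lat, time_h, depth=0.0):
        """(u, v) in m s⁻¹; NaN outside the domain."""
        uv = self._uv(self._points(lon, lat, depth, time_h))
        return uv[:, 0], uv[:, 1]

    def temperature(self, lon, lat, time_h, depth=0.0):
        """Water temperature in °C; NaN outside the domain."""
        return self._t(self._points(lon, lat, depth, time_h))


class AnalyticSampler:
    """Sampler defined by analytic callables — exact fields for verification.

    ``u_fn``/``v_fn``/``t_fn`` take (lon, lat, time_h) arrays and return
    m s⁻¹ / °C.  Used to check integrator properties (e.g. convergence
    order) without grid interpolation error.
    """

    def __init__(self, u_fn, v_fn, t_fn=None):
        self.u_fn = u_fn
        self.v_fn = v_fn
        self.t_fn = t_fn or (lambda lon, lat, t: np.full_like(np.asarray(lon, float), 27.0))

    def velocity(self, lon, lat, time_h, depth=0.0):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            np.asarray(self.u_fn(lon, lat, time_h), dtype=float),
            np.asarray(self.v_fn(lon, lat, time_h), dtype=float),
        )

    def temperature(self, lon, lat, time_h, depth=0.0):
        return np.asarray(self.t_fn(np.asarray(lon, float), np.asarray(lat, float), time_h), dtype=float)


def sample_field(
    field: GriddedOceanField,
    lon,
    lat,
    depth=0.0,
    time_h=0.0,
    vertical_mode: str = "surface_layer",
):
    """Interpolate (u, v, temperature) at arbitrary points.

    Exact at grid nodes; raises if the query time is outside the field's
    time axis; spatial out-of-domain points return NaN.
    """
    g = field.grid
    tq = np.asarray(time_h, dtype=float)
    if np.any(tq < g.times_h[0]) or np.any(tq > g.times_h[-1]):
        raise ValidationError("query time outside the field time range")
    s = FieldSampler(field, vertical_mode=vertical_mode, fixed_depth=float(np.min(depth)))
    u, v = s.velocity(lon, lat, time_h, depth)
    t = s.temperature(lon, lat, time_h, depth)
    return u, v, t


# ---------------------------------------------------------------------------
# RK4 integration


def rk4_step(lon, lat, time_h, dt_h, sampler, depth=0.0):
    """Advance positions one RK4 step of ``dt_h`` hours.

    Four velocity evaluations (t, twice t+dt/2, t+dt) are combined with the
    classical 1/6·(k₁+2k₂+2k₃+k₄) weights; each evaluation converts m s⁻¹
    to degrees s⁻¹ with the cos(lat) metric at the stage position.  Returns
    (new_lon, new_lat, out_of_domain); positions of out-of-domain particles
    (any stage evaluation outside the field) are left unchanged.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    dt_s = dt_h * 3600.0

    def deriv(ln, lt, th):
        u, v = sampler.velocity(ln, lt, th, depth)
        dlon = u / (M_PER_DEG * np.cos(np.radians(lt)))
        dlat = v / M_PER_DEG
        return dlon, dlat  # degrees per second

    k1x, k1y = deriv(lon, lat, time_h)
    k2x, k2y = deriv(lon + 0.5 * dt_s * k1x, lat + 0.5 * dt_s * k1y, time_h + 0.5 * dt_h)
    k3x, k3y = deriv(lon + 0.5 * dt_s * k2x, lat + 0.5 * dt_s * k2y, time_h + 0.5 * dt_h)
    k4x, k4y = deriv(lon + dt_s * k3x, lat + dt_s * k3y, time_h + dt_h)

    new_lon = lon + dt_s / 6.0 * (k1x + 2.0 * k2x + 2.0 * k3x + k4x)
    new_lat = lat + dt_s / 6.0 * (k1y + 2.0 * k2y + 2.0 * k3y + k4y)
    oob = ~(np.isfinite(new_lon) & np.isfinite(new_lat))
    if hasattr(sampler, "grid"):
        oob |= ~sampler.grid.contains(new_lon, new_lat)
    new_lon[oob] = lon[oob]
    new_lat[oob] = lat[oob]
    return new_lon, new_lat, oob


# ---------------------------------------------------------------------------
# trajectory ensemble


@dataclass
class TrajectorySet:
    """End states plus an optional dense position log for one release.

    Per-particle arrays share one index; ``log_lon``/``log_lat`` have shape
    (n_logged_times, n_particles) with NaN once a particle is no longer
    alive, so the log holds exactly the positions of living particles.
    """

    ids: np.ndarray
    source: np.ndarray
    spawn_time_h: float
    fate: np.ndarray          # Fate codes, int8
    fate_time_h: np.ndarray   # hours from experiment origin; NaN while alive
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    distance_km: np.ndarray
    stage: np.ndarray         # "egg" | "larva" at end of record
    log_times_h: np.ndarray | None = None
    log_lon: np.ndarray | None = None
    log_lat: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def alive(self) -> np.ndarray:
        return self.fate == Fate.ALIVE

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    @property
    def particles(self) -> pd.DataFrame:
        """Flat one-row-per-particle fate table."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "source": self.source,
                "spawn_time_h": self.spawn_time_h,
                "stage": self.stage,
                "fate": [Fate(f).label for f in self.fate],
                "fate_time_h": self.fate_time_h,
                "lon": self.lon,
                "lat": self.lat,
                "depth_m": self.depth,
                "distance_km": self.distance_km,
            }
        )

    def write_fate_csv(self, path: str | Path) -> None:
        self.particles.to_csv(path, index=False)

    def drop_log(self) -> None:
        """Free the dense position log (end states are kept)."""
        self.log_times_h = self.log_lon = self.log_lat = None

    def to_netcdf(self, path: str | Path) -> None:
        data = {
            "source": ("particle", self.source.astype("U8")),
            "fate": ("particle", self.fate.astype("i1")),
            "fate_time_h": ("particle", self.fate_time_h),
            "lon": ("particle", self.lon),
            "lat": ("particle", self.lat),
            "depth": ("particle", self.depth),
            "distance_km": ("particle", self.distance_km),
            "stage": ("particle", self.stage.astype("U5")),
        }
        coords = {"particle": self.ids}
        if self.log_lon is not None:
            data["log_lon"] = (("time", "particle"), self.log_lon)
            data["log_lat"] = (("time", "particle"), self.log_lat)
            coords["time"] = self.log_times_h
        attrs = {"spawn_time_h": self.spawn_time_h}
        attrs.update({k: str(v) for k, v in self.meta.items()})
        xr.Dataset(data, coords=coords, attrs=attrs).to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "TrajectorySet":
        with xr.open_dataset(Path(path)) as ds:
            ds = ds.load()
        has_log = "log_lon" in ds
        return cls(
            ids=ds["particle"].values,
            source=ds["source"].values.astype(object),
            spawn_time_h=float(ds.attrs["spawn_time_h"]),
            fate=ds["fate"].values,
            fate_time_h=ds["fate_time_h"].values,
            lon=ds["lon"].values,
            lat=ds["lat"].values,
            depth=ds["depth"].values,
            distance_km=ds["distance_km"].values,
            stage=ds["stage"].values.astype(object),
            log_times_h=ds["time"].values if has_log else None,
            log_lon=ds["log_lon"].values if has_log else None,
            log_lat=ds["log_lat"].values if has_log else None,
            meta={k: v for k, v in ds.attrs.items() if k != "spawn_time_h"},
        )


def run_transport(
    release: Release,
    field: GriddedOceanField,
    config: TransportConfig,
    mortality_rule: ToleranceWindow | None = None,
) -> TrajectorySet:
    """Advect one release through a field for the full pelagic duration.

    Every particle is stepped from its spawn time until the PLD elapses or
    a fate is set.  Each step: RK4 move, out-of-domain check (fate
    advected_out, which takes precedence), then — when a tolerance window is
    given — classification of the interpolated temperature at the new
    position.  A step that would land on a masked (land) cell leaves the
    particle at its previous water position, still alive (no-slip beaching).
    Deterministic: same release, field and config give identical output.
    """
    g = field.grid
    t0 = release.spawn_time_h
    pld_h = config.pld_h
    dt = config.time_step_h
    if t0 < g.times_h[0] or t0 + pld_h > g.times_h[-1]:
        raise FieldCoverageError(
            f"field time axis [{g.times_h[0]}, {g.times_h[-1]}] h does not cover "
            f"spawn {t0} h + PLD {pld_h} h"
        )
    sampler = FieldSampler(field, config.vertical_mode, config.fixed_depth)

    n = len(release)
    lon = np.array(release.lon, dtype=float)
    lat = np.array(release.lat, dtype=float)
    depth = np.array(release.depth, dtype=float)
    fate = np.full(n, Fate.ALIVE, dtype=np.int8)
    fate_time = np.full(n, np.nan)
    dist = np.zeros(n)

    t_spawn = sampler.temperature(lon, lat, t0, depth)
    if np.any(~np.isfinite(t_spawn)):
        raise ValidationError("some particles spawn outside the model domain")

    n_steps = int(round(pld_h / dt))
    log_stride = max(1, int(round(config.log_every_h / dt)))
    log_idx = list(range(0, n_steps + 1, log_stride))
    if log_idx[-1] != n_steps:
        log_idx.append(n_steps)
    log_times = t0 + dt * np.asarray(log_idx, dtype=float)
    log_lon = np.full((len(log_idx), n), np.nan, dtype=np.float32)
    log_lat = np.full((len(log_idx), n), np.nan, dtype=np.float32)
    log_pos = {k: i for i, k in enumerate(log_idx)}
    log_lon[0], log_lat[0] = lon, lat

    if field.land_mask is not None:
        dlat_c, dlon_c = g.cell_width_deg

    for k in range(n_steps):
        t = t0 + k * dt
        idx = np.flatnonzero(fate == Fate.ALIVE)
        if idx.size:
            nlon, nlat, oob = rk4_step(lon[idx], lat[idx], t, dt, sampler, depth[idx])
            if field.land_mask is not None:
                # no-slip beaching: revert moves that land on a masked cell
                ci = np.clip(np.rint((nlat - g.lat_min) / dlat_c).astype(int), 0, g.n_lat - 1)
                cj = np.clip(np.rint((nlon - g.lon_min) / dlon_c).astype(int), 0, g.n_lon - 1)
                beached = field.land_mask[ci, cj] & ~oob
                nlon[beached] = lon[idx][beached]
                nlat[beached] = lat[idx][beached]
            dist[idx] += haversine_km(lon[idx], lat[idx], nlon, nlat)
            lon[idx], lat[idx] = nlon, nlat
            out = idx[oob]
            fate[out] = Fate.ADVECTED_OUT
            fate_time[out] = t + dt
            live = idx[~oob]
            if mortality_rule is not None and live.size:
                temp = sampler.temperature(lon[live], lat[live], t + dt, depth[live])
                cls = classify_temperature(temp, mortality_rule)
                died = live[cls != Fate.ALIVE]
                fate[died] = cls[cls != Fate.ALIVE]
                fate_time[died] = t + dt
        if (k + 1) in log_pos:
            row = log_pos[k + 1]
            sel = fate == Fate.ALIVE
            log_lon[row, sel] = lon[sel]
            log_lat[row, sel] = lat[sel]

    age_end = np.where(np.isfinite(fate_time), fate_time - t0, pld_h)
    stage = np.where(age_end < config.egg_phase_h, "egg", "larva").astype(object)

    return TrajectorySet(
        ids=np.arange(n),
        source=np.asarray(release.source, dtype=object),
        spawn_time_h=t0,
        fate=fate,
        fate_time_h=fate_time,
        lon=lon,
        lat=lat,
        depth=depth,
        distance_km=dist,
        stage=stage,
        log_times_h=log_times,
        log_lon=log_lon,
        log_lat=log_lat,
        meta={"window": mortality_rule.label if mortality_rule else "none"},
    )


# ---------------------------------------------------------------------------
# travel-distance statistics


def travelled_distance_summary(
    trajectories,
    only_alive: bool = True,
    site_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Five-number summaries of along-track distance per source site.

    Computed over particles still alive at the end of the run (the boxplot
    statistic of the travel-distance comparison); sites with no survivors
    are flagged ``empty``.  ``trajectories`` may be one TrajectorySet or a
    list (pooled).  Outliers are counted beyond 1.5×IQR whiskers.
    """
    sets = trajectories if isinstance(trajectories, (list, tuple)) else [trajectories]
    source = np.concatenate([np.asarray(ts.source) for ts in sets])
    distance = np.concatenate([ts.distance_km for ts in sets])
    fates = np.concatenate([ts.fate for ts in sets])
    order = site_order if site_order is not None else sorted(set(source))
    if only_alive:
        keep = fates == Fate.ALIVE
        source, distance = source[keep], distance[keep]
    rows = {}
    for sid in order:
        d = distance[source == sid]
        if d.size == 0:
            rows[sid] = dict(
                n=0, mean=np.nan, min=np.nan, q1=np.nan, median=np.nan,
                q3=np.nan, max=np.nan, n_outliers=0, empty=True,
            )
            continue
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        iqr = q3 - q1
        out = np.sum((d < q1 - 1.5 * iqr) | (d > q3 + 1.5 * iqr))
        rows[sid] = dict(
            n=int(d.size), mean=float(d.mean()), min=float(d.min()), q1=float(q1),
            median=float(med), q3=float(q3), max=float(d.max()),
            n_outliers=int(out), empty=False,
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "site"
    return df
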