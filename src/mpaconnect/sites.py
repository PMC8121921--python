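"""Marine protected area (MPA) geometry: sites, release allocation, queries.

Each site is a named spawning source and recruitment sink with a centroid,
a surface area (km²) and a spatial footprint polygon.  A packaged registry
describes the nine federal reef MPAs of the southwestern tropical Atlantic
(five shelf sites and four oceanic islands); for synthetic runs their
footprints default to area-matched rectangles around the published
centroids, and arbitrary polygons can be supplied through CSV.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .errors import IntegrityError, ValidationError
from .scenarios import M_PER_DEG

__all__ = [
    "MPASite",
    "MPARegistry",
    "load_registry",
    "default_registry",
    "allocate_releases",
    "locate",
    "locate_points",
    "seed_positions",
]


@dataclass(frozen=True)
class MPASite:
    """One protected area: id code, centroid (deg), area (km²), footprint."""

    id: str
    name: str
    centroid: tuple[float, float]  # (lon, lat)
    area_km2: float
    footprint: Polygon
    n_cells: int | None = None
    released_particles: int | None = None  # reference per-event release count

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise ValidationError(f"site {self.id}: area must be > 0")
        if self.footprint.is_empty:
            raise ValidationError(f"site {self.id}: footprint is empty")


def rectangle_footprint(lon: float, lat: float, area_km2: float) -> Polygon:
    """Axis-aligned square of the given surface area centred on (lon, lat)."""
    side_km = float(np.sqrt(area_km2))
    dlat = side_km / (M_PER_DEG / 1000.0) / 2.0
    dlon = side_km / (M_PER_DEG / 1000.0 * np.cos(np.radians(lat))) / 2.0
    return box(lon - dlon, lat - dlat, lon + dlon, lat + dlat)


class MPARegistry:
    """Ordered collection of :class:`MPASite` with unique ids and
    pairwise-disjoint footprints (asserted at construction)."""

    def __init__(self, sites: list[MPASite]):
        ids = [s.id for s in sites]
        if len(set(ids)) != len(ids):
            raise IntegrityError("site ids must be unique")
        for i, a in enumerate(sites):
            for b in sites[i + 1:]:
                if a.footprint.intersection(b.footprint).area > 0:
                    raise IntegrityError(
                        f"footprints of {a.id} and {b.id} overlap"
                    )
        self.sites: tuple[MPASite, ...] = tuple(sites)
        self._by_id = {s.id: s for s in sites}

    # -- container protocol ---------------------------------------------
    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def __getitem__(self, key: int | str) -> MPASite:
        if isinstance(key, str):
            return self._by_id[key]
        return self.sites[key]

    def __contains__(self, site_id: str) -> bool:
        return site_id in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sites)

    @property
    def areas(self) -> np.ndarray:
        return np.array([s.area_km2 for s in self.sites])

    def index_of(self, site_id: str) -> int:
        return self.ids.index(site_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "name": [s.name for s in self.sites],
                "lon": [s.centroid[0] for s in self.sites],
                "lat": [s.centroid[1] for s in self.sites],
                "area_km2": [s.area_km2 for s in self.sites],
            }
        ).set_index("id")


def load_registry(path: str | Path) -> MPARegistry:
    """Load sites from CSV (id, name, lon, lat, area_km2[, wkt, ...]).

    If a ``wkt`` column is present it supplies the footprint polygon;
    otherwise an area-matched rectangle is built around the centroid.
    """
    df = pd.read_csv(path)
    required = {"id", "name", "lon", "lat", "area_km2"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"registry file missing columns: {sorted(missing)}")
    sites = []
    for _, row in df.iterrows():
        if "wkt" in df.columns and isinstance(row.get("wkt"), str) and row["wkt"].strip():
            footprint = shapely.from_wkt(row["wkt"])
        else:
            footprint = rectangle_footprint(row["lon"], row["lat"], row["area_km2"])
        sites.append(
            MPASite(
                id=str(row["id"]),
                name=str(row["name"]),
                centroid=(float(row["lon"]), float(row["lat"])),
                area_km2=float(row["area_km2"]),
                footprint=footprint,
                n_cells=int(row["n_cells"]) if "n_cells" in df.columns else None,
                released_particles=(
                    int(row["released_particles"])
                    if "released_particles" in df.columns
                    else None
                ),
            )
        )
    return MPARegistry(sites)


def default_registry() -> MPARegistry:
    """The packaged nine-site southwestern Atlantic MPA registry."""
    res = importlib.resources.files("mpaconnect.data") / "south_atlantic_mpas.csv"
    with importlib.resources.as_file(res) as p:
        return load_registry(p)


# ---------------------------------------------------------------------------
# release allocation


def allocate_releases(registry: MPARegistry, total: int) -> np.ndarray:
    """Distribute a release budget across sites proportionally to area.

    Largest-remainder rounding: counts are the floors of ``total·aᵢ/Σa`` and
    leftover particles go to the largest fractional remainders (ties broken
    toward the larger area, then registry order).  The counts always sum
    exactly to ``total``.
    """
    if total <= 0:
        raise ValidationError("total releases must be positive")
    if total < len(registry):
        raise ValidationError("total must be at least the number of sites")
    areas = registry.areas
    quotas = total * areas / areas.sum()
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    if remainder > 0:
        frac = quotas - counts
        order = np.lexsort((np.arange(len(areas)), -areas, -frac))
        counts[order[:remainder]] += 1
    return counts


# ---------------------------------------------------------------------------
# point-in-MPA queries


def locate_points(registry: MPARegistry, lon, lat) -> np.ndarray:
    """Vectorized point→site lookup; returns site index per point, −1 if none.

    Containment is boundary-inclusive.  A point covered by two footprints
    indicates a violated disjointness invariant and raises IntegrityError.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    pts = shapely.points(lon, lat)
    result = np.full(lon.shape, -1, dtype=int)
    hits = np.zeros(lon.shape, dtype=int)
    for k, site in enumerate(registry):
        inside = shapely.covers(site.footprint, pts)
        hits += inside
        result[inside] = k
    if np.any(hits > 1):
        raise IntegrityError("point covered by multiple site footprints")
    return result


def locate(point: tuple[float, float], registry: MPARegistry) -> str | None:
    """Return the id of the site whose footprint covers (lon, lat), or None."""
    lon, lat = point
    if not (np.isfinite(lon) and np.isfinite(lat)):
        raise ValidationError("point coordinates must be finite")
    idx = locate_points(registry, [lon], [lat])[0]
    return registry.ids[idx] if idx >= 0 else None


# ---------------------------------------------------------------------------
# spawning positions


def seed_positions(
    site: MPASite,
    n: int,
    rng_seed: int | np.random.Generator = 0,
    release_depth_max: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` spawning positions uniformly over the site footprint.

    Eggs are released in the first metres of the water column: depth is
    uniform on [0, release_depth_max].  Deterministic under a fixed seed.
    Returns (lon, lat, depth) arrays.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lon_out = np.empty(n)
    lat_out = np.empty(n)
    if n:
        minx, miny, maxx, maxy = site.footprint.bounds
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            xs = rng.uniform(minx, maxx, m)
            ys = rng.uniform(miny, maxy, m)
            inside = shapely.covers(site.footprint, shapely.points(xs, ys))
            take = min(int(inside.sum()), n - filled)
            lon_out[filled: filled + take] = xs[inside][:take]
            lat_out[filled: filled + take] = ys[inside][:take]
            filled += take
    depth = rng.uniform(0.0, release_depth_max, n)
    return lon_out, lat_out, depth
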