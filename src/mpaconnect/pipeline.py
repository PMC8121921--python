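"""Experiment orchestration: seasons × years × tolerance windows.

One :class:`ExperimentConfig` drives the whole chain for every
(season, year, window) combination: proportional release allocation →
uniform spawning positions over site footprints → RK4 transport → fate
tallies → recruitment records; then pooled transition matrices, density
maps, travel-distance summaries and the Kruskal–Wallis comparison between
tolerance windows (and between seasons).  All randomness derives
deterministically from one master seed, so a config fully determines every
output byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import (
    DensityAccumulator,
    DensityMap,
    RecruitmentRecord,
    TransitionProbabilityMatrix,
    build_tpm,
    combine_records,
    detect_recruitment,
    local_retention,
    recruitment_rate,
)
from .errors import ConfigurationError, ValidationError
from .fields import GridSpec
from .mortality import ToleranceWindow, combine_tallies, compare_scenarios, tally_fates
from .scenarios import ScenarioSpec, SSTPattern, generate_field
from .sites import MPARegistry, allocate_releases, default_registry, load_registry, seed_positions
from .transport import Release, TransportConfig, TrajectorySet, run_transport, travelled_distance_summary

__all__ = ["ExperimentConfig", "ExperimentBundle", "run_experiment", "summarize", "write_bundle"]

#: hours between release events inside a spawning season (one per month)
EVENT_INTERVAL_H = 30.0 * 24.0


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic sub-seed from the master seed and integer context keys."""
    ss = np.random.SeedSequence([int(master), *[int(k) for k in keys]])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a full scenario experiment."""

    scenario: ScenarioSpec
    grid: GridSpec
    registry: MPARegistry
    years: tuple[int, ...]
    seasons: tuple[str, ...] = ("summer", "winter")
    windows: tuple[str, ...] = ("non_acclimated", "acclimated")
    total_release: int = 70_000
    per_site_counts: tuple[int, ...] | None = None  # explicit per-event counts
    events_per_season: int = 2
    transport: TransportConfig = dc_field(default_factory=TransportConfig)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.years or not self.seasons or not self.windows:
            raise ConfigurationError("need at least one year, season and window")
        for s in self.seasons:
            if s not in ("summer", "winter"):
                raise ConfigurationError(f"unknown season {s!r}")
        for w in self.windows:
            ToleranceWindow.named(w)  # validates
        if self.events_per_season < 1:
            raise ConfigurationError("events_per_season must be >= 1")
        if self.per_site_counts is not None and len(self.per_site_counts) != len(self.registry):
            raise ConfigurationError("per_site_counts length must match registry")
        # fail before any simulation if the field cannot cover the runs
        needed = (self.events_per_season - 1) * EVENT_INTERVAL_H + self.transport.pld_h
        span = self.grid.times_h[-1] - self.grid.times_h[0]
        if span < needed:
            raise ConfigurationError(
                f"field time axis spans {span:.0f} h but the release schedule "
                f"plus PLD needs {needed:.0f} h"
            )

    def event_budgets(self) -> list[int]:
        """Split the seasonal budget across release events, conserving the total."""
        e = self.events_per_season
        base = self.total_release // e
        extra = self.total_release - base * e
        return [base + (1 if i < extra else 0) for i in range(e)]

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, MPARegistry):
                return [s.id for s in obj]
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj
        payload = {
            "scenario": enc(self.scenario), "grid": enc(self.grid),
            "registry": [s.id for s in self.registry],
            "years": list(self.years), "seasons": list(self.seasons),
            "windows": list(self.windows), "total_release": self.total_release,
            "per_site_counts": list(self.per_site_counts) if self.per_site_counts else None,
            "events_per_season": self.events_per_season,
            "transport": enc(self.transport), "master_seed": self.master_seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path, master_seed: int | None = None) -> "ExperimentConfig":
        """Build a config from the structured text schema (see docs)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scen = dict(raw["scenario"])
        if "sst" in scen:
            scen["sst"] = SSTPattern(**scen["sst"])
        registry = (
            load_registry(raw["registry"]) if "registry" in raw else default_registry()
        )
        kwargs = dict(
            scenario=ScenarioSpec(**scen),
            grid=GridSpec(**raw["grid"]),
            registry=registry,
            years=tuple(raw["years"]),
        )
        for key in ("seasons", "windows"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("total_release", "events_per_season"):
            if key in raw:
                kwargs[key] = int(raw[key])
        if "per_site_counts" in raw and raw["per_site_counts"] is not None:
            kwargs["per_site_counts"] = tuple(raw["per_site_counts"])
        if "transport" in raw:
            kwargs["transport"] = TransportConfig(**raw["transport"])
        kwargs["master_seed"] = (
            int(master_seed) if master_seed is not None else int(raw.get("master_seed", 0))
        )
        return cls(**kwargs)


@dataclass
class RunResult:
    """Outputs of one (season, year, window) simulation."""

    season: str
    year: int
    window: str
    tally: pd.DataFrame
    record: RecruitmentRecord
    trajectories: list[TrajectorySet]  # final states; logs dropped by default


@dataclass
class ExperimentBundle:
    """Everything an experiment produced, ready for reporting/serialization."""

    config: ExperimentConfig
    runs: list[RunResult]
    tpms: dict[tuple[str, str], TransitionProbabilityMatrix]
    density_maps: dict[tuple[str, str], DensityMap]
    distance_summaries: dict[tuple[str, str], pd.DataFrame]
    comparisons: pd.DataFrame
    provenance: dict

    def mortality_table(self) -> pd.DataFrame:
        """Long-format per-site mortality across all runs."""
        rows = []
        for r in self.runs:
            t = r.tally.reset_index()
            t.insert(0, "window", r.window)
            t.insert(0, "year", r.year)
            t.insert(0, "season", r.season)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def mortality_groups(self, by: str = "window") -> dict[str, np.ndarray]:
        """Per-site-per-(season, year) total mortality %, grouped for testing."""
        table = self.mortality_table()
        return {
            key: grp["total_mortality_pct"].dropna().to_numpy()
            for key, grp in table.groupby(by)
        }

    def metrics_table(self) -> pd.DataFrame:
        """Local retention and recruitment rate per (window, season, site)."""
        rows = []
        for (window, season), tpm in self.tpms.items():
            recs = [r.record for r in self.runs if r.window == window and r.season == season]
            lr = local_retention(recs)
            rr = recruitment_rate(recs)
            for sid in tpm.site_ids:
                rows.append({"window": window, "season": season, "site": sid,
                             "LR": lr[sid], "R": rr[sid]})
        return pd.DataFrame(rows)


def _make_release(config: ExperimentConfig, season_idx: int, year: int, event: int,
                  spawn_time_h: float) -> Release:
    reg = config.registry
    if config.per_site_counts is not None:
        counts = np.asarray(config.per_site_counts, dtype=int)
    else:
        counts = allocate_releases(reg, config.event_budgets()[event])
    rng = np.random.default_rng(
        derive_seed(config.master_seed, 1, season_idx, year, event)
    )
    lons, lats, depths, src = [], [], [], []
    for site, n in zip(reg, counts):
        lo, la, de = seed_positions(site, int(n), rng, config.transport.release_depth_max)
        lons.append(lo)
        lats.append(la)
        depths.append(de)
        src.append(np.full(int(n), site.id, dtype=object))
    return Release(
        lon=np.concatenate(lons), lat=np.concatenate(lats),
        depth=np.concatenate(depths), source=np.concatenate(src),
        spawn_time_h=spawn_time_h,
    )


def run_experiment(config: ExperimentConfig, keep_trajectory_logs: bool = False,
                   progress=None) -> ExperimentBundle:
    """Run the full experiment matrix and assemble all outputs.

    For every (season, year): generate the seasonal field (interannual
    variability enters through the seeded noise of the scenario), build the
    release events, then run each tolerance window over identical releases
    and fields — so window comparisons are paired particle-for-particle.
    """
    cfg = config
    runs: list[RunResult] = []
    density_acc: dict[tuple[str, str], DensityAccumulator] = {}
    run_seeds = {}

    for si, season in enumerate(cfg.seasons):
        for year in cfg.years:
            field_seed = derive_seed(cfg.master_seed, 0, si, year)
            scen = replace(cfg.scenario, season=season, seed=field_seed)
            fld = generate_field(scen, cfg.grid)
            releases = [
                _make_release(cfg, si, year, e, cfg.grid.times_h[0] + e * EVENT_INTERVAL_H)
                for e in range(cfg.events_per_season)
            ]
            for window in cfg.windows:
                if progress:
                    progress(f"{season} {year} {window}")
                wobj = ToleranceWindow.named(window)
                key = (window, season)
                if key not in density_acc:
                    density_acc[key] = DensityAccumulator(cfg.grid, land_mask=fld.land_mask)
                event_sets = []
                for rel in releases:
                    ts = run_transport(rel, fld, cfg.transport, wobj)
                    ts.meta.update(season=season, year=year, window=window,
                                   scenario=cfg.scenario.name)
                    density_acc[key].add(ts)
                    if not keep_trajectory_logs:
                        ts.drop_log()
                    event_sets.append(ts)
                tally = combine_tallies([tally_fates(ts, cfg.registry) for ts in event_sets])
                record = combine_records(
                    [detect_recruitment(ts, cfg.registry) for ts in event_sets]
                )
                record.meta.update(season=season, year=year, window=window)
                runs.append(RunResult(season, year, window, tally, record, event_sets))
            run_seeds[f"{season}-{year}"] = field_seed

    tpms, density_maps, distance_summaries = {}, {}, {}
    for window in cfg.windows:
        for season in cfg.seasons:
            sel = [r for r in runs if r.window == window and r.season == season]
            key = (window, season)
            tpms[key] = build_tpm([r.record for r in sel], cfg.registry,
                                  meta={"window": window, "season": season,
                                        "years": list(cfg.years)})
            density_maps[key] = density_acc[key].finalize()
            pooled = [ts for r in sel for ts in r.trajectories]
            distance_summaries[key] = travelled_distance_summary(
                pooled, only_alive=True, site_order=cfg.registry.ids
            )

    comparisons = _comparisons(cfg, runs)
    provenance = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "field_seeds": run_seeds,
        "n_runs": len(runs),
    }
    return ExperimentBundle(cfg, runs, tpms, density_maps, distance_summaries,
                            comparisons, provenance)


def _comparisons(cfg: ExperimentConfig, runs: list[RunResult]) -> pd.DataFrame:
    def groups(select, by):
        out = {}
        for r in runs:
            if select(r):
                out.setdefault(by(r), []).append(
                    r.tally["total_mortality_pct"].dropna().to_numpy()
                )
        return {k: np.concatenate(v) for k, v in out.items()}

    rows = []
    if len(cfg.windows) >= 2:
        g = groups(lambda r: True, lambda r: r.window)
        h, p = compare_scenarios(*g.values())
        rows.append({"comparison": "acclimated_vs_non_acclimated",
                     "groups": "|".join(g), "H": h, "p": p})
    if len(cfg.seasons) >= 2:
        for window in cfg.windows:
            g = groups(lambda r: r.window == window, lambda r: r.season)
            h, p = compare_scenarios(*g.values())
            rows.append({"comparison": f"seasons_within_{window}",
                         "groups": "|".join(g), "H": h, "p": p})
    return pd.DataFrame(rows, columns=["comparison", "groups", "H", "p"])


# ---------------------------------------------------------------------------
# reporting and serialization


def summarize(bundle: ExperimentBundle) -> str:
    """Human-readable report of mortality, retention, recruitment, distances
    and the scenario-comparison statistics."""
    if not bundle.runs:
        raise ConfigurationError("bundle is empty: the transport stage produced no runs")
    cfg = bundle.config
    lines = [
        f"Experiment: scenario={cfg.scenario.name} years={list(cfg.years)} "
        f"seasons={list(cfg.seasons)} windows={list(cfg.windows)}",
        f"Sites: {', '.join(cfg.registry.ids)}",
        f"Release budget: {cfg.total_release} per season-year "
        f"({cfg.events_per_season} event(s))",
        "",
    ]
    mort = (
        bundle.mortality_table()
        .groupby(["window", "season", "site"], sort=False)["total_mortality_pct"]
        .mean()
        .unstack("site")
    )
    lines += ["Mean total mortality (%) per site:", mort.round(1).to_string(), ""]
    metrics = bundle.metrics_table()
    if not metrics.empty:
        lr = metrics.pivot_table(index=["window", "season"], columns="site",
                                 values="LR", sort=False)
        lines += ["Local retention (diagonal of the TPM):", lr.round(4).to_string(), ""]
    for key, summ in bundle.distance_summaries.items():
        lines += [f"Travel distance (km, survivors) — window={key[0]}, season={key[1]}:",
                  summ[["n", "mean", "median", "max"]].round(1).to_string(), ""]
    if not bundle.comparisons.empty:
        lines += ["Kruskal-Wallis comparisons of total mortality:",
                  bundle.comparisons.to_string(index=False, float_format=lambda x: f"{x:.4g}"),
                  ""]
    return "\n".join(lines)


def write_bundle(bundle: ExperimentBundle, out_dir: str | Path,
                 figures: bool = True) -> Path:
    """Write CSV/NetCDF/JSON outputs (and PNG figures) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.mortality_table().to_csv(out / "tallies.csv", index=False)
    bundle.metrics_table().to_csv(out / "metrics.csv", index=False)
    bundle.comparisons.to_csv(out / "comparisons.csv", index=False)
    for (window, season), tpm in bundle.tpms.items():
        tpm.to_csv(out / f"tpm_{window}_{season}.csv")
    for (window, season), dm in bundle.density_maps.items():
        dm.to_netcdf(out / f"density_{window}_{season}.nc")
    for (window, season), df in bundle.distance_summaries.items():
        df.to_csv(out / f"distances_{window}_{season}.csv")
    (out / "report.txt").write_text(summarize(bundle))
    with open(out / "provenance.json", "w") as fh:
        json.dump(bundle.provenance, fh, indent=2, sort_keys=True)
    if figures:
        from . import plots
        for (window, season), tpm in bundle.tpms.items():
            plots.tpm_heatmap(tpm).savefig(out / f"tpm_{window}_{season}.png", dpi=120)
        for (window, season), dm in bundle.density_maps.items():
            if not dm.empty:
                plots.density_plot(dm, bundle.config.registry).savefig(
                    out / f"density_{window}_{season}.png", dpi=120)
        plots.fate_proportions(bundle).savefig(out / "fate_proportions.png", dpi=120)
        import matplotlib.pyplot as plt
        plt.close("all")
    return out
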