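"""Recruitment counting, retention/recruitment rates, transition matrices,
density maps and field-evaluation statistics, checked against brute force."""

import numpy as np
import pytest
from shapely.geometry import box

from mpaconnect import (
    GridSpec,
    MPARegistry,
    MPASite,
    ValidationError,
    bias,
    build_tpm,
    density_map,
    detect_recruitment,
    local_retention,
    recruitment_rate,
    rmse,
)
from mpaconnect.connectivity import RecruitmentRecord, combine_records
from mpaconnect.mortality import Fate
from mpaconnect.transport import TrajectorySet


def toy_registry():
    a = MPASite(id="A", name="A", centroid=(0.0, 0.0), area_km2=100.0,
                footprint=box(-1.0, -1.0, 1.0, 1.0))
    b = MPASite(id="B", name="B", centroid=(5.0, 0.0), area_km2=100.0,
                footprint=box(4.0, -1.0, 6.0, 1.0))
    return MPARegistry([a, b])


def make_ts(source, fate, lon, lat, log=None):
    n = len(source)
    kwargs = {}
    if log is not None:
        log_lon, log_lat = log
        kwargs = dict(log_times_h=np.arange(log_lon.shape[0], dtype=float),
                      log_lon=log_lon, log_lat=log_lat)
    return TrajectorySet(
        ids=np.arange(n), source=np.asarray(source, dtype=object), spawn_time_h=0.0,
        fate=np.asarray(fate, dtype=np.int8),
        fate_time_h=np.where(np.asarray(fate) == 0, np.nan, 1.0),
        lon=np.asarray(lon, dtype=float), lat=np.asarray(lat, dtype=float),
        depth=np.zeros(n), distance_km=np.zeros(n),
        stage=np.array(["larva"] * n, dtype=object), **kwargs,
    )


def brute_force_counts(registry, source, fate, lon, lat):
    """Exhaustive per-particle enumeration oracle for recruit counting."""
    ids = list(registry.ids)
    k = len(ids)
    counts = np.zeros((k, k))
    spawned = np.zeros(k)
    for s, f, x, y in zip(source, fate, lon, lat):
        i = ids.index(s)
        spawned[i] += 1
        if f != Fate.ALIVE:
            continue
        for j, site in enumerate(registry):
            minx, miny, maxx, maxy = site.footprint.bounds
            if minx <= x <= maxx and miny <= y <= maxy:
                counts[i, j] += 1
                break
    return counts, spawned


class TestDetectRecruitment:
    def test_all_dead_no_recruits(self):
        reg = toy_registry()
        ts = make_ts(["A", "B"], [Fate.DEAD_HYPERTHERMIA] * 2, [0.0, 5.0], [0.0, 0.0])
        rec = detect_recruitment(ts, reg)
        assert np.all(rec.counts == 0)
        assert rec.spawned.tolist() == [1.0, 1.0]

    def test_stationary_survivors_fully_retained(self):
        reg = toy_registry()
        ts = make_ts(["A"] * 3 + ["B"] * 2, [Fate.ALIVE] * 5,
                     [0.0, 0.1, -0.2, 5.0, 5.3], [0.0] * 5)
        rec = detect_recruitment(ts, reg)
        assert np.array_equal(rec.counts, [[3, 0], [0, 2]])

    def test_alive_outside_all_footprints_recruits_nowhere(self):
        reg = toy_registry()
        ts = make_ts(["A"], [Fate.ALIVE], [2.5], [0.0])  # between the sites
        rec = detect_recruitment(ts, reg)
        assert rec.counts.sum() == 0 and rec.spawned[0] == 1

    def test_matches_brute_force_enumeration_on_random_toy(self, registry):
        rng = np.random.default_rng(6)
        n = 100
        ids = list(registry.ids)
        source = rng.choice(ids, n)
        fate = rng.choice([Fate.ALIVE, Fate.DEAD_HYPERTHERMIA], n, p=[0.7, 0.3])
        # scatter endings around site centroids so some recruit, some miss
        home = np.array([registry[s].centroid for s in source])
        lon = home[:, 0] + rng.normal(0, 0.3, n)
        lat = home[:, 1] + rng.normal(0, 0.3, n)
        ts = make_ts(source, fate, lon, lat)
        rec = detect_recruitment(ts, registry)
        counts, spawned = brute_force_counts(registry, source, fate, lon, lat)
        np.testing.assert_array_equal(rec.counts, counts)
        np.testing.assert_array_equal(rec.spawned, spawned)


class TestRates:
    def two_site_record(self):
        # of 100 spawned at A: 3 recruit elsewhere (B), 2 retained at A
        return RecruitmentRecord(site_ids=("A", "B"),
                                 counts=np.array([[2.0, 3.0], [0.0, 0.0]]),
                                 spawned=np.array([100.0, 0.0]))

    def test_recruitment_rate_formula(self):
        r = recruitment_rate(self.two_site_record())
        assert np.isclose(r["A"], 0.05)  # (3 + 2) / 100

    def test_recruitment_bounds(self):
        rec = RecruitmentRecord(("A", "B"), np.array([[50.0, 0.0], [0.0, 0.0]]),
                                np.array([50.0, 0.0]))
        assert recruitment_rate(rec)["A"] == 1.0

    def test_local_retention_formula(self):
        rec = RecruitmentRecord(("A",), np.array([[5.0]]), np.array([213.0]))
        assert np.isclose(local_retention(rec)["A"], 5.0 / 213.0, rtol=1e-12)

    def test_local_retention_undefined_without_spawn(self):
        with pytest.raises(ValidationError):
            local_retention(self.two_site_record())

    def test_no_spawn_at_all_is_error(self):
        rec = RecruitmentRecord(("A",), np.zeros((1, 1)), np.zeros(1))
        with pytest.raises(ValidationError):
            recruitment_rate(rec)

    def test_single_site_consistency_between_rates(self):
        # with one source site and all recruitment local, R·(N_s/N_i) = LR
        rec = RecruitmentRecord(("A",), np.array([[7.0]]), np.array([40.0]))
        r = recruitment_rate(rec)["A"]
        lr = local_retention(rec)["A"]
        assert np.isclose(r * (40.0 / 40.0), lr, rtol=1e-12)


class TestTPM:
    def test_toy_counting(self):
        reg = toy_registry()
        # 10 spawned at A: 3 end inside A, 2 inside B, 5 dead
        src = ["A"] * 10 + ["B"] * 5
        fate = [Fate.ALIVE] * 5 + [Fate.DEAD_HYPERTHERMIA] * 5 + [Fate.ALIVE] * 5
        lon = [0.0, 0.2, -0.3, 5.0, 5.1] + [0.0] * 5 + [5.0] * 5
        lat = [0.0] * 15
        tpm = build_tpm(detect_recruitment(make_ts(src, fate, lon, lat), reg), reg)
        np.testing.assert_allclose(tpm.P[0], [0.3, 0.2])
        np.testing.assert_allclose(tpm.P[1], [0.0, 1.0])

    def test_identity_when_everyone_retained(self):
        reg = toy_registry()
        ts = make_ts(["A", "B"], [Fate.ALIVE] * 2, [0.0, 5.0], [0.0, 0.0])
        tpm = build_tpm(detect_recruitment(ts, reg), reg)
        np.testing.assert_array_equal(tpm.P, np.eye(2))

    def test_dead_source_row_is_zero(self):
        reg = toy_registry()
        ts = make_ts(["A"] * 4 + ["B"], [Fate.DEAD_HYPERTHERMIA] * 4 + [Fate.ALIVE],
                     [0.0] * 4 + [5.0], [0.0] * 5)
        tpm = build_tpm(detect_recruitment(ts, reg), reg)
        assert np.all(tpm.P[0] == 0.0)

    def test_diagonal_equals_local_retention(self, registry):
        rng = np.random.default_rng(2)
        n = 90
        ids = list(registry.ids)
        source = rng.choice(ids, n)
        fate = rng.choice([Fate.ALIVE, Fate.ADVECTED_OUT], n)
        home = np.array([registry[s].centroid for s in source])
        lon = home[:, 0] + rng.normal(0, 0.2, n)
        lat = home[:, 1] + rng.normal(0, 0.2, n)
        rec = detect_recruitment(make_ts(source, fate, lon, lat), registry)
        tpm = build_tpm(rec, registry)
        np.testing.assert_allclose(np.diag(tpm.P), local_retention(rec).to_numpy())

    def test_row_accounting_is_exhaustive(self, registry):
        # row sum + (not-recruited fraction) = 1 for every source
        rng = np.random.default_rng(3)
        n = 100
        source = rng.choice(list(registry.ids), n)
        fate = rng.choice([Fate.ALIVE, Fate.DEAD_HYPOTHERMIA], n)
        home = np.array([registry[s].centroid for s in source])
        lon = home[:, 0] + rng.normal(0, 0.5, n)
        lat = home[:, 1] + rng.normal(0, 0.5, n)
        ts = make_ts(source, fate, lon, lat)
        rec = detect_recruitment(ts, registry)
        tpm = build_tpm(rec, registry)
        for i, sid in enumerate(registry.ids):
            sel = np.asarray(ts.source) == sid
            if not sel.any():
                continue
            n_i = sel.sum()
            recruited = rec.counts[i].sum()
            not_recruited = n_i - recruited  # dead or alive-but-outside
            assert np.isclose(tpm.P[i].sum() + not_recruited / n_i, 1.0, rtol=1e-12)

    def test_pooling_over_simulations(self):
        reg = toy_registry()
        r1 = RecruitmentRecord(("A", "B"), np.array([[1.0, 0], [0, 0]]), np.array([10.0, 5.0]))
        r2 = RecruitmentRecord(("A", "B"), np.array([[3.0, 0], [0, 0]]), np.array([10.0, 5.0]))
        tpm = build_tpm([r1, r2], reg)
        assert np.isclose(tpm.P[0, 0], 4.0 / 20.0)
        pooled = combine_records([r1, r2])
        assert pooled.n_spawned_total == 30.0


class TestDensityMap:
    def grid(self):
        return GridSpec(-1.0, 1.0, -1.0, 1.0, n_lon=11, n_lat=11, n_times=2)

    def stationary_set(self, n_alive=1, lon=0.0, lat=0.0):
        n = n_alive
        log_lon = np.full((4, n), lon, dtype=np.float32)
        log_lat = np.full((4, n), lat, dtype=np.float32)
        return make_ts(["A"] * n, [Fate.ALIVE] * n, [lon] * n, [lat] * n,
                       log=(log_lon, log_lat))

    def test_mass_is_one_and_concentrated(self):
        dm = density_map(self.stationary_set(), self.grid(), bandwidth_deg=0.2)
        assert np.isclose(dm.values.sum(), 1.0, rtol=1e-9)
        i = np.argmax(dm.values)
        iy, ix = np.unravel_index(i, dm.values.shape)
        assert np.isclose(dm.lons[ix], 0.0) and np.isclose(dm.lats[iy], 0.0)

    def test_zero_weight_set_does_not_contribute(self):
        alive = self.stationary_set(n_alive=100, lon=0.5)
        dead = make_ts(["A"], [Fate.DEAD_HYPERTHERMIA], [-0.5], [0.0],
                       log=(np.full((4, 1), -0.5, np.float32), np.zeros((4, 1), np.float32)))
        dm_both = density_map([alive, dead], self.grid())
        dm_alone = density_map([alive], self.grid())
        np.testing.assert_allclose(dm_both.values, dm_alone.values)

    def test_duplicate_sets_leave_map_unchanged(self):
        one = self.stationary_set(n_alive=10, lon=-0.4)
        dm1 = density_map([one], self.grid())
        dm2 = density_map([one, one], self.grid())
        np.testing.assert_allclose(dm1.values, dm2.values, rtol=1e-12)

    def test_no_survivors_flags_empty(self):
        dead = make_ts(["A"], [Fate.DEAD_HYPOTHERMIA], [0.0], [0.0],
                       log=(np.full((4, 1), np.nan, np.float32),
                            np.full((4, 1), np.nan, np.float32)))
        dm = density_map([dead], self.grid())
        assert dm.empty and dm.values.sum() == 0.0

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValidationError):
            density_map([self.stationary_set()], self.grid(), bandwidth_deg=0.0)


class TestFieldEvaluation:
    def test_identical_sequences(self):
        x = np.array([1.0, 2.0, 3.0])
        assert rmse(x, x) == 0.0 and bias(x, x) == 0.0

    def test_hand_computed_example(self):
        model, obs = [1.0, 2.0, 3.0], [0.0, 2.0, 4.0]
        assert np.isclose(bias(model, obs), 0.0)
        assert np.isclose(rmse(model, obs), np.sqrt(2.0 / 3.0), rtol=1e-12)

    def test_constant_offset(self):
        x = np.linspace(0, 5, 7)
        assert np.isclose(bias(x + 2.5, x), 2.5, rtol=1e-12)
        assert np.isclose(rmse(x + 2.5, x), 2.5, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            rmse([1.0, 2.0], [1.0])
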