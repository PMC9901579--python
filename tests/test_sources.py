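import numpy as np
import pytest

from patmap.activation import ActivationEvent, ActivationMatrix, PRIMARY
from patmap.sources import (
    classify_front_sources,
    classify_repetitiveness,
    conduction_vector_field,
    detect_activation_origins,
    dynamic_map_stack,
    leading_front_conduction_fields,
    leading_points,
)
from patmap.wavefronts import WaveFrontConfig, WaveFrontLabeling, label_wavefronts


def matrix_from(events, shape, dt_ms=1.0):
    evs = [ActivationEvent(x, y, t, PRIMARY, 0.5) for x, y, t in events]
    return ActivationMatrix.from_events(evs, shape=shape, dt_ms=dt_ms)


def labeled(events, shape, theta=50.0):
    mat = matrix_from(events, shape)
    return mat, label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=theta))


def spiral_events(ny=21, nx=21, period=100.0, cycles=3, r_in=3.0, r_out=9.5):
    """Idealized rotational activation: AT grows with angle around the core."""
    cy, cx = ny // 2, nx // 2
    events = []
    for y in range(ny):
        for x in range(nx):
            r = np.hypot(x - cx, y - cy)
            if not (r_in <= r <= r_out):
                continue
            ang = np.mod(np.arctan2(y - cy, x - cx), 2 * np.pi)
            for c in range(cycles):
                t = int(round((ang / (2 * np.pi) + c) * period))
                events.append((x, y, t))
    return events


class TestRepetitiveness:
    def test_single_beat_zero_repetitions(self):
        events = [(x, y, x, ) for y in range(8) for x in range(8)]
        events = [(x, y, t) for (x, y, t) in events]
        mat, lab = labeled(events, (100, 8, 8))
        res = classify_repetitiveness(lab, 1, erp_min_ms=50.0)
        assert res.classification == "non_repetitive"
        vals = res.count_map[np.isfinite(res.count_map)]
        assert np.all(vals == 0)

    def test_k_cycles_k_minus_1_repetitions(self):
        events = spiral_events(cycles=4, period=120.0)
        mat, lab = labeled(events, (600, 21, 21), theta=40.0)
        assert lab.n_labels == 1
        res = classify_repetitiveness(lab, 1, erp_min_ms=80.0)
        assert res.classification == "repetitive"
        peak = max(res.histogram, key=lambda k: res.histogram[k])
        assert peak == 3

    def test_below_erp_not_counted(self):
        events = [(0, 0, 0), (0, 0, 30), (1, 0, 5)]
        mat, lab = labeled(events, (100, 1, 2), theta=40.0)
        res = classify_repetitiveness(lab, 1, erp_min_ms=50.0)
        assert res.classification == "non_repetitive"
        assert res.count_map[0, 0] == 0

    def test_majority_rule_option(self):
        events = [(0, 0, 0), (0, 0, 100), (1, 0, 0)]
        mat, lab = labeled(events, (200, 1, 2), theta=150.0)
        mode = classify_repetitiveness(lab, 1, 50.0, rule="mode")
        majority = classify_repetitiveness(lab, 1, 50.0, rule="majority")
        # histogram {0: 1, 1: 1} -> mode picks the higher count; tie -> max count key
        assert majority.classification == "non_repetitive"
        assert set(mode.histogram.items()) == {(0, 1), (1, 1)}


class TestOrigins:
    def test_interior_focal_breakthrough_centroid(self):
        # radial activation from (10, 10) on a 21x21 sheet
        events = []
        for y in range(21):
            for x in range(21):
                events.append((x, y, int(round(3 * np.hypot(x - 10, y - 10)))))
        mat, lab = labeled(events, (200, 21, 21), theta=20.0)
        mask = np.ones((21, 21), bool)
        o = detect_activation_origins(lab, 1, 80.0, mask)
        assert len(o.clusters) == 1
        c = o.clusters[0]
        assert c.kind == "breakthrough"
        assert abs(c.centroid[0] - 10) <= 1 and abs(c.centroid[1] - 10) <= 1

    def test_planar_entry_origins_passive_on_edge(self):
        events = [(x, y, 4 * x) for y in range(10) for x in range(10)]
        mat, lab = labeled(events, (100, 10, 10), theta=20.0)
        o = detect_activation_origins(lab, 1, 60.0, np.ones((10, 10), bool))
        assert len(o.clusters) >= 1
        for c in o.clusters:
            assert c.kind == "passive"
            assert all(x == 0 for x, y, t in c.members)

    def test_broad_plateau_fed_by_peripheral_source_rejected(self):
        # early edge source feeds a broad simultaneous interior plateau
        events = [(0, y, 0) for y in range(10)]           # peripheral source
        events += [(1, y, 10) for y in range(10)]          # conduction step
        events += [(x, y, 20) for y in range(10) for x in range(2, 8)]  # plateau
        mat, lab = labeled(events, (100, 10, 10), theta=30.0)
        o = detect_activation_origins(lab, 1, 60.0, np.ones((10, 10), bool))
        # only the genuine left-edge origin survives
        assert len(o.clusters) == 1
        assert all(x == 0 for x, y, t in o.clusters[0].members)

    def test_occurrence_map_incremented_per_member(self):
        events = [(x, y, int(round(3 * np.hypot(x - 5, y - 5))))
                  for y in range(11) for x in range(11)]
        mat, lab = labeled(events, (100, 11, 11), theta=20.0)
        o = detect_activation_origins(lab, 1, 50.0, np.ones((11, 11), bool))
        assert o.occurrence_map.sum() == sum(len(c.members) for c in o.clusters)
        assert o.centroid_map.sum() == len(o.clusters)

    def test_three_simultaneous_foci_recovered(self):
        foci = [(8, 8), (30, 8), (19, 30)]
        events = []
        for y in range(40):
            for x in range(40):
                t = min(np.hypot(x - fx, y - fy) for fx, fy in foci)
                events.append((x, y, int(round(3 * t))))
        mat, lab = labeled(events, (300, 40, 40), theta=20.0)
        o = detect_activation_origins(lab, 1, 100.0, np.ones((40, 40), bool))
        bts = o.of_kind("breakthrough")
        assert len(bts) == 3
        got = sorted(c.centroid for c in bts)
        for (gx, gy), (fx, fy) in zip(got, sorted(foci)):
            assert abs(gx - fx) <= 1 and abs(gy - fy) <= 1


class TestDynamicMapStack:
    def test_single_beat_single_map(self):
        events = [(x, y, 2 * x) for y in range(6) for x in range(6)]
        x, y, t = (np.array(v) for v in zip(*events))
        dyn = dynamic_map_stack((x, y, t.astype(float)), (6, 6))
        assert len(dyn) == 1
        assert np.isfinite(dyn.maps[0].values).sum() == 36

    def test_two_cycles_at_least_two_maps_span_bounded(self):
        events = spiral_events(cycles=2, period=100.0)
        x, y, t = (np.array(v) for v in zip(*events))
        dyn = dynamic_map_stack((x, y, t.astype(float)), (21, 21))
        assert len(dyn) >= 2
        for m in dyn:
            vals = m.values[m.fresh]
            assert vals.max() - vals.min() <= 100.0 + 1

    def test_conservation_every_event_mapped_once(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.integers(0, 15, n)
        y = rng.integers(0, 15, n)
        t = rng.integers(0, 500, n).astype(float)
        dyn = dynamic_map_stack((x, y, t), (15, 15))
        fresh_vals = np.concatenate([m.values[m.fresh] for m in dyn])
        assert sorted(fresh_vals.tolist()) == sorted(t.tolist())

    def test_window_filtering_and_empty_error(self):
        x = np.array([0]); y = np.array([0]); t = np.array([10.0])
        assert len(dynamic_map_stack((x, y, t), (2, 2), (0.0, 5.0))) == 0
        with pytest.raises(ValueError):
            dynamic_map_stack((x, y, t), (2, 2), (5.0, 5.0))


class TestConductionVectors:
    def test_planar_ramp_unit_x(self):
        at = np.tile(np.arange(10.0) * 4, (10, 1))
        v = conduction_vector_field(at)
        ok = np.isfinite(v[..., 0])
        assert ok.all()
        assert np.allclose(v[ok][:, 0], 1.0, atol=1e-9)
        assert np.allclose(v[ok][:, 1], 0.0, atol=1e-9)

    def test_radial_cone_points_outward(self):
        yy, xx = np.mgrid[0:21, 0:21]
        at = 3.0 * np.hypot(xx - 10, yy - 10)
        v = conduction_vector_field(at)
        for y in range(2, 19):
            for x in range(2, 19):
                r = np.hypot(x - 10, y - 10)
                if r < 3:
                    continue
                u = v[y, x]
                truth = np.array([x - 10, y - 10]) / r
                ang = np.degrees(np.arccos(np.clip(u @ truth, -1, 1)))
                assert ang < 5.0

    def test_uniform_patch_undefined(self):
        at = np.full((7, 7), 42.0)
        v = conduction_vector_field(at)
        assert not np.isfinite(v).any()


class TestConductionFields:
    def _planar(self, nx=12, ny=8, step=4.0):
        at = np.tile(np.arange(nx) * step, (ny, 1))
        v = conduction_vector_field(at)
        return at, v

    def test_planar_leading_edge_and_back_corridor(self):
        at, v = self._planar()
        pts = leading_points(at)
        assert all(x == 11 for x, y in pts)
        fields = leading_front_conduction_fields(at, v, theta_t_cb_ms=5.0)
        f = next(fl for fl in fields if fl.leading_point == (11, 4))
        xs = {x for x, y in f.points}
        assert xs == set(range(12))
        assert {y for x, y in f.points} == {4}

    def test_two_independent_fronts_disjoint_fields(self):
        at = np.full((8, 13), np.nan)
        at[:, :6] = np.tile(np.arange(6) * 4.0, (8, 1))          # left front
        at[:, 7:] = np.tile(np.arange(6) * 4.0, (8, 1))[:, ::-1]  # right front
        v = conduction_vector_field(at)
        fields = leading_front_conduction_fields(at, v, theta_t_cb_ms=5.0)
        left = [f for f in fields if f.leading_point[0] == 5]
        right = [f for f in fields if f.leading_point[0] == 7]
        assert left and right
        for fl in left:
            for fr in right:
                assert not (fl.points & fr.points)

    def test_no_upstream_neighbor_field_is_self(self):
        at = np.full((5, 5), np.nan)
        at[2, 2] = 10.0
        v = conduction_vector_field(at)
        fields = leading_front_conduction_fields(at, v, 5.0)
        assert len(fields) == 1
        assert fields[0].points == {(2, 2)}


class TestClassification:
    def _setup_planar(self):
        events = [(x, y, 4 * x) for y in range(10) for x in range(10)]
        mat, lab = labeled(events, (100, 10, 10), theta=20.0)
        o = detect_activation_origins(lab, 1, 60.0, np.ones((10, 10), bool))
        at = np.full((10, 10), np.nan)
        for x, y, t in events:
            at[y, x] = t
        v = conduction_vector_field(at)
        fields = leading_front_conduction_fields(at, v, 20.0)
        return fields, o, at, lab

    def test_passive_edge_driven_wave(self):
        fields, o, at, lab = self._setup_planar()
        cls = classify_front_sources(fields, o, at, 60.0, 20.0, lab, 1)
        assert cls.percentages["passive"] == 100.0
        assert sum(cls.percentages.values()) == pytest.approx(100.0)

    def test_breakthrough_focal_episode(self):
        events = [(x, y, int(round(4 * np.hypot(x - 7, y - 7))))
                  for y in range(15) for x in range(15)]
        mat, lab = labeled(events, (100, 15, 15), theta=20.0)
        o = detect_activation_origins(lab, 1, 60.0, np.ones((15, 15), bool))
        at = np.full((15, 15), np.nan)
        for x, y, t in events:
            at[y, x] = t
        v = conduction_vector_field(at)
        fields = leading_front_conduction_fields(at, v, 20.0)
        cls = classify_front_sources(fields, o, at, 60.0, 20.0, lab, 1)
        assert cls.counts["breakthrough"] > 0

    def test_myocardial_reentry_across_core(self):
        # rotational one-cycle map: field wraps the annulus; neighbors across
        # the branch cut differ by ~period >> ERPmin
        events = spiral_events(cycles=1, period=300.0, ny=21, nx=21)
        at = np.full((21, 21), np.nan)
        for x, y, t in events:
            at[y, x] = t
        v = conduction_vector_field(at, max_dt_ms=120.0)
        fields = leading_front_conduction_fields(at, v, theta_t_cb_ms=60.0)
        mat, lab = labeled(events, (400, 21, 21), theta=60.0)
        o = detect_activation_origins(lab, 1, 100.0, np.ones((21, 21), bool))
        cls = classify_front_sources(fields, o, at, 100.0, 60.0, lab, 1)
        assert cls.counts["myocardial_reentry"] > 0

    def test_percentages_invariant_to_time_shift(self):
        fields, o, at, lab = self._setup_planar()
        cls1 = classify_front_sources(fields, o, at, 60.0, 20.0, lab, 1)
        # shift all times by a constant
        events = [(x, y, 4 * x + 500) for y in range(10) for x in range(10)]
        mat2, lab2 = labeled(events, (600, 10, 10), theta=20.0)
        o2 = detect_activation_origins(lab2, 1, 60.0, np.ones((10, 10), bool))
        at2 = at + 500.0
        v2 = conduction_vector_field(at2)
        fields2 = leading_front_conduction_fields(at2, v2, 20.0)
        cls2 = classify_front_sources(fields2, o2, at2, 60.0, 20.0, lab2, 1)
        assert cls1.percentages == cls2.percentages
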