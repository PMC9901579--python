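import numpy as np
import pytest

from patmap.activation import ActivationMatrix, ActivationEvent, PRIMARY, SECONDARY
from patmap.wavefronts import (
    WaveFrontConfig,
    estimate_conduction_block_threshold,
    label_wavefronts,
    wavefront_at_maps,
)


def matrix_from(events, shape, dt_ms=1.0):
    evs = [ActivationEvent(x, y, t, comp, 0.5) for x, y, t, comp in events]
    return ActivationMatrix.from_events(evs, shape=shape, dt_ms=dt_ms)


def planar_matrix(nx=10, ny=10, t0=0, step=1, nt=200):
    events = [(x, y, t0 + step * x, PRIMARY) for y in range(ny) for x in range(nx)]
    return matrix_from(events, (nt, ny, nx))


def brute_force_labels(matrix, theta_ms):
    """Independent oracle: transitive closure of pairwise connectivity."""
    import networkx as g

    n = len(matrix)
    graph = g.Graph()
    graph.add_nodes_from(range(n))
    theta_f = theta_ms / matrix.dt_ms
    for i in range(n):
        for j in range(i + 1, n):
            dx = abs(int(matrix.x[i]) - int(matrix.x[j]))
            dy = abs(int(matrix.y[i]) - int(matrix.y[j]))
            dt = abs(int(matrix.t[i]) - int(matrix.t[j]))
            if max(dx, dy) == 1 and dt <= theta_f:
                graph.add_edge(i, j)
    comp = np.empty(n, dtype=int)
    for k, cc in enumerate(g.connected_components(graph)):
        for i in cc:
            comp[i] = k
    return comp


def same_partition(a, b):
    seen = {}
    for x, y in zip(a.tolist(), b.tolist()):
        if x in seen:
            if seen[x] != y:
                return False
        else:
            seen[x] = y
    return len(set(seen.values())) == len(seen)


class TestThetaEstimation:
    def test_engineered_slow_pathway(self):
        # one neighbor pair shows a 60 ms delay exactly 4 times; everything
        # else conducts at < 60 ms
        events = []
        for beat in range(4):
            base = beat * 300
            for x in range(6):
                events.append((x, 0, base + 5 * x, PRIMARY))   # fast row
            events.append((0, 1, base, PRIMARY))
            events.append((1, 1, base + 60, PRIMARY))          # slow pair
        mat = matrix_from(events, (1400, 2, 6))
        assert estimate_conduction_block_threshold(mat, 4, 6, 2) == 60.0

    def test_uniform_planar_single_delay(self):
        mat = planar_matrix(step=1)
        assert estimate_conduction_block_threshold(mat, 1, 10, 10) == 1.0

    def test_recurrence_within_one_pair_required(self):
        # four different pairs each showing 80 ms once must not qualify at n=4
        events = []
        for beat in range(4):
            base = beat * 400
            for x in range(8):
                events.append((x, 0, base + 2 * x, PRIMARY))
            # one-off late event at a different pixel each beat
            events.append((beat * 2, 1, base + 2 * beat * 2 + 80, PRIMARY))
        mat = matrix_from(events, (2000, 2, 8))
        theta = estimate_conduction_block_threshold(mat, 4, 8, 2)
        assert theta < 80.0

    def test_no_qualifying_delay_errors(self):
        mat = matrix_from([(0, 0, 0, PRIMARY), (5, 5, 50, PRIMARY)], (100, 6, 6))
        with pytest.raises(ValueError):
            estimate_conduction_block_threshold(mat, 2, 6, 6)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            estimate_conduction_block_threshold(planar_matrix(), 0, 10, 10)


class TestLabeling:
    def test_single_planar_wave_one_label(self):
        lab = label_wavefronts(planar_matrix(), WaveFrontConfig(theta_t_cb_ms=5))
        assert lab.n_labels == 1

    def test_two_separated_beats_two_labels(self):
        m1 = [(x, y, x, PRIMARY) for y in range(6) for x in range(6)]
        m2 = [(x, y, 100 + x, PRIMARY) for y in range(6) for x in range(6)]
        mat = matrix_from(m1 + m2, (200, 6, 6))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=10))
        assert lab.n_labels == 2

    def test_labels_contiguous_first_event_order(self):
        m1 = [(x, y, 100 + x, PRIMARY) for y in range(4) for x in range(4)]
        m2 = [(x, y, x, PRIMARY) for y in range(4) for x in range(4)]
        mat = matrix_from(m1 + m2, (300, 4, 4))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=10))
        first = {}
        for i, lbl in enumerate(lab.labels):
            first.setdefault(int(lbl), int(mat.t[i]))
        assert sorted(first) == list(range(1, lab.n_labels + 1))
        assert first[1] < first[2]

    def test_partition_invariant(self):
        rng = np.random.default_rng(0)
        events = [(int(x), int(y), int(t), PRIMARY)
                  for x, y, t in zip(rng.integers(0, 12, 150),
                                     rng.integers(0, 12, 150),
                                     rng.integers(0, 300, 150))]
        events = list({e[:3]: e for e in events}.values())
        mat = matrix_from(events, (300, 12, 12))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=20))
        total = sum(v["n_events"] for v in lab.info.values())
        assert total == len(mat)
        assert (lab.labels >= 1).all()

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        events = [(int(x), int(y), int(t), PRIMARY)
                  for x, y, t in zip(rng.integers(0, 15, n),
                                     rng.integers(0, 15, n),
                                     rng.integers(0, 400, n))]
        events = list({e[:3]: e for e in events}.values())
        mat = matrix_from(events, (400, 15, 15))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=30))
        oracle = brute_force_labels(mat, 30)
        assert same_partition(lab.labels, oracle)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        events = [(int(x), int(y), int(t), PRIMARY)
                  for x, y, t in zip(rng.integers(0, 10, 80),
                                     rng.integers(0, 10, 80),
                                     rng.integers(0, 200, 80))]
        events = list({e[:3]: e for e in events}.values())
        mat = matrix_from(events, (200, 10, 10))
        cfg = WaveFrontConfig(theta_t_cb_ms=15)
        l1 = label_wavefronts(mat, cfg)
        l2 = label_wavefronts(mat, cfg)
        assert np.array_equal(l1.labels, l2.labels)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_monotone_in_theta(self, seed):
        rng = np.random.default_rng(seed)
        events = [(int(x), int(y), int(t), PRIMARY)
                  for x, y, t in zip(rng.integers(0, 12, 100),
                                     rng.integers(0, 12, 100),
                                     rng.integers(0, 300, 100))]
        events = list({e[:3]: e for e in events}.values())
        mat = matrix_from(events, (300, 12, 12))
        prev = None
        for theta in (2, 5, 10, 20, 50, 100):
            n = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=theta)).n_labels
            if prev is not None:
                assert n <= prev
            prev = n

    def test_temporal_connectivity_symmetric_closed(self):
        mat = matrix_from([(0, 0, 0, PRIMARY), (1, 0, 10, PRIMARY)], (50, 2, 2))
        assert label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=10)).n_labels == 1
        assert label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=9.5)).n_labels == 2

    def test_exclude_secondary_option(self):
        mat = matrix_from([(0, 0, 0, PRIMARY), (1, 0, 5, SECONDARY)], (50, 2, 2))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=10,
                                                    include_secondary=False))
        assert lab.n_labels == 1
        assert lab.labels[mat.component == 1][0] == 0

    def test_erp_warning(self):
        with pytest.warns(UserWarning, match="erp_min_ms"):
            WaveFrontConfig(theta_t_cb_ms=50, erp_min_ms=40)


class TestWaveFrontMaps:
    def test_planar_label_affine_secondary_empty(self):
        mat = planar_matrix(step=2)
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=5))
        primary, secondary = wavefront_at_maps(mat, lab, 1)
        xs = np.arange(10)
        assert np.allclose(primary[4], 2.0 * xs)
        assert not np.isfinite(secondary).any()

    def test_biphasic_pixel_populates_both_maps(self):
        events = [(0, 0, 10, PRIMARY), (0, 0, 40, SECONDARY), (1, 0, 12, PRIMARY)]
        mat = matrix_from(events, (100, 1, 2))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=50))
        primary, secondary = wavefront_at_maps(mat, lab, 1)
        assert primary[0, 0] == 10.0
        assert secondary[0, 0] == 40.0
        assert secondary[0, 0] > primary[0, 0]

    def test_unvisited_pixels_sentinel(self):
        mat = matrix_from([(0, 0, 0, PRIMARY)], (50, 3, 3))
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=10))
        primary, _ = wavefront_at_maps(mat, lab, 1)
        assert np.isfinite(primary).sum() == 1

    def test_unknown_label_rejected(self):
        mat = planar_matrix()
        lab = label_wavefronts(mat, WaveFrontConfig(theta_t_cb_ms=5))
        with pytest.raises(KeyError):
            wavefront_at_maps(mat, lab, 99)
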