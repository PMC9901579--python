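"""Shared fixtures and signal constructors for the test suite."""

from __future__ import annotations

import logging

import numpy as np
import pytest

import patmap
from patmap import synthetic as syn

logging.disable(logging.INFO)


def make_ap_train(nt: int = 4000, period: int = 500, start: int = 200,
                  apd: int = 200, rise: int = 10, fs: float = 1000.0) -> np.ndarray:
    """Noiseless periodic action-potential-like train (smooth edges)."""
    t = np.arange(nt)
    sig = np.zeros(nt)
    for t0 in range(start, nt - apd - rise, period):
        up = slice(t0, t0 + rise)
        sig[up] = 0.5 * (1 - np.cos(np.pi * np.arange(rise) / rise))
        sig[t0 + rise:t0 + apd] = 1.0
        fall = slice(t0 + apd, t0 + apd + 4 * rise)
        n = sig[fall].size
        sig[fall] = 0.5 * (1 + np.cos(np.pi * np.arange(n) / n))
    return sig


def make_biphasic_signal(depth: float, peak: float = 1.0, n_ramp: int = 20,
                         gap: int = 30, dt_ms: float = 1.0
                         ) -> tuple[np.ndarray, tuple[int, int], int, int]:
    """Signal whose central-difference derivative has two equal maxima
    (3-sample plateaus of height ``peak``) separated by a valley plateau at
    ``peak * (1 - depth)``.  The plateaus make the measured extrema exact.

    Returns (signal, window, t_peak1, t_peak2).
    """
    v = peak * (1.0 - depth)
    g = np.concatenate([
        np.zeros(5),
        np.linspace(0, peak, n_ramp, endpoint=False),
        np.full(3, peak),
        np.linspace(peak, v, n_ramp, endpoint=False),
        np.full(gap, v),
        np.linspace(v, peak, n_ramp, endpoint=False),
        np.full(3, peak),
        np.linspace(peak, 0, n_ramp, endpoint=False),
        np.zeros(5),
    ])
    sig = np.concatenate([[0.0], np.cumsum(g) * dt_ms])
    t1 = 5 + n_ramp + 1          # leftmost sample of first derivative plateau
    t2 = t1 + 2 * n_ramp + gap + 3
    return sig, (0, sig.size), t1, t2


def brute_force_window_events(sig: np.ndarray, intervals, threshold: float,
                              dt_ms: float = 1.0) -> list[int]:
    """Independent oracle: per retained window, the argmax of the explicit
    central-difference derivative (one event per window, no biphasic
    resolution)."""
    d = np.empty_like(sig)
    d[1:-1] = (sig[2:] - sig[:-2]) / (2 * dt_ms)
    d[0] = (sig[1] - sig[0]) / dt_ms
    d[-1] = (sig[-1] - sig[-2]) / dt_ms
    out = []
    for (a, b) in intervals:
        seg = d[a:b]
        tt = np.arange(a, b)
        coeffs = np.polyfit(tt * dt_ms, sig[a:b], 1)
        if coeffs[0] <= 0 or seg.max() < threshold:
            continue
        out.append(a + int(np.argmax(seg)))
    return out


@pytest.fixture(scope="session")
def planar_run():
    """Noiseless single planar beat, full detection chain (40x40)."""
    scn = syn.planar_scenario(nx=40, ny=40, duration_ms=900, beats=1)
    mem, truth = syn.simulate_excitable_sheet(scn)
    raw = syn.emulate_optical_observation(mem, blur_sigma_px=0.5, snr_target=None)
    stack = patmap.precondition_stack(raw, dt_ms=scn.dt_ms, pitch_mm=scn.pitch_mm)
    wm = patmap.stack_upstroke_windows(stack)
    thr = patmap.auto_derivative_threshold(stack, wm)
    mat = patmap.build_activation_matrix(stack, wm, thr)
    lab = patmap.label_wavefronts(mat, patmap.WaveFrontConfig(theta_t_cb_ms=20.0))
    return {"scenario": scn, "membrane": mem, "truth": truth, "stack": stack,
            "windows": wm, "threshold": thr, "matrix": mat, "labeling": lab}


@pytest.fixture(scope="session")
def two_beat_run():
    """Noiseless two-beat planar recording (30x30), detection chain."""
    scn = syn.planar_scenario(nx=30, ny=30, duration_ms=1500, beats=2,
                              interval_ms=700)
    mem, truth = syn.simulate_excitable_sheet(scn)
    raw = syn.emulate_optical_observation(mem, blur_sigma_px=0.5, snr_target=None)
    stack = patmap.precondition_stack(raw, dt_ms=scn.dt_ms, pitch_mm=scn.pitch_mm)
    wm = patmap.stack_upstroke_windows(stack)
    thr = patmap.auto_derivative_threshold(stack, wm)
    mat = patmap.build_activation_matrix(stack, wm, thr)
    lab = patmap.label_wavefronts(mat, patmap.WaveFrontConfig(theta_t_cb_ms=20.0))
    return {"scenario": scn, "membrane": mem, "truth": truth, "stack": stack,
            "windows": wm, "threshold": thr, "matrix": mat, "labeling": lab}
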