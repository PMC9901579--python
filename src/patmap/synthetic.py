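"""Ground-truthed synthetic optical-mapping stacks.

A two-variable phenomenological excitable medium (Aliev-Panfilov-type
reaction-diffusion) on a 2-D sheet stands in for detailed ionic models:
the analysis pipeline only needs realistic activation/repolarization
morphology.  Scenarios cover planar paced waves, focal (point) sources,
S1S2S3S4 short-coupled trains and cross-field-induced spiral reentry.
An optical observation model adds spatial blur, signal inversion,
baseline drift and calibrated noise.

Membrane excitation variable u is dimensionless in [0, ~1]; ground-truth
activation (eAT) is the upward crossing of u through 50% of its range.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
from scipy import ndimage, stats

from .stack import defined

#: Default reaction parameters (Aliev-Panfilov form) and the time scale
#: mapping one model time unit to milliseconds.
DEFAULT_MODEL = {
    "k": 8.0,
    "a": 0.1,
    "eps0": 0.02,
    "mu1": 0.3,
    "mu2": 0.3,
    "time_scale_ms": 12.9,
    "diffusion_mm2_ms": 0.1,
}


@dataclass
class Stimulus:
    """One stimulus event.

    kind:
      * ``planar_edge`` — raise u along one border strip
        (geometry: side in {left,right,top,bottom}, width_px)
      * ``point`` — raise u in a disc (geometry: x, y, radius_px)
      * ``cross_field`` — raise u over a half-plane fraction of the sheet
        (geometry: side, fraction)
    """

    kind: str
    t_ms: float
    geometry: dict[str, Any] = field(default_factory=dict)
    amplitude: float = 1.0


@dataclass
class SimScenario:
    nx: int = 100
    ny: int = 100
    pitch_mm: float = 0.7
    dt_ms: float = 1.0                  # sampling interval of the output stack
    duration_ms: float = 2000.0
    dt_int_ms: float = 0.5              # explicit integration step
    model: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MODEL))
    stimuli: list[Stimulus] = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimScenario":
        d = json.loads(text)
        d["stimuli"] = [Stimulus(**s) for s in d.get("stimuli", [])]
        return cls(**d)


@dataclass
class GroundTruth:
    """eAT events and scenario truth for validating the pipeline."""

    x: np.ndarray
    y: np.ndarray
    t_ms: np.ndarray
    shape: tuple[int, int]              # (ny, nx)
    origins: list[dict[str, Any]] = field(default_factory=list)
    apd_map_ms: np.ndarray | None = None

    def first_beat_map(self, t0_ms: float = -np.inf, t1_ms: float = np.inf
                       ) -> np.ndarray:
        """Earliest eAT per pixel within a time window, NaN sentinel (ms)."""
        out = np.full(self.shape, np.nan)
        sel = (self.t_ms >= t0_ms) & (self.t_ms < t1_ms)
        order = np.argsort(self.t_ms[sel], kind="stable")[::-1]
        xs, ys, ts = self.x[sel][order], self.y[sel][order], self.t_ms[sel][order]
        out[ys, xs] = ts
        return out

    def beats_at(self, x: int, y: int) -> np.ndarray:
        sel = (self.x == x) & (self.y == y)
        return np.sort(self.t_ms[sel])


def _stim_mask(stim: Stimulus, ny: int, nx: int) -> np.ndarray:
    g = stim.geometry
    m = np.zeros((ny, nx), dtype=bool)
    if stim.kind == "planar_edge":
        side = g.get("side", "left")
        w = int(g.get("width_px", 3))
        if side == "left":
            m[:, :w] = True
        elif side == "right":
            m[:, -w:] = True
        elif side == "top":
            m[:w, :] = True
        elif side == "bottom":
            m[-w:, :] = True
        else:
            raise ValueError(f"unknown side {side!r}")
    elif stim.kind == "point":
        yy, xx = np.mgrid[0:ny, 0:nx]
        r = float(g.get("radius_px", 2.0))
        m = (xx - g["x"]) ** 2 + (yy - g["y"]) ** 2 <= r ** 2
    elif stim.kind == "cross_field":
        side = g.get("side", "bottom")
        frac = float(g.get("fraction", 0.5))
        if side == "bottom":
            m[int(round(ny * (1 - frac))):, :] = True
        elif side == "top":
            m[:int(round(ny * frac)), :] = True
        elif side == "left":
            m[:, :int(round(nx * frac))] = True
        elif side == "right":
            m[:, int(round(nx * (1 - frac))):] = True
        else:
            raise ValueError(f"unknown side {side!r}")
    else:
        raise ValueError(f"unknown stimulus kind {stim.kind!r}")
    if not m.any():
        raise ValueError("stimulus geometry selects no pixels")
    return m


def simulate_excitable_sheet(scenario: SimScenario) -> tuple[np.ndarray, GroundTruth]:
    """Integrate the excitable sheet and record membrane stack + ground truth.

    Explicit Euler with a 5-point Laplacian and no-flux boundaries;
    deterministic for a fixed scenario.  eAT events are upward crossings
    of u through 0.5 detected at the sampling resolution, with linear
    sub-sample interpolation, then kept in ms.

    Raises
    ------
    ValueError
        If the integration step violates the diffusion CFL condition.
    """
    p = {**DEFAULT_MODEL, **scenario.model}
    h = scenario.pitch_mm
    d_coef = p["diffusion_mm2_ms"]
    dt = scenario.dt_int_ms
    if dt > h * h / (4.0 * d_coef):
        raise ValueError(
            f"dt_int_ms={dt} violates CFL limit {h * h / (4 * d_coef):.3f} ms "
            f"for D={d_coef} mm^2/ms, pitch={h} mm")
    ny, nx = scenario.ny, scenario.nx
    n_steps = int(round(scenario.duration_ms / dt))
    sample_every = max(1, int(round(scenario.dt_ms / dt)))
    nt = n_steps // sample_every
    tau = p["time_scale_ms"]
    k, a, eps0, mu1, mu2 = p["k"], p["a"], p["eps0"], p["mu1"], p["mu2"]

    u = np.zeros((ny, nx), dtype=np.float64)
    v = np.zeros((ny, nx), dtype=np.float64)
    stack = np.empty((nt, ny, nx), dtype=np.float32)
    stims = sorted(scenario.stimuli, key=lambda s: s.t_ms)
    stim_masks = [_stim_mask(s, ny, nx) for s in stims]
    next_stim = 0

    ex: list[np.ndarray] = []
    ey: list[np.ndarray] = []
    et: list[np.ndarray] = []
    prev_sample = u.copy()
    frame = 0
    lap = np.empty_like(u)
    for step in range(n_steps):
        t_ms = step * dt
        while next_stim < len(stims) and stims[next_stim].t_ms <= t_ms:
            m = stim_masks[next_stim]
            u[m] = np.maximum(u[m], stims[next_stim].amplitude)
            next_stim += 1
        # no-flux Laplacian
        lap[:] = -4.0 * u
        lap[1:, :] += u[:-1, :]
        lap[:-1, :] += u[1:, :]
        lap[:, 1:] += u[:, :-1]
        lap[:, :-1] += u[:, 1:]
        lap[0, :] += u[0, :]
        lap[-1, :] += u[-1, :]
        lap[:, 0] += u[:, 0]
        lap[:, -1] += u[:, -1]
        du = d_coef * lap / (h * h) + (k * u * (u - a) * (1.0 - u) - u * v) / tau
        dv = (eps0 + mu1 * v / (u + mu2)) * (-v - k * u * (u - a - 1.0)) / tau
        u += dt * du
        v += dt * dv
        if (step + 1) % sample_every == 0:
            np.clip(u, 0.0, None, out=u)
            stack[frame] = u
            crossed = (prev_sample < 0.5) & (u >= 0.5)
            if crossed.any():
                ys, xs = np.nonzero(crossed)
                # linear interpolation between samples for sub-frame timing
                f = (0.5 - prev_sample[ys, xs]) / (u[ys, xs] - prev_sample[ys, xs])
                ex.append(xs)
                ey.append(ys)
                et.append((frame - 1 + f) * scenario.dt_ms)
            prev_sample = u.copy()
            frame += 1

    origins = [{"kind": s.kind, "t_ms": s.t_ms, **s.geometry} for s in stims]
    truth = GroundTruth(
        x=np.concatenate(ex).astype(np.int32) if ex else np.empty(0, np.int32),
        y=np.concatenate(ey).astype(np.int32) if ey else np.empty(0, np.int32),
        t_ms=np.concatenate(et) if et else np.empty(0),
        shape=(ny, nx),
        origins=origins,
    )
    return stack, truth


def emulate_optical_observation(
    membrane: np.ndarray,
    blur_sigma_px: float = 1.0,
    snr_target: float | None = None,
    drift_per_s: float = 0.0,
    dt_ms: float = 1.0,
    seed: int = 0,
    offset: float = 1000.0,
    gain: float = 100.0,
) -> np.ndarray:
    """Turn a membrane stack into a raw fluorescence-like stack.

    Applies Gaussian spatial blur, inverts the sign (fluorescence falls on
    depolarization), optionally adds a linear baseline drift, and adds
    white Gaussian noise calibrated so that the measured SNR — peak-to-peak
    of the 60 Hz-low-passed signal over the SD of the residual, the
    pre-processing module's definition — matches ``snr_target`` (median
    over a pixel subsample; iterative rescaling because noise leaks into
    the low-passed peak-to-peak).  ``snr_target=None`` means noiseless.
    """
    if blur_sigma_px < 0:
        raise ValueError("blur_sigma_px must be >= 0")
    if snr_target is not None and snr_target <= 0:
        raise ValueError("snr_target must be > 0")
    out = membrane.astype(np.float32)
    if blur_sigma_px > 0:
        out = ndimage.gaussian_filter(out, sigma=(0, blur_sigma_px, blur_sigma_px))
    out = offset - gain * out
    nt = out.shape[0]
    if drift_per_s:
        t_s = np.arange(nt, dtype=np.float32) * (dt_ms / 1000.0)
        out = out + (gain * drift_per_s) * t_s[:, None, None]
    if snr_target is not None:
        rng = np.random.default_rng(seed)
        p2p = np.ptp(out - out.mean(axis=0), axis=0)
        amp = float(np.median(p2p[p2p > 0])) if (p2p > 0).any() else gain
        noise = rng.normal(0.0, 1.0, size=out.shape).astype(np.float32)
        # subsample of active pixels for measurement
        ys, xs = np.nonzero(p2p > 0)
        if ys.size:
            pick = rng.choice(ys.size, size=min(128, ys.size), replace=False)
            sub = out[:, ys[pick], xs[pick]].astype(np.float64)
            nsub = noise[:, ys[pick], xs[pick]].astype(np.float64)
            sigma = amp / snr_target
            for _ in range(3):
                measured = _median_snr(sub + sigma * nsub, dt_ms)
                sigma *= measured / snr_target
        else:
            sigma = amp / snr_target
        out = out + (sigma * noise).astype(np.float32)
    return out


def _median_snr(sig: np.ndarray, dt_ms: float, cutoff_hz: float = 60.0) -> float:
    """Median per-pixel SNR of a (nt, npix) array, pre-processing definition."""
    from scipy import signal as ss

    fs = 1000.0 / dt_ms
    sos = ss.butter(3, cutoff_hz / (fs / 2.0), btype="low", output="sos")
    low = ss.sosfiltfilt(sos, sig, axis=0)
    enbw = cutoff_hz * (np.pi / 6.0) / np.sin(np.pi / 6.0)
    corr = np.sqrt(max(1.0 - enbw / (fs / 2.0), 1e-6))
    resid_sd = (sig - low).std(axis=0) / corr
    p2p = np.percentile(low, 99, axis=0) - np.percentile(low, 1, axis=0)
    with np.errstate(divide="ignore"):
        snr = p2p / resid_sd
    return float(np.median(snr))


def at_map_agreement(candidate: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Pixel-to-pixel linear-regression agreement of two AT maps.

    Returns R^2, slope, intercept, the number of common pixels and the
    5th-to-95th percentile AT span ("total AT") of each map.
    """
    if candidate.shape != truth.shape:
        raise ValueError("maps must share a shape")
    common = defined(candidate) & defined(truth)
    n = int(common.sum())
    if n < 10:
        raise ValueError(f"only {n} common pixels (< 10)")
    c = candidate[common]
    t = truth[common]
    res = stats.linregress(t, c)
    span = lambda m: float(np.percentile(m, 95) - np.percentile(m, 5))  # noqa: E731
    return {
        "r2": float(res.rvalue ** 2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "n": n,
        "total_at_candidate_ms": span(c),
        "total_at_truth_ms": span(t),
    }


# ---------------------------------------------------------------------------
# ready-made scenarios
# ---------------------------------------------------------------------------

def planar_scenario(nx: int = 60, ny: int = 60, duration_ms: float = 1200.0,
                    beats: int = 1, interval_ms: float = 600.0,
                    t0_ms: float = 20.0, seed: int = 0) -> SimScenario:
    """One or more planar beats paced from the left edge."""
    stims = [Stimulus("planar_edge", t0_ms + i * interval_ms,
                      {"side": "left", "width_px": 3}) for i in range(beats)]
    return SimScenario(nx=nx, ny=ny, duration_ms=duration_ms, stimuli=stims,
                       seed=seed)


def focal_scenario(sources: list[tuple[int, int, float]], nx: int = 60, ny: int = 60,
                   duration_ms: float = 800.0, seed: int = 0) -> SimScenario:
    """Point stimuli at (x, y, t_ms) triples."""
    stims = [Stimulus("point", t, {"x": x, "y": y, "radius_px": 2.0})
             for x, y, t in sources]
    return SimScenario(nx=nx, ny=ny, duration_ms=duration_ms, stimuli=stims,
                       seed=seed)


def s1s2s3s4_scenario(nx: int = 60, ny: int = 60, s1_ms: float = 20.0,
                      intervals_ms: tuple[float, ...] = (380.0, 300.0, 260.0),
                      tail_ms: float = 500.0, seed: int = 0) -> SimScenario:
    """An S1 planar beat followed by progressively short-coupled extra stimuli."""
    stims = [Stimulus("planar_edge", s1_ms, {"side": "left", "width_px": 3})]
    t = s1_ms
    for iv in intervals_ms:
        t += iv
        stims.append(Stimulus("planar_edge", t, {"side": "left", "width_px": 3}))
    return SimScenario(nx=nx, ny=ny, duration_ms=t + tail_ms, stimuli=stims,
                       seed=seed)


def spiral_scenario(nx: int = 100, ny: int = 100, duration_ms: float = 4000.0,
                    s1_ms: float = 20.0, s2_ms: float = 450.0,
                    seed: int = 0) -> SimScenario:
    """Cross-field-induced spiral: planar S1 then a half-field S2 on the
    repolarization tail (vulnerable window)."""
    stims = [
        Stimulus("planar_edge", s1_ms, {"side": "left", "width_px": 3}),
        Stimulus("cross_field", s2_ms, {"side": "bottom", "fraction": 0.5}),
    ]
    return SimScenario(nx=nx, ny=ny, duration_ms=duration_ms, stimuli=stims,
                       seed=seed)
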