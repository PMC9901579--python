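"""Pixel-independent upstroke windowing via Hilbert-transform phase.

Phase is the angle of the analytic signal of the mean-subtracted trace,
mapped to [0, 2*pi).  The imaginary part of the analytic signal is the
Hilbert transform of the input, which lags it by 90 degrees, so the
angle already carries the -90 degree shift of the windowing convention:
for a pure sinusoid ``sin(w t)`` the phase is ``(w t - pi/2) mod 2*pi``
and phi > pi holds exactly on ``w t in (-pi/2, pi/2)`` — the rising
half-cycle centered on the upstroke.

Non-periodic signals break the single-pass Hilbert phase, so phase is
additionally computed over recursive binary subdivisions of the trace
down to a minimum segment duration; a sample is windowed if phi > pi in
the full trace or in any subdivision segment (union rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.signal.windows import tukey

#: Windows shorter than this many samples are discarded (derivative undefined).
MIN_WINDOW_SAMPLES = 3

#: Fraction of each segment end tapered (cosine) before the Hilbert transform.
TAPER_FRAC = 0.05

#: Frames excluded from windows at each end of the recording: zero-phase
#: filtering and the per-segment taper leave warm-up transients there whose
#: derivatives mimic weak upstrokes.
EDGE_GUARD_FRAMES = 10


class ConstantSignalError(ValueError):
    """Raised when phase is requested for a constant signal."""


@dataclass
class UpstrokeWindows:
    """Phase-derived upstroke windows for one pixel.

    ``intervals`` is a list of half-open frame intervals ``(t0, t1)``;
    ``mask`` is the equivalent boolean series.  Intervals are disjoint,
    sorted, and lie inside ``[0, n)``.
    """

    n: int
    intervals: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        for t0, t1 in self.intervals:
            m[t0:t1] = True
        return m

    def __len__(self) -> int:
        return len(self.intervals)

    @classmethod
    def from_mask(cls, mask: np.ndarray, min_samples: int = MIN_WINDOW_SAMPLES
                  ) -> "UpstrokeWindows":
        mask = np.asarray(mask, dtype=bool)
        edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))
                                       .astype(np.int8)))
        starts, stops = edges[::2], edges[1::2]
        ivals = [(int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_samples]
        return cls(n=mask.size, intervals=ivals)


def _phase_2d(seg: np.ndarray) -> np.ndarray:
    """Phase in [0, 2*pi) of each row of ``seg`` (npix, n)."""
    n = seg.shape[-1]
    x = seg - seg.mean(axis=-1, keepdims=True)
    if n >= 8 and TAPER_FRAC > 0:
        x = x * tukey(n, alpha=2 * TAPER_FRAC)[None, :]
    z = hilbert(x, axis=-1)
    return np.mod(np.angle(z), 2.0 * np.pi)


def instantaneous_phase(sig: np.ndarray) -> np.ndarray:
    """Hilbert phase of a 1-D series, in [0, 2*pi).

    The input is mean-subtracted internally (not mutated); the returned
    angle of the analytic signal carries the Hilbert transform's inherent
    -90 degree lag, placing action-potential upstrokes in phi > pi.

    Raises
    ------
    ConstantSignalError
        If the signal has zero range (phase undefined).
    """
    sig = np.asarray(sig, dtype=np.float64)
    if sig.ndim != 1:
        raise ValueError("instantaneous_phase expects a 1-D series")
    if sig.size < 4:
        raise ValueError("signal too short for phase computation (need >= 4 samples)")
    if np.ptp(sig) == 0:
        raise ConstantSignalError("constant signal has no phase")
    return _phase_2d(sig[None, :])[0]


def segment_spans(n: int, min_len: int) -> list[list[tuple[int, int]]]:
    """Recursive binary subdivision of ``[0, n)`` down to ``min_len`` samples.

    Returns one list of half-open spans per recursion level, starting with
    the full trace.  A level is only produced if every span in it has at
    least ``min_len`` samples, so no emitted span is shorter than the floor.
    """
    if n < 1:
        return []
    levels = [[(0, n)]]
    while True:
        nxt: list[tuple[int, int]] = []
        for a, b in levels[-1]:
            m = (a + b) // 2
            nxt.extend([(a, m), (m, b)])
        if min(b - a for a, b in nxt) < min_len:
            break
        levels.append(nxt)
    return levels


def _window_mask_2d(sig: np.ndarray, dt_ms: float, min_segment_ms: float) -> np.ndarray:
    """Union of phi > pi masks over all recursion levels; sig is (npix, nt)."""
    nt = sig.shape[-1]
    min_len = max(4, int(round(min_segment_ms / dt_ms)))
    mask = np.zeros(sig.shape, dtype=bool)
    for level in segment_spans(nt, min_len):
        for a, b in level:
            seg = sig[:, a:b]
            live = np.ptp(seg, axis=-1) > 0
            if not live.any():
                continue
            phi = _phase_2d(seg[live])
            mask[live, a:b] |= phi > np.pi
    return mask


def _apply_edge_guard(mask: np.ndarray, guard: int) -> np.ndarray:
    if guard > 0:
        mask[..., :guard] = False
        mask[..., mask.shape[-1] - guard:] = False
    return mask


def segmented_upstroke_windows(
    sig: np.ndarray, dt_ms: float = 1.0, min_segment_ms: float = 128.0,
    edge_guard_frames: int = EDGE_GUARD_FRAMES,
) -> UpstrokeWindows:
    """Upstroke windows of a single pixel via recursive segmented phase.

    The phi > pi criterion is evaluated over the full trace and over every
    recursive binary subdivision whose segments stay >= ``min_segment_ms``;
    a sample belongs to a window if any segment flags it.  Resulting runs
    shorter than 3 samples are discarded.

    If ``min_segment_ms`` exceeds the trace duration only the full-length
    segment is used.
    """
    sig = np.asarray(sig, dtype=np.float64)
    if sig.ndim != 1:
        raise ValueError("expected a 1-D series")
    if np.ptp(sig) == 0:
        return UpstrokeWindows(n=sig.size)
    mask = _window_mask_2d(sig[None, :], dt_ms, min_segment_ms)[0]
    return UpstrokeWindows.from_mask(_apply_edge_guard(mask, edge_guard_frames))


def stack_upstroke_windows(stack, min_segment_ms: float = 128.0,
                           edge_guard_frames: int = EDGE_GUARD_FRAMES) -> np.ndarray:
    """Boolean window mask (nt, ny, nx) for all masked-in pixels of a stack.

    Vectorized equivalent of :func:`segmented_upstroke_windows` per pixel;
    masked-out pixels are all-False.  Run-length pruning of short windows
    is applied per pixel when intervals are extracted, not here.
    """
    ys, xs = stack.masked_indices()
    out = np.zeros(stack.data.shape, dtype=bool)
    if ys.size == 0:
        return out
    sig = stack.data[:, ys, xs].T.astype(np.float64)  # (npix, nt)
    m = _apply_edge_guard(_window_mask_2d(sig, stack.dt_ms, min_segment_ms),
                          edge_guard_frames)
    out[:, ys, xs] = m.T
    return out


def _window_slope_and_maxderiv(sig: np.ndarray, deriv: np.ndarray,
                               t0: int, t1: int, dt_ms: float) -> tuple[float, float]:
    seg = sig[t0:t1]
    t = np.arange(seg.size, dtype=np.float64)
    slope = float(np.polyfit(t * dt_ms, seg, 1)[0])
    return slope, float(deriv[t0:t1].max())


def filter_windows(
    sig: np.ndarray,
    windows: UpstrokeWindows,
    deriv_threshold: float,
    dt_ms: float = 1.0,
) -> UpstrokeWindows:
    """Reject windows with non-positive linear trend or a weak derivative.

    A window is retained iff its in-window least-squares slope is > 0 and
    its in-window maximal first derivative (central difference) is
    >= ``deriv_threshold``.
    """
    if deriv_threshold < 0:
        raise ValueError("derivative threshold must be >= 0")
    sig = np.asarray(sig, dtype=np.float64)
    deriv = np.gradient(sig, dt_ms)
    kept = []
    for t0, t1 in windows.intervals:
        if t1 - t0 < MIN_WINDOW_SAMPLES:
            continue
        slope, maxd = _window_slope_and_maxderiv(sig, deriv, t0, t1, dt_ms)
        if slope > 0 and maxd >= deriv_threshold:
            kept.append((t0, t1))
    return UpstrokeWindows(n=windows.n, intervals=kept)
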