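"""Activation-time (pAT) detection inside phase-derived upstroke windows.

The activation time of an upstroke is the time of the maximal first
derivative of the normalized signal within its window.  Biphasic
upstrokes — two derivative maxima separated by a deep enough valley —
yield a primary (earlier) and a secondary (later) activation component.
Derivatives are central differences over one frame (``np.gradient``)
throughout, matching the estimator used by the automated threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phase import MIN_WINDOW_SAMPLES, UpstrokeWindows, _window_slope_and_maxderiv
from .stack import VoltageStack, new_map

PRIMARY = 0
SECONDARY = 1


class ThresholdError(ValueError):
    """Raised when the automated derivative threshold cannot be estimated."""


@dataclass
class DerivativeThreshold:
    """Global signal-derivative threshold in normalized amplitude per ms."""

    value: float
    method: str = "manual"  # "manual" | "auto"
    fdr_q: float = 0.01
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("derivative threshold must be > 0")
        if not 0.0 < self.fdr_q < 1.0:
            raise ValueError("fdr_q must lie in (0, 1)")


@dataclass
class ActivationEvent:
    x: int
    y: int
    t: int              # frame index
    component: int      # PRIMARY or SECONDARY
    vf_star: float      # normalized max-derivative amplitude in [0, 1]


@dataclass
class ActivationMatrix:
    """Sparse set of pAT events over a stack, sorted by (t, y, x, component)."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    component: np.ndarray
    vf_star: np.ndarray
    shape: tuple[int, int, int] | None = None  # (nt, ny, nx)
    dt_ms: float = 1.0

    @classmethod
    def from_events(cls, events: list[ActivationEvent],
                    shape: tuple[int, int, int] | None = None,
                    dt_ms: float = 1.0) -> "ActivationMatrix":
        if events:
            order = np.lexsort((
                [e.component for e in events],
                [e.x for e in events],
                [e.y for e in events],
                [e.t for e in events],
            ))
            events = [events[i] for i in order]
        return cls(
            x=np.array([e.x for e in events], dtype=np.int32),
            y=np.array([e.y for e in events], dtype=np.int32),
            t=np.array([e.t for e in events], dtype=np.int32),
            component=np.array([e.component for e in events], dtype=np.int8),
            vf_star=np.array([e.vf_star for e in events], dtype=np.float32),
            shape=shape,
            dt_ms=dt_ms,
        )

    def __len__(self) -> int:
        return self.x.size

    @property
    def t_ms(self) -> np.ndarray:
        return self.t * self.dt_ms

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "x": self.x, "y": self.y, "t_ms": self.t_ms,
            "component": np.where(self.component == PRIMARY, "primary", "secondary"),
            "vf_star": self.vf_star,
        })

    def select(self, idx: np.ndarray) -> "ActivationMatrix":
        return ActivationMatrix(self.x[idx], self.y[idx], self.t[idx],
                                self.component[idx], self.vf_star[idx],
                                self.shape, self.dt_ms)

    def dense(self) -> np.ndarray:
        """Dense boolean (nt, ny, nx) pAT matrix (1 at each event)."""
        if self.shape is None:
            raise ValueError("dense() requires a known stack shape")
        out = np.zeros(self.shape, dtype=bool)
        out[self.t, self.y, self.x] = True
        return out


def _window_max_derivatives(stack: VoltageStack, window_mask: np.ndarray) -> np.ndarray:
    """Max in-window derivative of every (pixel, window), as a flat array."""
    ys, xs = stack.masked_indices()
    vals: list[float] = []
    for y, x in zip(ys, xs):
        m = window_mask[:, y, x]
        if not m.any():
            continue
        w = UpstrokeWindows.from_mask(m)
        if not w.intervals:
            continue
        d = np.gradient(stack.data[:, y, x].astype(np.float64), stack.dt_ms)
        for t0, t1 in w.intervals:
            vals.append(float(d[t0:t1].max()))
    return np.asarray(vals, dtype=np.float64)


def auto_derivative_threshold(
    stack: VoltageStack,
    window_mask: np.ndarray,
    fdr_q: float = 0.01,
    min_windows: int = 50,
) -> DerivativeThreshold:
    """Estimate a global derivative threshold by FDR outlier detection.

    The per-window maximal derivatives are modelled as a noise bulk plus
    upper outliers (true depolarizations).  A robust null is fitted from
    the lower half of the empirical distribution (median, half-sample MAD
    scale), one-sided p-values are computed under that Gaussian null, and
    Benjamini-Hochberg at ``fdr_q`` declares outliers.  The threshold is
    the smallest outlier value.  When no window is declared an outlier the
    population is treated as homogeneous (e.g., a noiseless stack where
    every window is a true upstroke) and the threshold falls back just
    below the bulk, at ``median - 4 * scale``.
    """
    vals = _window_max_derivatives(stack, window_mask)
    if vals.size < min_windows:
        raise ThresholdError(
            f"only {vals.size} upstroke windows available (< {min_windows}); "
            "set a manual derivative threshold"
        )
    med = float(np.median(vals))
    lower = vals[vals <= med]
    scale = 1.4826 * float(np.median(med - lower))
    scale = max(scale, 0.05 * abs(med), 1e-12)
    from scipy.stats import norm

    p = norm.sf((vals - med) / scale)
    n = p.size
    order = np.argsort(p)
    ranked = p[order]
    crit = fdr_q * np.arange(1, n + 1) / n
    below = np.nonzero(ranked <= crit)[0]
    if below.size:
        k = below[-1] + 1
        rejected = vals[order[:k]]
        theta = float(rejected.min())
        method_note = "bh-outlier"
    else:
        theta = max(med - 4.0 * scale, 1e-12)
        method_note = "homogeneous-fallback"
    return DerivativeThreshold(
        value=theta, method="auto", fdr_q=fdr_q,
        meta={"n_windows": int(n), "null_median": med, "null_scale": scale,
              "rule": method_note},
    )


def _local_maxima(d: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima of ``d`` (leftmost sample of plateaus)."""
    if d.size < 3:
        return np.empty(0, dtype=int)
    left = d[1:-1] > d[:-2]
    right = d[1:-1] >= d[2:]
    return np.nonzero(left & right)[0] + 1


def detect_upstroke_activations(
    sig: np.ndarray,
    window: tuple[int, int],
    threshold: DerivativeThreshold,
    valley_frac: float = 0.75,
    dt_ms: float = 1.0,
    deriv: np.ndarray | None = None,
) -> list[tuple[int, int, float]]:
    """Resolve one or two activation times inside a retained window.

    If the two largest in-window derivative maxima both exceed the
    threshold and the derivative valley between them, measured relative to
    the smaller of the two maxima, is at least ``valley_frac``, the
    upstroke is biphasic: the chronologically earlier maximum is the
    primary activation and the later one the secondary.  Otherwise a
    single activation is placed at the global in-window derivative
    maximum (earliest sample on ties).

    Returns a list of ``(t_frame, component, vf_star)`` tuples where
    ``vf_star`` is the derivative maximum normalized by the in-window
    signal amplitude (clipped to [0, 1]).
    """
    t0, t1 = window
    if t1 - t0 < MIN_WINDOW_SAMPLES:
        raise ValueError("window shorter than 3 samples")
    sig = np.asarray(sig, dtype=np.float64)
    if deriv is None:
        deriv = np.gradient(sig, dt_ms)
    d = deriv[t0:t1]
    amp = float(np.ptp(sig[t0:t1]))

    def vf(v: float) -> float:
        if amp <= 0:
            return 0.0
        return float(np.clip(v * dt_ms / amp, 0.0, 1.0))

    peaks = _local_maxima(d)
    peaks = peaks[d[peaks] >= threshold.value]
    if peaks.size >= 2:
        # two largest by value; earliest first on exact ties
        order = np.lexsort((peaks, -d[peaks]))
        i1, i2 = sorted(peaks[order[:2]])
        smaller = min(d[i1], d[i2])
        valley = float(d[i1:i2 + 1].min())
        if smaller > 0 and (smaller - valley) / smaller >= valley_frac:
            return [
                (t0 + int(i1), PRIMARY, vf(float(d[i1]))),
                (t0 + int(i2), SECONDARY, vf(float(d[i2]))),
            ]
    i = int(np.argmax(d))
    return [(t0 + i, PRIMARY, vf(float(d[i])))]


def build_activation_matrix(
    stack: VoltageStack,
    window_mask: np.ndarray,
    threshold: DerivativeThreshold,
    valley_frac: float = 0.75,
) -> ActivationMatrix:
    """Detect pAT events over all masked-in pixels and windows.

    Each per-pixel window is first subjected to the retention filter
    (positive in-window trend and maximal derivative >= threshold); the
    survivors are resolved to one or two activation events.  Events are
    returned sorted by (t, y, x).
    """
    ys, xs = stack.masked_indices()
    events: list[ActivationEvent] = []
    for y, x in zip(ys, xs):
        m = window_mask[:, y, x]
        if not m.any():
            continue
        w = UpstrokeWindows.from_mask(m)
        if not w.intervals:
            continue
        sig = stack.data[:, y, x].astype(np.float64)
        d = np.gradient(sig, stack.dt_ms)
        for t0, t1 in w.intervals:
            slope, maxd = _window_slope_and_maxderiv(sig, d, t0, t1, stack.dt_ms)
            if slope <= 0 or maxd < threshold.value:
                continue
            for t, comp, v in detect_upstroke_activations(
                sig, (t0, t1), threshold, valley_frac, stack.dt_ms, deriv=d
            ):
                events.append(ActivationEvent(int(x), int(y), t, comp, v))
    return ActivationMatrix.from_events(events, shape=stack.data.shape,
                                        dt_ms=stack.dt_ms)


def uniform_window_at(
    stack: VoltageStack,
    t0: int,
    t1: int,
    threshold: DerivativeThreshold | None = None,
) -> np.ndarray:
    """Baseline uAT map: per-pixel max-derivative time in a fixed window.

    All pixels share the window ``[t0, t1)``.  Pixels whose maximal
    derivative falls below the threshold (if given) carry the sentinel.
    Returned in ms.
    """
    if not 0 <= t0 < t1 <= stack.nt:
        raise ValueError(f"empty or out-of-range window [{t0}, {t1})")
    if t1 - t0 < MIN_WINDOW_SAMPLES:
        raise ValueError("uniform window shorter than 3 samples")
    out = new_map((stack.ny, stack.nx))
    ys, xs = stack.masked_indices()
    sig = stack.data[t0:t1, ys, xs].astype(np.float64)
    d = np.gradient(sig, stack.dt_ms, axis=0)
    idx = np.argmax(d, axis=0)
    maxd = d[idx, np.arange(d.shape[1])]
    at = (t0 + idx) * stack.dt_ms
    if threshold is not None:
        at = np.where(maxd >= threshold.value, at, np.nan)
    out[ys, xs] = at
    return out
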