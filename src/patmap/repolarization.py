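"""Per-wave-front repolarization-time (RT) and APD mapping.

RT is found inside refined APD limits after each activation: by default
as the first downward crossing of a fractional amplitude recovery level
(e.g. 80% repolarization), or — for drifting baselines — as the time of
the minimum signal derivative in the same interval.  APD = RT - AT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stack import VoltageStack, new_map
from .wavefronts import WaveFrontLabeling, wavefront_at_maps

#: Default fallback factor: ERPmin = 0.8 x minimum basal APD.
ERP_FALLBACK_FACTOR = 0.8


def erp_min_from_apd(min_basal_apd_ms: float,
                     factor: float = ERP_FALLBACK_FACTOR) -> float:
    """Fallback ERPmin when no short-coupled reference recording exists."""
    if min_basal_apd_ms <= 0:
        raise ValueError("minimum basal APD must be > 0")
    return factor * min_basal_apd_ms


@dataclass
class RepolarizationConfig:
    level_frac: float = 0.8           # APD80 by default
    apd_min_ms: float = 80.0          # user limits (APD'min / APD'max)
    apd_max_ms: float = 400.0
    method: str = "amplitude_crossing"  # or "min_derivative"
    baseline_ms: float = 10.0         # pre-upstroke window for the baseline

    def __post_init__(self) -> None:
        if not 0.0 < self.level_frac < 1.0:
            raise ValueError("level_frac must lie in (0, 1)")
        if not 0.0 < self.apd_min_ms < self.apd_max_ms:
            raise ValueError("require 0 < apd_min_ms < apd_max_ms")
        if self.method not in ("amplitude_crossing", "min_derivative"):
            raise ValueError(f"unknown RT method {self.method!r}")


def detect_repolarization(
    sig: np.ndarray,
    pat_frame: int,
    config: RepolarizationConfig,
    limits_ms: tuple[float, float] | None = None,
    dt_ms: float = 1.0,
) -> float:
    """RT (ms) for one activation, or NaN when no repolarization is found.

    The search interval is ``[pat + apd_min, pat + apd_max]`` using the
    refined per-front limits when given.  The amplitude method references
    the signal peak within the interval to a pre-upstroke baseline (median
    of ``baseline_ms`` before the activation) and takes the first downward
    crossing of ``peak - level_frac * amplitude`` after the peak.  The
    derivative method takes the time of the minimum signal derivative.
    """
    sig = np.asarray(sig, dtype=np.float64)
    lo_ms, hi_ms = limits_ms if limits_ms is not None else (
        config.apd_min_ms, config.apd_max_ms)
    i0 = pat_frame + int(np.ceil(lo_ms / dt_ms))
    i1 = pat_frame + int(np.floor(hi_ms / dt_ms)) + 1
    if i0 >= sig.size:
        return np.nan
    i1 = min(i1, sig.size)
    if i1 - i0 < 2:
        return np.nan

    if config.method == "min_derivative":
        d = np.gradient(sig, dt_ms)
        i = int(np.argmin(d[i0:i1]))
        return (i0 + i) * dt_ms

    # amplitude reference: peak over [pat, pat + apd_max]
    pk_hi = min(pat_frame + int(np.floor(hi_ms / dt_ms)) + 1, sig.size)
    seg = sig[pat_frame:pk_hi]
    ipeak = pat_frame + int(np.argmax(seg))
    peak = sig[ipeak]
    b0 = max(pat_frame - int(round(config.baseline_ms / dt_ms)), 0)
    baseline = float(np.median(sig[b0:pat_frame])) if pat_frame > b0 else float(sig[pat_frame])
    amp = peak - baseline
    if amp <= 0:
        return np.nan
    level = peak - config.level_frac * amp
    start = max(i0, ipeak)  # never report a crossing on the rising limb
    seg = sig[start:i1]
    prev = sig[start - 1:i1 - 1] if start >= 1 else np.concatenate(([sig[0]], seg[:-1]))
    crossing = np.nonzero((seg <= level) & (prev > level))[0]
    if crossing.size == 0:
        return np.nan
    return (start + crossing[0]) * dt_ms


def refine_apd_limits(
    stack: VoltageStack,
    at_map_ms: np.ndarray,
    config: RepolarizationConfig,
    pad_ms: float = 10.0,
) -> tuple[float, float]:
    """Per-front APD''min/APD''max from APDs resolved under the user limits.

    A first RT pass under the user limits yields a sample of APDs for the
    front; the refined interval is [p5 - pad, p95 + pad] of that sample,
    clipped to the user limits.  If nothing resolves, the user limits are
    returned unchanged with a warning.
    """
    apds = []
    ys, xs = np.nonzero(np.isfinite(at_map_ms) & stack.mask)
    for y, x in zip(ys, xs):
        at = at_map_ms[y, x]
        rt = detect_repolarization(stack.data[:, y, x], int(round(at / stack.dt_ms)),
                                   config, None, stack.dt_ms)
        if np.isfinite(rt):
            apds.append(rt - at)
    if not apds:
        warnings.warn("no repolarization resolved under user APD limits; "
                      "falling back to user limits", stacklevel=2)
        return (config.apd_min_ms, config.apd_max_ms)
    p5, p95 = np.percentile(apds, [5, 95])
    lo = max(p5 - pad_ms, config.apd_min_ms)
    hi = min(p95 + pad_ms, config.apd_max_ms)
    if lo >= hi:  # degenerate (single tight APD sample); keep a sane interval
        lo, hi = config.apd_min_ms, config.apd_max_ms
    return (float(lo), float(hi))


def apd_map(at_map_ms: np.ndarray, rt_map_ms: np.ndarray) -> np.ndarray:
    """APD = RT - AT where both are defined; sentinel elsewhere."""
    if at_map_ms.shape != rt_map_ms.shape:
        raise ValueError("AT and RT maps must share a shape")
    out = rt_map_ms - at_map_ms
    out[~(out > 0)] = np.nan
    return out


def map_front_repolarization(
    stack: VoltageStack,
    labeling: WaveFrontLabeling,
    label_id: int,
    config: RepolarizationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """RT and APD maps (ms) of one wave front, with refined APD limits.

    Runs the refinement pass then the definitive RT pass on the front's
    primary AT map.  Returns (rt_map, apd_map, refined_limits).
    """
    config = config or RepolarizationConfig()
    at_ms, _ = wavefront_at_maps(labeling.matrix, labeling, label_id)
    limits = refine_apd_limits(stack, at_ms, config)
    rt = new_map(at_ms.shape)
    ys, xs = np.nonzero(np.isfinite(at_ms) & stack.mask)
    for y, x in zip(ys, xs):
        rt[y, x] = detect_repolarization(
            stack.data[:, y, x], int(round(at_ms[y, x] / stack.dt_ms)),
            config, limits, stack.dt_ms)
    return rt, apd_map(at_ms, rt), limits
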