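"""Core containers: normalized voltage stacks and per-pixel QC maps.

Conventions used throughout the package:

* Stacks are stored frame-first, ``data[t, y, x]``, x-fastest in memory.
* Frame index ``i`` corresponds to time ``i * dt_ms`` (0-based); time
  intervals are half-open ``[t0, t1)``.
* Scalar maps over ``(y, x)`` use ``NaN`` as the "unassigned" sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Sentinel value for unassigned pixels in scalar maps.
SENTINEL = np.nan


@dataclass
class VoltageStack:
    """Normalized fluorescence movie with acquisition geometry.

    Attributes
    ----------
    data : ndarray, shape (nt, ny, nx)
        Per-pixel signals, dimensionless; after pre-conditioning every
        masked-in time series lies in [0, 1] and masked-out pixels are
        exactly 0 at all frames.
    dt_ms : float
        Frame interval in milliseconds.
    pitch_mm : float
        Pixel edge length in millimetres.
    mask : ndarray of bool, shape (ny, nx)
        Region-of-interest mask; True = tissue.
    meta : dict
        Free-form provenance record.
    """

    data: np.ndarray
    dt_ms: float = 1.0
    pitch_mm: float = 0.7
    mask: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be (nt, ny, nx), got shape {self.data.shape}")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be > 0")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[1:]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match spatial shape "
                    f"{self.data.shape[1:]}"
                )

    @property
    def nt(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nx(self) -> int:
        return self.data.shape[2]

    @property
    def duration_ms(self) -> float:
        return self.nt * self.dt_ms

    @property
    def fs_hz(self) -> float:
        """Sampling rate in Hz."""
        return 1000.0 / self.dt_ms

    def pixel(self, x: int, y: int) -> np.ndarray:
        """Time series of pixel ``(x, y)`` (view, not a copy)."""
        return self.data[:, y, x]

    def masked_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(ys, xs) index arrays of masked-in pixels in scan order (y, x)."""
        ys, xs = np.nonzero(self.mask)
        return ys, xs

    def copy(self) -> "VoltageStack":
        return VoltageStack(
            data=self.data.copy(),
            dt_ms=self.dt_ms,
            pitch_mm=self.pitch_mm,
            mask=self.mask.copy(),
            meta=dict(self.meta),
        )


@dataclass
class SignalQC:
    """Per-pixel signal quality maps; NaN on masked-out / undefined pixels.

    ``snr`` is peak-to-peak amplitude of the low-passed signal over the
    standard deviation of the residual above the noise band lower edge.
    ``regularity_index`` is the fraction of (DC-free) spectral power within
    +/- ``peak_band_hz`` of the dominant spectral peak.  Neither metric has
    a canonical definition in the optical-mapping literature; the ones used
    here are recorded in ``meta``.
    """

    snr: np.ndarray
    dominant_freq_hz: np.ndarray
    regularity_index: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)


def new_map(shape: tuple[int, int]) -> np.ndarray:
    """Allocate a scalar map filled with the unassigned sentinel."""
    return np.full(shape, SENTINEL, dtype=float)


def defined(map_: np.ndarray) -> np.ndarray:
    """Boolean mask of assigned pixels of a scalar map."""
    return np.isfinite(map_)
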