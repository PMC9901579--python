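"""Pre-conditioning and quality control of raw optical-mapping stacks.

The standard pre-conditioning chain is: zero-phase low-pass temporal
filtering (forwards-backwards Butterworth), mask-aware spatial box
averaging, a short uniform running-average temporal filter, signal
inversion (fluorescence decreases on depolarization) and per-pixel
min-max normalization to [0, 1].
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .stack import SignalQC, VoltageStack

#: Butterworth order used for the zero-phase low-pass stage.
BUTTER_ORDER = 3


def _lowpass_sos(cutoff_hz: float, fs_hz: float):
    nyq = fs_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    return signal.butter(BUTTER_ORDER, cutoff_hz / nyq, btype="low", output="sos")


def _filtfilt_time(data: np.ndarray, sos: np.ndarray, chunk: int = 2048) -> np.ndarray:
    """Zero-phase filter along axis 0, chunked over pixels to bound memory."""
    nt = data.shape[0]
    flat = data.reshape(nt, -1)
    out = np.empty_like(flat, dtype=np.float32)
    for lo in range(0, flat.shape[1], chunk):
        hi = min(lo + chunk, flat.shape[1])
        out[:, lo:hi] = signal.sosfiltfilt(sos, flat[:, lo:hi].astype(np.float64),
                                           axis=0).astype(np.float32)
    return out.reshape(data.shape)


def _spatial_average(data: np.ndarray, mask: np.ndarray, kernel: int) -> np.ndarray:
    """Mask-aware k x k uniform average per frame.

    The kernel shrinks at borders and at mask boundaries: each output pixel
    averages only the in-mask pixels available under the kernel footprint,
    so background zeros never bleed into tissue.
    """
    if kernel == 1:
        return data
    m = mask.astype(np.float32)
    num = ndimage.uniform_filter(data * m[None, :, :], size=(1, kernel, kernel),
                                 mode="constant", cval=0.0)
    den = ndimage.uniform_filter(m, size=kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den[None, :, :]
    out[:, den == 0] = 0.0
    return out.astype(np.float32)


def precondition_stack(
    raw: np.ndarray,
    cutoff_hz: float = 60.0,
    spatial_kernel: int = 3,
    temporal_kernel: int = 3,
    dt_ms: float = 1.0,
    pitch_mm: float = 0.7,
    mask: np.ndarray | None = None,
    invert: bool = True,
) -> VoltageStack:
    """Filter, invert and normalize a raw intensity stack.

    Parameters
    ----------
    raw : ndarray, shape (nt, ny, nx)
        Raw fluorescence intensities.
    cutoff_hz : float
        Low-pass cutoff of the forwards-backwards Butterworth filter.
        Must be below Nyquist.
    spatial_kernel, temporal_kernel : int
        Odd box-filter sizes in pixels / frames.
    invert : bool
        Negate the signal before normalization so that depolarization
        (a fluorescence decrease) becomes a positive upstroke.  Set to
        False for stacks that are already upstroke-positive.

    Returns
    -------
    VoltageStack
        Per-pixel min-max normalized stack in [0, 1]; zero-range pixels
        map to 0; masked-out pixels are exactly 0.
    """
    raw = np.asarray(raw, dtype=np.float32)
    if raw.ndim != 3:
        raise ValueError("raw stack must be 3-D (nt, ny, nx)")
    if spatial_kernel < 1 or spatial_kernel % 2 == 0:
        raise ValueError("spatial_kernel must be a positive odd integer")
    if temporal_kernel < 1 or temporal_kernel % 2 == 0:
        raise ValueError("temporal_kernel must be a positive odd integer")
    nt, ny, nx = raw.shape
    if ny < 2 * spatial_kernel or nx < 2 * spatial_kernel:
        raise ValueError("stack spatial dimensions too small for the spatial kernel")
    fs = 1000.0 / dt_ms
    sos = _lowpass_sos(cutoff_hz, fs)
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples on each side
    warmup = 3 * (2 * sos.shape[0] + 1)
    if nt <= warmup:
        raise ValueError(
            f"stack of {nt} frames is shorter than the filter warm-up ({warmup} frames)"
        )
    if nt < temporal_kernel:
        raise ValueError("stack shorter than the temporal kernel")
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (ny, nx):
            raise ValueError("mask shape does not match stack spatial shape")
        if not mask.any():
            raise ValueError("ROI mask is empty (all pixels masked out)")

    out = _filtfilt_time(raw, sos)
    out = _spatial_average(out, mask, spatial_kernel)
    if temporal_kernel > 1:
        out = ndimage.uniform_filter1d(out, size=temporal_kernel, axis=0, mode="nearest")
    if invert:
        np.negative(out, out=out)
    # per-pixel min-max over the full recording; 0/0 -> 0 for flat pixels
    lo = out.min(axis=0)
    rng = out.max(axis=0) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (out - lo[None, :, :]) / rng[None, :, :]
    out[:, rng == 0] = 0.0
    out[:, ~mask] = 0.0
    stack = VoltageStack(
        data=out.astype(np.float32),
        dt_ms=dt_ms,
        pitch_mm=pitch_mm,
        mask=mask,
        meta={
            "preconditioning": {
                "cutoff_hz": cutoff_hz,
                "butter_order": BUTTER_ORDER,
                "spatial_kernel": spatial_kernel,
                "temporal_kernel": temporal_kernel,
                "inverted": bool(invert),
            }
        },
    )
    return stack


def apply_roi_mask(stack: VoltageStack, mask: np.ndarray) -> VoltageStack:
    """Zero out all pixels outside ``mask``; masked-in series are unchanged."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (stack.ny, stack.nx):
        raise ValueError("mask shape does not match stack spatial shape")
    if not mask.any():
        raise ValueError("ROI mask is empty (all pixels masked out)")
    out = stack.copy()
    out.data[:, ~mask] = 0.0
    out.mask = stack.mask & mask
    return out


def signal_qc(
    stack: VoltageStack,
    noise_band_hz: float = 60.0,
    peak_band_hz: float = 0.75,
    min_freq_hz: float = 0.5,
) -> SignalQC:
    """Per-pixel SNR, dominant frequency and regularity index.

    SNR is the robust peak-to-peak (1st-99th percentile) of the
    ``noise_band_hz``-low-passed signal over the noise SD estimated from
    the residual above that cutoff; the residual SD is corrected for the
    equivalent noise bandwidth removed by the low-pass so that it
    estimates the full white-noise SD.  The regularity index is the
    fraction of DC-free spectral power within +/- ``peak_band_hz`` of the
    dominant peak, the dominant peak being sought at >= ``min_freq_hz``.
    All-zero (or constant) pixels are flagged NaN rather than 0.
    """
    if stack.duration_ms < 1000.0:
        raise ValueError("signal_qc requires at least 1 s of recording")
    nt = stack.nt
    fs = stack.fs_hz
    ys, xs = stack.masked_indices()
    sig = stack.data[:, ys, xs].astype(np.float64)  # (nt, npix)

    snr = np.full((stack.ny, stack.nx), np.nan)
    dom = np.full((stack.ny, stack.nx), np.nan)
    reg = np.full((stack.ny, stack.nx), np.nan)

    live = np.ptp(sig, axis=0) > 0
    if live.any():
        s = sig[:, live]
        sos = _lowpass_sos(noise_band_hz, fs)
        low = signal.sosfiltfilt(sos, s, axis=0)
        resid = s - low
        p2p = np.percentile(low, 99, axis=0) - np.percentile(low, 1, axis=0)
        # white noise above the cutoff carries (1 - ENBW/nyquist) of the power
        enbw = noise_band_hz * (np.pi / (2 * BUTTER_ORDER)) / np.sin(
            np.pi / (2 * BUTTER_ORDER))
        corr = np.sqrt(max(1.0 - enbw / (fs / 2.0), 1e-6))
        noise_sd = resid.std(axis=0) / corr
        with np.errstate(invalid="ignore", divide="ignore"):
            snr_v = p2p / noise_sd
        snr_v[noise_sd == 0] = np.inf

        freqs = np.fft.rfftfreq(nt, d=stack.dt_ms / 1000.0)
        power = np.abs(np.fft.rfft(s - s.mean(axis=0), axis=0)) ** 2
        searchable = freqs >= min_freq_hz
        pk = np.argmax(np.where(searchable[:, None], power, 0.0), axis=0)
        dom_v = freqs[pk]
        in_band = np.abs(freqs[:, None] - dom_v[None, :]) <= peak_band_hz
        total = power[1:].sum(axis=0)  # exclude DC
        band = np.where(in_band[1:], power[1:], 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            reg_v = band / total
        reg_v[total == 0] = np.nan

        snr[ys[live], xs[live]] = snr_v
        dom[ys[live], xs[live]] = dom_v
        reg[ys[live], xs[live]] = np.clip(reg_v, 0.0, 1.0)

    return SignalQC(
        snr=snr,
        dominant_freq_hz=dom,
        regularity_index=reg,
        meta={
            "snr_definition": "p2p_1_99(lowpass)/enbw-corrected sd(residual)",
            "noise_band_hz": noise_band_hz,
            "regularity_definition": f"power fraction within +/-{peak_band_hz} Hz of peak",
        },
    )
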