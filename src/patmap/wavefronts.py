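"""Space-time grouping of pAT events into wave fronts.

Two events are connected when their pixels are 8-neighbors and their
activation times differ by at most the conduction-block threshold
theta_t_CB (closed interval).  A wave front is a connected component of
this relation, so converging fronts form a single object.  Labels are
contiguous integers starting at 1, assigned in scan order (fastest
through x, then y, then t) of each component's first event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .activation import ActivationMatrix
from .stack import new_map

_OFFSETS_8 = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]


@dataclass
class WaveFrontConfig:
    """Parameters of wave-front grouping.

    ``theta_t_cb_ms`` is the largest neighbor-to-neighbor activation delay
    still treated as propagation.  ``erp_min_ms`` is the shortest interval
    accepted as genuine re-excitation (used downstream by repetitiveness
    and origin analysis); it normally exceeds theta_t_CB.
    """

    theta_t_cb_ms: float
    erp_min_ms: float | None = None
    theta_method: str = "manual"  # "manual" | "auto"
    erp_method: str = "manual"
    include_secondary: bool = True

    def __post_init__(self) -> None:
        if self.theta_t_cb_ms <= 0:
            raise ValueError("theta_t_cb_ms must be > 0")
        if self.erp_min_ms is not None and self.erp_min_ms <= self.theta_t_cb_ms:
            warnings.warn(
                "erp_min_ms <= theta_t_cb_ms: re-excitation may be conflated "
                "with slow conduction", stacklevel=2)


@dataclass
class WaveFrontLabeling:
    """One positive integer label per ActivationMatrix event."""

    labels: np.ndarray                    # int32, parallel to matrix events
    matrix: ActivationMatrix
    info: dict[int, dict] = field(default_factory=dict)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0

    def events_of(self, label_id: int) -> np.ndarray:
        """Boolean selector of the events carrying ``label_id``."""
        if label_id < 1 or label_id > self.n_labels:
            raise KeyError(f"unknown wave-front label {label_id}")
        return self.labels == label_id


def _pair_delays_ms(matrix: ActivationMatrix, nx: int, ny: int
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Conduction delays per (unordered neighbor pair, beat), in ms.

    For every event and each of the 4 forward neighbor offsets, the event
    is matched to the temporally nearest event of the neighboring pixel;
    the matched |dt| is one delay sample.  Matching from the lower pixel
    of each unordered pair only, one delay per beat per pair, keeps a
    persistent slow pathway crossed by every stimulus at exactly one count
    per stimulus.  Returns (pair_id, delay_ms) arrays.
    """
    if len(matrix) == 0:
        return np.empty(0, np.int64), np.empty(0)
    pix = matrix.y.astype(np.int64) * nx + matrix.x.astype(np.int64)
    order = np.lexsort((matrix.t, pix))
    spix, st = pix[order], matrix.t[order].astype(np.float64)
    tspan = float(matrix.t.max()) + 2.0
    key = spix * tspan + st
    pair_ids: list[np.ndarray] = []
    delays: list[np.ndarray] = []
    for k_off, (dx, dy) in enumerate([(1, 0), (0, 1), (1, 1), (1, -1)]):
        nxp = matrix.x + dx
        nyp = matrix.y + dy
        ok = (nxp >= 0) & (nxp < nx) & (nyp >= 0) & (nyp < ny)
        if not ok.any():
            continue
        src_pix = pix[ok]
        npix = nyp[ok].astype(np.int64) * nx + nxp[ok]
        tt = matrix.t[ok].astype(np.float64)
        lo = np.searchsorted(key, npix * tspan)
        hi = np.searchsorted(key, (npix + 1) * tspan)
        pos = np.searchsorted(key, npix * tspan + tt)  # lo <= pos <= hi
        nxt = np.clip(pos, 0, key.size - 1)
        prv = np.clip(pos - 1, 0, key.size - 1)
        d_next = np.where(pos < hi, np.abs(st[nxt] - tt), np.inf)
        d_prev = np.where(pos - 1 >= lo, np.abs(st[prv] - tt), np.inf)
        best = np.minimum(d_next, d_prev)
        fin = np.isfinite(best)
        if fin.any():
            # unordered pair identified by (source pixel, offset index)
            pair_ids.append(src_pix[fin] * 4 + k_off)
            delays.append(best[fin] * matrix.dt_ms)
    if not delays:
        return np.empty(0, np.int64), np.empty(0)
    return np.concatenate(pair_ids), np.concatenate(delays)


def estimate_conduction_block_threshold(
    reference: ActivationMatrix,
    n_short_stimuli: int,
    nx: int,
    ny: int,
) -> float:
    """theta_t_CB from a short-coupled (S1S2S3S4-style) reference recording.

    All 8-neighborhood conduction delays are binned at 1 ms per unordered
    pixel pair; the estimate is the largest delay shown by some single
    pair on at least ``n_short_stimuli`` distinct beats (the largest
    activation gradient common to all short-coupled stimuli).  Requiring
    recurrence within one pair rejects chance coincidences from spurious
    events.  Zero delays (simultaneous neighbors) are not conduction and
    are excluded.
    """
    if n_short_stimuli < 1:
        raise ValueError("n_short_stimuli must be >= 1")
    pair_ids, delays = _pair_delays_ms(reference, nx, ny)
    delays = np.rint(delays).astype(np.int64)
    keep = delays >= 1
    pair_ids, delays = pair_ids[keep], delays[keep]
    if delays.size == 0:
        raise ValueError("no neighbor conduction delays found; set theta manually")
    combo = pair_ids * (delays.max() + 1) + delays
    _, inverse, counts = np.unique(combo, return_inverse=True, return_counts=True)
    qualifying = delays[counts[inverse] >= n_short_stimuli]
    if qualifying.size == 0:
        raise ValueError(
            f"no pair repeats a delay on >= {n_short_stimuli} beats; "
            "set theta manually")
    return float(qualifying.max())


def label_wavefronts(matrix: ActivationMatrix, config: WaveFrontConfig
                     ) -> WaveFrontLabeling:
    """Group events into wave fronts by space-time connected components.

    Deterministic: events are visited in scan order (x fastest, then y,
    then t) and component ids are renumbered 1..L by first-event order.
    Secondary-component events participate like primary ones unless
    ``config.include_secondary`` is False (they then stay unlabeled, 0).
    """
    if matrix.shape is None:
        raise ValueError("ActivationMatrix must carry its stack shape")
    _, ny, nx = matrix.shape
    n = len(matrix)
    labels = np.zeros(n, dtype=np.int32)
    if n == 0:
        return WaveFrontLabeling(labels=labels, matrix=matrix)

    active = np.ones(n, dtype=bool)
    if not config.include_secondary:
        active = matrix.component == 0
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return WaveFrontLabeling(labels=labels, matrix=matrix)

    ax, ay, at = matrix.x[idx], matrix.y[idx], matrix.t[idx].astype(np.int64)
    theta_f = config.theta_t_cb_ms / matrix.dt_ms
    pix = ay.astype(np.int64) * nx + ax.astype(np.int64)
    order = np.lexsort((at, pix))
    spix, st = pix[order], at[order]
    tspan = int(matrix.t.max()) + 2

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    key = spix * tspan + st
    for dx, dy in _OFFSETS_8:
        nxp = ax + dx
        nyp = ay + dy
        ok = (nxp >= 0) & (nxp < nx) & (nyp >= 0) & (nyp < ny)
        if not ok.any():
            continue
        src = np.nonzero(ok)[0]
        npix = nyp[src].astype(np.int64) * nx + nxp[src]
        tt = at[src]
        t_lo = np.maximum(np.ceil(tt - theta_f).astype(np.int64), 0)
        t_hi = np.minimum(np.floor(tt + theta_f).astype(np.int64), tspan - 2)
        lo = np.searchsorted(key, npix * tspan + t_lo)
        hi = np.searchsorted(key, npix * tspan + t_hi, side="right")
        cnt = hi - lo
        has = cnt > 0
        if not has.any():
            continue
        src, lo, cnt = src[has], lo[has], cnt[has]
        reps = np.repeat(src, cnt)
        tgt_sorted = np.repeat(lo, cnt) + _ragged_arange(cnt)
        rows.append(reps)
        cols.append(order[tgt_sorted])

    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = coo_matrix((np.ones(r.size, dtype=np.int8), (r, c)),
                           shape=(idx.size, idx.size))
        _, comp = connected_components(graph, directed=False)
    else:
        comp = np.arange(idx.size)

    # renumber components by first appearance in scan order (t, y, x)
    scan = np.lexsort((ax, ay, at))
    remap = np.full(comp.max() + 1, -1, dtype=np.int32)
    nxt = 1
    for c_id in comp[scan]:
        if remap[c_id] < 0:
            remap[c_id] = nxt
            nxt += 1
    labels[idx] = remap[comp]

    info: dict[int, dict] = {}
    t_ms = matrix.t_ms
    for lab in range(1, nxt):
        sel = labels == lab
        pixels = set(zip(matrix.x[sel].tolist(), matrix.y[sel].tolist()))
        info[lab] = {
            "first_ms": float(t_ms[sel].min()),
            "last_ms": float(t_ms[sel].max()),
            "n_events": int(sel.sum()),
            "n_pixels": len(pixels),
            "duration_ms": float(t_ms[sel].max() - t_ms[sel].min()),
        }
    return WaveFrontLabeling(labels=labels, matrix=matrix, info=info)


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] for a vector of counts."""
    total = int(counts.sum())
    out = np.arange(total)
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    return out - starts


def wavefront_at_maps(
    matrix: ActivationMatrix,
    labeling: WaveFrontLabeling,
    label_id: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Primary and secondary AT maps (ms) of one wave front.

    The primary map holds the earliest labeled pAT per pixel; the
    secondary map holds the earliest labeled secondary-component pAT
    where one exists.  Unvisited pixels carry the sentinel.
    """
    sel = labeling.events_of(label_id)
    _, ny, nx = matrix.shape
    primary = new_map((ny, nx))
    secondary = new_map((ny, nx))
    order = np.nonzero(sel)[0][np.argsort(matrix.t[sel], kind="stable")[::-1]]
    # iterate latest-first so earliest events win the final write
    for i in order:
        primary[matrix.y[i], matrix.x[i]] = matrix.t_ms[i]
        if matrix.component[i] == 1:
            secondary[matrix.y[i], matrix.x[i]] = matrix.t_ms[i]
    return primary, secondary
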