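"""Wave-front characterisation: repetitiveness, origins, dynamic maps and
conduction-source classification of the leading wave front.

Class vocabulary for leading-edge points:

* ``breakthrough`` — the conduction field contains a breakthrough origin
  (a focal source appearing inside the mapped surface).
* ``passive`` — the field contains an origin at the mask periphery
  (activation entering the field of view).
* ``myocardial_reentry`` — neighboring field points differ in pAT by more
  than ERPmin (re-excitation through the same tissue).
* ``tortuous`` — a field point has time-eligible neighbors but none with
  an intersecting conduction vector (discontinuous propagation path).
* ``boundary`` — a field point with no intersecting same-field neighbor
  that touches pAT points of a different wave-front label.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationMatrix
from .stack import new_map
from .wavefronts import WaveFrontLabeling

_OFFS = [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)]

CLASS_NAMES = ("breakthrough", "passive", "myocardial_reentry", "tortuous", "boundary")


# ---------------------------------------------------------------------------
# repetitiveness
# ---------------------------------------------------------------------------

@dataclass
class RepetitivenessResult:
    classification: str            # "repetitive" | "non_repetitive"
    count_map: np.ndarray          # repetitions per pixel (0 on non-repeating support)
    histogram: dict[int, int]      # repetition count -> n pixels

    @property
    def repetitive(self) -> bool:
        return self.classification == "repetitive"


def classify_repetitiveness(
    labeling: WaveFrontLabeling,
    label_id: int,
    erp_min_ms: float,
    mask: np.ndarray | None = None,
    rule: str = "mode",
) -> RepetitivenessResult:
    """Count per-pixel pAT repetitions of a wave front and classify it.

    Same-label activations at a pixel count as repetitions only when
    separated by at least ``erp_min_ms`` (greedy forward pass, first
    event always counted).  The front is repetitive when the histogram
    peak (mode) of per-pixel repetition counts is >= 1; ``rule='majority'``
    instead requires more than half of the support pixels to repeat.
    """
    if rule not in ("mode", "majority"):
        raise ValueError("rule must be 'mode' or 'majority'")
    m = labeling.matrix
    sel = labeling.events_of(label_id)
    _, ny, nx = m.shape
    count_map = new_map((ny, nx))
    if mask is not None:
        count_map[mask] = 0.0
    t_ms = m.t_ms[sel]
    pix = m.y[sel].astype(np.int64) * nx + m.x[sel].astype(np.int64)
    order = np.lexsort((t_ms, pix))
    pix, t_ms = pix[order], t_ms[order]
    counts: list[int] = []
    for p in np.unique(pix):
        ts = t_ms[pix == p]
        c = 0
        last = -np.inf
        for t in ts:
            if t - last >= erp_min_ms:
                c += 1
                last = t
        reps = c - 1
        counts.append(reps)
        count_map[p // nx, p % nx] = reps
    hist: dict[int, int] = {}
    for c in counts:
        hist[c] = hist.get(c, 0) + 1
    if not hist:
        return RepetitivenessResult("non_repetitive", count_map, hist)
    if rule == "mode":
        peak = max(sorted(hist), key=lambda k: hist[k])
        repetitive = peak >= 1
    else:
        repeating = sum(n for k, n in hist.items() if k >= 1)
        repetitive = repeating > sum(hist.values()) / 2
    return RepetitivenessResult(
        "repetitive" if repetitive else "non_repetitive", count_map, hist)


# ---------------------------------------------------------------------------
# origins of activation
# ---------------------------------------------------------------------------

@dataclass
class OriginCluster:
    members: list[tuple[int, int, float]]   # (x, y, t_ms) of minima events
    beat_t_ms: float
    kind: str                               # "breakthrough" | "passive"
    centroid: tuple[int, int]


@dataclass
class OriginSet:
    clusters: list[OriginCluster]
    occurrence_map: np.ndarray      # +1 at every origin member pixel
    centroid_map: np.ndarray        # +1 at every cluster centroid

    def of_kind(self, kind: str) -> list[OriginCluster]:
        return [c for c in self.clusters if c.kind == kind]


def _periphery(mask: np.ndarray) -> np.ndarray:
    """Pixels 8-adjacent to the image border or to masked-out pixels."""
    ny, nx = mask.shape
    padded = np.zeros((ny + 2, nx + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    out = np.zeros_like(mask)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            out |= ~padded[1 + dy:ny + 1 + dy, 1 + dx:nx + 1 + dx]
    return out & mask


def detect_activation_origins(
    labeling: WaveFrontLabeling,
    label_id: int,
    erp_min_ms: float,
    mask: np.ndarray,
    sim_tol_ms: float | None = None,
) -> OriginSet:
    """Find activation-origin clusters of a wave front.

    pAT minima are events with no strictly preceding same-label event
    within ``erp_min_ms`` in their 8-neighborhood.  Minima are clustered
    by spatial 8-connectivity within a simultaneity tolerance
    (``sim_tol_ms``, default one frame).  Each cluster is then expanded
    over the near-simultaneous same-label region around it: if any
    expanded member has a neighbor event outside the region preceding it
    within ERPmin, the whole cluster is a false positive (continuation of
    propagation from a peripheral source) and is rejected.  Surviving
    clusters touching the mask periphery are typed ``passive``, interior
    ones ``breakthrough``.
    """
    m = labeling.matrix
    _, ny, nx = m.shape
    sel = np.nonzero(labeling.events_of(label_id))[0]
    occurrence = np.zeros((ny, nx), dtype=np.int32)
    centroid_map = np.zeros((ny, nx), dtype=np.int32)
    if sel.size == 0:
        return OriginSet([], occurrence, centroid_map)
    if sim_tol_ms is None:
        sim_tol_ms = m.dt_ms

    ex, ey, et = m.x[sel], m.y[sel], m.t_ms[sel]
    # per-pixel sorted time lists for neighbor queries
    bypix: dict[tuple[int, int], np.ndarray] = {}
    for p in set(zip(ex.tolist(), ey.tolist())):
        s = (ex == p[0]) & (ey == p[1])
        bypix[p] = np.sort(et[s])

    def preceded(x: int, y: int, t: float,
                 ignore: set[tuple[int, int, float]] | None = None) -> bool:
        for dx, dy in _OFFS:
            ts = bypix.get((x + dx, y + dy))
            if ts is None:
                continue
            i = np.searchsorted(ts, t)
            for tp in ts[:i][::-1]:
                if t - tp >= erp_min_ms:
                    break
                if tp < t and (ignore is None
                               or (x + dx, y + dy, float(tp)) not in ignore):
                    return True
        return False

    is_min = np.array([not preceded(int(x), int(y), float(t))
                       for x, y, t in zip(ex, ey, et)])
    min_idx = np.nonzero(is_min)[0]
    if min_idx.size == 0:
        return OriginSet([], occurrence, centroid_map)

    # cluster minima: spatial 8-connectivity + near-simultaneity
    pts = [(int(ex[i]), int(ey[i]), float(et[i])) for i in min_idx]
    unvisited = set(range(len(pts)))
    by_xy: dict[tuple[int, int], list[int]] = {}
    for i, (x, y, _) in enumerate(pts):
        by_xy.setdefault((x, y), []).append(i)
    raw_clusters: list[list[int]] = []
    while unvisited:
        seed = unvisited.pop()
        comp = [seed]
        q = deque([seed])
        while q:
            i = q.popleft()
            x, y, t = pts[i]
            for dx, dy in _OFFS:
                for j in by_xy.get((x + dx, y + dy), ()):
                    if j in unvisited and abs(pts[j][2] - t) <= sim_tol_ms:
                        unvisited.remove(j)
                        comp.append(j)
                        q.append(j)
        raw_clusters.append(comp)

    periph = _periphery(mask)
    all_pts = {(int(x), int(y), float(t)) for x, y, t in zip(ex, ey, et)}

    def expand(members: list[tuple[int, int, float]]) -> set:
        """Near-simultaneous same-label region chained around the cluster."""
        region = set(members)
        q = deque(members)
        while q:
            x, y, t = q.popleft()
            for dx, dy in _OFFS:
                nxp, nyp = x + dx, y + dy
                ts = bypix.get((nxp, nyp))
                if ts is None:
                    continue
                for tn in ts[(ts >= t - sim_tol_ms) & (ts <= t + sim_tol_ms)]:
                    p = (nxp, nyp, float(tn))
                    if p in all_pts and p not in region:
                        region.add(p)
                        q.append(p)
        return region

    # merge raw clusters whose simultaneous regions overlap (one physical origin
    # can produce several disjoint minima patches inside its region)
    regions = [expand([pts[i] for i in comp]) for comp in raw_clusters]
    parent = list(range(len(raw_clusters)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            if regions[i] & regions[j]:
                parent[find(i)] = find(j)
    merged: dict[int, list[int]] = {}
    for i in range(len(raw_clusters)):
        merged.setdefault(find(i), []).append(i)

    clusters: list[OriginCluster] = []
    for group in merged.values():
        members = [pts[i] for g in group for i in raw_clusters[g]]
        region = set().union(*(regions[g] for g in group))
        beat_t = min(p[2] for p in members)
        if any(preceded(x, y, t, ignore=region) for x, y, t in region):
            continue  # false-positive cluster fed from the periphery
        xs = np.array([p[0] for p in members], dtype=float)
        ys = np.array([p[1] for p in members], dtype=float)
        cx, cy = int(round(xs.mean())), int(round(ys.mean()))
        kind = "passive" if any(periph[p[1], p[0]] for p in members) else "breakthrough"
        for x, y, _ in members:
            occurrence[y, x] += 1
        centroid_map[cy, cx] += 1
        clusters.append(OriginCluster(members, beat_t, kind, (cx, cy)))
    clusters.sort(key=lambda c: c.beat_t_ms)
    return OriginSet(clusters, occurrence, centroid_map)


# ---------------------------------------------------------------------------
# dynamic map stacks
# ---------------------------------------------------------------------------

@dataclass
class DynamicMap:
    values: np.ndarray      # (ny, nx) time map, NaN sentinel
    fresh: np.ndarray       # bool; True where this map wrote a new value
    t_start_ms: float
    t_end_ms: float


@dataclass
class DynamicMapStack:
    maps: list[DynamicMap]

    def __len__(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)


def dynamic_map_stack(
    events_xyt: tuple[np.ndarray, np.ndarray, np.ndarray],
    shape: tuple[int, int],
    window_ms: tuple[float, float] | None = None,
) -> DynamicMapStack:
    """Tile a time-point matrix (pAT or RT) into collision-free partial maps.

    Events (x, y, t_ms arrays) are consumed in time order; the current map
    fills until an event lands on a pixel it already holds, at which point
    a new map starts as a copy of the previous one and the colliding event
    overwrites forward.  Every event is written exactly once as a fresh
    value, so the multiset of fresh values equals the multiset of windowed
    events.
    """
    x, y, t = (np.asarray(a) for a in events_xyt)
    if window_ms is not None:
        t0, t1 = window_ms
        if t1 <= t0:
            raise ValueError("empty dynamic-map window")
        keep = (t >= t0) & (t < t1)
        x, y, t = x[keep], y[keep], t[keep]
    order = np.lexsort((x, y, t))
    x, y, t = x[order], y[order], t[order]
    maps: list[DynamicMap] = []
    if x.size == 0:
        return DynamicMapStack(maps)
    cur = new_map(shape)
    fresh = np.zeros(shape, dtype=bool)
    start = float(t[0])
    for xi, yi, ti in zip(x, y, t):
        if fresh[yi, xi]:
            maps.append(DynamicMap(cur.copy(), fresh.copy(), start, float(ti)))
            fresh = np.zeros(shape, dtype=bool)
            start = float(ti)
        cur[yi, xi] = ti
        fresh[yi, xi] = True
    maps.append(DynamicMap(cur, fresh, start, float(t[-1])))
    return DynamicMapStack(maps)


# ---------------------------------------------------------------------------
# conduction vectors, fields and source classification
# ---------------------------------------------------------------------------

def conduction_vector_field(at_map_ms: np.ndarray, pitch_mm: float = 1.0,
                            max_dt_ms: float | None = None) -> np.ndarray:
    """Unit propagation direction per pixel from local AT plane fits.

    Fits AT = a*x + b*y + c over the defined pixels of a 3x3 window
    (expanded to 5x5 when rank-deficient) and normalizes the spatial
    gradient; the gradient of AT points in the direction of propagation.
    Neighbors whose AT differs from the center by more than ``max_dt_ms``
    (conduction block — e.g. across the wavefront line of a reentrant
    map, where successive cycles abut) are excluded from the fit.
    Returns (ny, nx, 2) with (ux, uy); NaN where undefined.
    """
    ny, nx = at_map_ms.shape
    out = np.full((ny, nx, 2), np.nan)
    good = np.isfinite(at_map_ms)
    for y in range(ny):
        for x in range(nx):
            if not good[y, x]:
                continue
            g = _plane_gradient(at_map_ms, good, x, y, 1, max_dt_ms)
            if g is None:
                g = _plane_gradient(at_map_ms, good, x, y, 2, max_dt_ms)
            if g is None:
                continue
            gx, gy = g
            norm = float(np.hypot(gx, gy))
            if norm < 1e-12:
                continue  # simultaneous patch: direction undefined
            out[y, x, 0] = gx / norm
            out[y, x, 1] = gy / norm
    return out


def _plane_gradient(at, good, x, y, r, max_dt_ms=None):
    ny, nx = at.shape
    xs, ys, ts = [], [], []
    t0 = at[y, x]
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            xx, yy = x + dx, y + dy
            if 0 <= xx < nx and 0 <= yy < ny and good[yy, xx]:
                if max_dt_ms is not None and abs(at[yy, xx] - t0) > max_dt_ms:
                    continue
                xs.append(dx)
                ys.append(dy)
                ts.append(at[yy, xx])
    if len(ts) < 4:
        return None
    a = np.column_stack([xs, ys, np.ones(len(ts))])
    sol, _, rank, _ = np.linalg.lstsq(a, np.asarray(ts), rcond=None)
    if rank < 3:
        return None
    return sol[0], sol[1]


def _ray_intersects(src: tuple[int, int], direction: np.ndarray,
                    dst: tuple[int, int], tol_px: float = 0.5) -> bool:
    """Does the ray from ``src`` along ``direction`` pass within ``tol_px``
    of ``dst``'s pixel center (forward direction only)?"""
    d = np.array([dst[0] - src[0], dst[1] - src[1]], dtype=float)
    s = float(d @ direction)
    if s < 0:
        return False
    perp = d - s * direction
    return float(np.hypot(*perp)) <= tol_px


@dataclass
class ConductionField:
    leading_point: tuple[int, int]          # (x, y)
    leading_t_ms: float
    points: set[tuple[int, int]] = field(default_factory=set)
    tortuous_points: set[tuple[int, int]] = field(default_factory=set)
    no_intersecting_neighbor: set[tuple[int, int]] = field(default_factory=set)


def leading_points(at_map_ms: np.ndarray) -> list[tuple[int, int]]:
    """Locally maximal pAT pixels of a dynamic map — the leading edge."""
    ny, nx = at_map_ms.shape
    good = np.isfinite(at_map_ms)
    pts = []
    for y in range(ny):
        for x in range(nx):
            if not good[y, x]:
                continue
            t = at_map_ms[y, x]
            is_max = False
            has_neighbor = False
            ok = True
            for dx, dy in _OFFS:
                xx, yy = x + dx, y + dy
                if 0 <= xx < nx and 0 <= yy < ny and good[yy, xx]:
                    has_neighbor = True
                    if at_map_ms[yy, xx] > t:
                        ok = False
                        break
                    if at_map_ms[yy, xx] < t:
                        is_max = True
            if ok and (is_max or not has_neighbor):
                pts.append((x, y))
    return pts


def leading_front_conduction_fields(
    at_map_ms: np.ndarray,
    vectors: np.ndarray,
    theta_t_cb_ms: float,
) -> list[ConductionField]:
    """Backward flood from each leading-edge point over intersecting vectors.

    From a leading point at time t, 8-neighbors with pAT strictly earlier
    within ``(t - theta, t)`` whose conduction-vector ray intersects the
    current pixel are recruited into the field; the flood recurses from
    each recruited pixel with its own time.  (Simultaneous neighbors are
    co-activated, not upstream, and are excluded.)  A neighbor whose
    conduction direction is undefined — a simultaneous patch or a focal
    apex — cannot be ruled out and is recruited as well.  Neighbors inside
    the time window but without an intersecting (defined) vector flag the
    current point as tortuous.
    """
    ny, nx = at_map_ms.shape
    good = np.isfinite(at_map_ms)
    fields = []
    for lx, ly in leading_points(at_map_ms):
        fld = ConductionField((lx, ly), float(at_map_ms[ly, lx]))
        fld.points.add((lx, ly))
        q = deque([(lx, ly)])
        while q:
            x, y = q.popleft()
            t = at_map_ms[y, x]
            eligible = 0
            recruited = 0
            for dx, dy in _OFFS:
                xx, yy = x + dx, y + dy
                if not (0 <= xx < nx and 0 <= yy < ny and good[yy, xx]):
                    continue
                tn = at_map_ms[yy, xx]
                if not (t - theta_t_cb_ms < tn < t):
                    continue
                eligible += 1
                u = vectors[yy, xx]
                undefined = not np.isfinite(u).all()
                if undefined or _ray_intersects((xx, yy), u, (x, y)):
                    recruited += 1
                    if (xx, yy) not in fld.points:
                        fld.points.add((xx, yy))
                        q.append((xx, yy))
            if eligible and not recruited:
                fld.tortuous_points.add((x, y))
            if not recruited:
                fld.no_intersecting_neighbor.add((x, y))
        fields.append(fld)
    return fields


@dataclass
class SourceClassification:
    per_point: dict[tuple[int, int], list[str]]   # leading point -> classes
    counts: dict[str, int]
    percentages: dict[str, float]                 # normalized to 100 over assignments

    @property
    def n_leading(self) -> int:
        return len(self.per_point)


def classify_front_sources(
    fields: list[ConductionField],
    origins: OriginSet,
    at_map_ms: np.ndarray,
    erp_min_ms: float,
    theta_t_cb_ms: float,
    labeling: WaveFrontLabeling | None = None,
    label_id: int | None = None,
    window_ms: tuple[float, float] | None = None,
) -> SourceClassification:
    """Classify each leading point's conduction field against five criteria.

    A field may satisfy several criteria; every satisfied class is
    recorded and aggregate percentages are normalized over all
    assignments.  Fields matching no criterion fall back to the class of
    the nearest plausible mechanism being undecidable and are recorded
    under ``tortuous`` only if flagged — otherwise they contribute no
    assignment.
    """
    ny, nx = at_map_ms.shape
    bt_pixels = {(x, y) for c in origins.of_kind("breakthrough") for x, y, _ in c.members}
    pa_pixels = {(x, y) for c in origins.of_kind("passive") for x, y, _ in c.members}

    other_label = np.zeros((ny, nx), dtype=bool)
    if labeling is not None and label_id is not None:
        m = labeling.matrix
        keep = labeling.labels > 0
        if window_ms is not None:
            keep &= (m.t_ms >= window_ms[0]) & (m.t_ms < window_ms[1])
        diff = keep & (labeling.labels != label_id)
        other_label[m.y[diff], m.x[diff]] = True

    per_point: dict[tuple[int, int], list[str]] = {}
    for fld in fields:
        classes: list[str] = []
        if fld.points & bt_pixels:
            classes.append("breakthrough")
        if fld.points & pa_pixels:
            classes.append("passive")
        # myocardial reentry: same-field neighbors separated by > ERPmin
        reentry = False
        for x, y in fld.points:
            t = at_map_ms[y, x]
            for dx, dy in _OFFS:
                p = (x + dx, y + dy)
                if p in fld.points and abs(at_map_ms[p[1], p[0]] - t) > erp_min_ms:
                    reentry = True
                    break
            if reentry:
                break
        if reentry:
            classes.append("myocardial_reentry")
        if fld.tortuous_points:
            classes.append("tortuous")
        boundary = False
        for x, y in fld.no_intersecting_neighbor:
            for dx, dy in _OFFS:
                xx, yy = x + dx, y + dy
                if 0 <= xx < nx and 0 <= yy < ny and other_label[yy, xx]:
                    boundary = True
                    break
            if boundary:
                break
        if boundary:
            classes.append("boundary")
        per_point[fld.leading_point] = classes

    counts = {name: 0 for name in CLASS_NAMES}
    for classes in per_point.values():
        for c in classes:
            counts[c] += 1
    total = sum(counts.values())
    percentages = {
        name: (100.0 * counts[name] / total if total else 0.0)
        for name in CLASS_NAMES
    }
    return SourceClassification(per_point, counts, percentages)
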