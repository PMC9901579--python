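"""Readers and writers for stacks, masks, event tables and maps.

Supported stack dialects:

* multi-frame TIFF (frames = time);
* raw binary + JSON sidecar: little-endian ``float32`` or ``uint16``,
  x-fastest (t, y, x) order, sidecar ``{nx, ny, nt, dt_ms, pitch_mm,
  dtype}`` stored next to the binary with a ``.json`` suffix.

Masks are single-frame TIFF or PNG, nonzero = inside the ROI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activation import ActivationMatrix, PRIMARY
from .stack import VoltageStack

_RAW_DTYPES = {"float32": "<f4", "uint16": "<u2"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_stack(path: str | Path, dt_ms: float | None = None,
               pitch_mm: float | None = None) -> VoltageStack:
    """Load a stack from TIFF or raw-binary + sidecar.

    For TIFF, ``dt_ms``/``pitch_mm`` default to 1.0 ms / 0.7 mm unless
    given; for raw binary they come from the sidecar (arguments override).
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        return VoltageStack(data=np.asarray(data, dtype=np.float32),
                            dt_ms=dt_ms or 1.0, pitch_mm=pitch_mm or 0.7,
                            meta={"source": str(path)})
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar {sidecar} not found for raw stack {path}")
    info = json.loads(sidecar.read_text())
    dtype = _RAW_DTYPES.get(info.get("dtype", "float32"))
    if dtype is None:
        raise ValueError(f"unsupported raw dtype {info.get('dtype')!r}")
    data = np.fromfile(path, dtype=dtype)
    nt, ny, nx = int(info["nt"]), int(info["ny"]), int(info["nx"])
    if data.size != nt * ny * nx:
        raise ValueError(
            f"raw file holds {data.size} samples, sidecar promises {nt * ny * nx}")
    data = data.reshape(nt, ny, nx).astype(np.float32)
    return VoltageStack(
        data=data,
        dt_ms=dt_ms or float(info.get("dt_ms", 1.0)),
        pitch_mm=pitch_mm or float(info.get("pitch_mm", 0.7)),
        meta={"source": str(path), "sidecar": info},
    )


def write_stack_raw(stack: VoltageStack, path: str | Path) -> Path:
    """Write a stack as little-endian float32 raw binary + JSON sidecar."""
    path = Path(path)
    stack.data.astype("<f4").tofile(path)
    sidecar = {
        "nx": stack.nx, "ny": stack.ny, "nt": stack.nt,
        "dt_ms": stack.dt_ms, "pitch_mm": stack.pitch_mm, "dtype": "float32",
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_mask(path: str | Path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Load a boolean ROI mask from single-frame TIFF or PNG (nonzero = in)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file {path} not found")
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    if img.ndim == 3:  # RGB(A): any nonzero channel counts
        img = img.max(axis=-1)
    mask = np.asarray(img) != 0
    if shape is not None and mask.shape != shape:
        raise ValueError(f"mask shape {mask.shape} does not match stack {shape}")
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))
    return path


def write_events_csv(matrix: ActivationMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path, shape: tuple[int, int, int],
                    dt_ms: float = 1.0) -> ActivationMatrix:
    df = pd.read_csv(path)
    comp = (df["component"].astype(str) == "secondary").to_numpy().astype(np.int8)
    t = np.rint(df["t_ms"].to_numpy() / dt_ms).astype(np.int32)
    m = ActivationMatrix(
        x=df["x"].to_numpy(np.int32), y=df["y"].to_numpy(np.int32), t=t,
        component=np.where(comp, 1, PRIMARY).astype(np.int8),
        vf_star=df["vf_star"].to_numpy(np.float32),
        shape=shape, dt_ms=dt_ms,
    )
    return m


def write_windows_csv(window_mask: np.ndarray, dt_ms: float,
                      path: str | Path) -> Path:
    """Per-pixel upstroke interval list (x, y, t_start_ms, t_end_ms)."""
    from .phase import UpstrokeWindows

    path = Path(path)
    rows = []
    _, ny, nx = window_mask.shape
    for y in range(ny):
        for x in range(nx):
            col = window_mask[:, y, x]
            if not col.any():
                continue
            for a, b in UpstrokeWindows.from_mask(col).intervals:
                rows.append((x, y, a * dt_ms, b * dt_ms))
    pd.DataFrame(rows, columns=["x", "y", "t_start_ms", "t_end_ms"]).to_csv(
        path, index=False)
    return path


def write_dense_events(matrix: ActivationMatrix, path: str | Path,
                       dt_ms: float = 1.0, pitch_mm: float = 0.7) -> Path:
    """Dense boolean pAT matrix in the raw-binary + sidecar dialect."""
    dense = matrix.dense().astype(np.float32)
    return write_stack_raw(VoltageStack(dense, dt_ms, pitch_mm), path)


def export_dynamic_stack(stack, outdir: str | Path, prefix: str = "dyn",
                         isoline_ms: float = 10.0) -> list[Path]:
    """Numbered CSV + PNG series for a dynamic map stack."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, dyn in enumerate(stack):
        p = write_map_csv(dyn.values, outdir / f"{prefix}_{i:03d}.csv")
        written.append(p)
        written.append(render_isochrone_png(
            dyn.values, outdir / f"{prefix}_{i:03d}.png", isoline_ms,
            title=f"{prefix} #{i} [{dyn.t_start_ms:.0f}-{dyn.t_end_ms:.0f} ms]"))
    return written


def write_map_csv(map_: np.ndarray, path: str | Path) -> Path:
    """Scalar map as a dense CSV matrix; blank cells for the sentinel."""
    path = Path(path)
    pd.DataFrame(map_).to_csv(path, index=False, header=False)
    return path


def read_map_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def render_isochrone_png(map_ms: np.ndarray, path: str | Path,
                         isoline_ms: float = 10.0, title: str = "") -> Path:
    """Render an AT/RT map with isolines every ``isoline_ms`` ms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.imshow(map_ms, origin="upper", cmap="viridis")
    finite = np.isfinite(map_ms)
    if finite.sum() > 10:
        lo, hi = np.nanmin(map_ms), np.nanmax(map_ms)
        if hi - lo > isoline_ms:
            levels = np.arange(np.ceil(lo / isoline_ms) * isoline_ms, hi, isoline_ms)
            ax.contour(map_ms, levels=levels, colors="k", linewidths=0.5)
    fig.colorbar(im, ax=ax, label="ms")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
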