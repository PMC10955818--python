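"""Volume, surface and en-face I/O with explicit axis conventions.

The canonical in-memory layout for an OCT acquisition is a rank-4 array
``[S, R, Z, X]``: slow (frame) position, repeat index, depth, fast (lateral)
position.  Indices are 0-based and depth increases away from the vitreous.
On disk a volume is a multi-page TIFF (one page per B-scan, slow-major page
order with repeats contiguous) or a raw binary grid; both carry a JSON
sidecar declaring shape, dtype, page order and native dynamic range
(``bit_max``).  Axis order is never inferred: raw files without a sidecar
are rejected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


class FormatError(ValueError):
    """Missing or malformed sidecar / container."""


class ShapeError(ValueError):
    """Declared and actual grid shapes disagree."""


class GeometryError(ValueError):
    """Layer surfaces cross or leave the grid."""


@dataclass
class OCTVolume:
    """Rank-4 OCT intensity grid ``[S, R, Z, X]`` with physical pixel sizes.

    Parameters
    ----------
    data : ndarray
        Non-negative intensities, shape (S, R, Z, X).
    dz_um, dx_um, ds_um : float
        Pixel pitch in depth, fast and slow directions (micrometres).
    bit_max : float
        Native dynamic range of the acquisition (e.g. 255 for 8-bit).
    """

    data: np.ndarray
    dz_um: float = 1.0
    dx_um: float = 1.0
    ds_um: float = 1.0
    bit_max: float = 255.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ShapeError(f"expected rank-4 [S,R,Z,X], got rank {self.data.ndim}")
        s, r, z, x = self.data.shape
        if s < 1 or r < 1 or z < 2 or x < 2:
            raise ShapeError(f"degenerate volume shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")
        for name in ("dz_um", "dx_um", "ds_um", "bit_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape

    @property
    def S(self) -> int:
        return self.data.shape[0]

    @property
    def R(self) -> int:
        return self.data.shape[1]

    @property
    def Z(self) -> int:
        return self.data.shape[2]

    @property
    def X(self) -> int:
        return self.data.shape[3]


@dataclass
class AngiogramVolume:
    """Rank-3 flow-contrast grid ``[S, Z, X]``.

    ``provenance`` records how the angiogram was produced: speckle variance
    over repeats (``temporal_sv``), over adjacent slow positions
    (``spatial_sv``), or a trained model (``model``).  ``n_scans`` is the
    number of B-scans entering each output frame.
    """

    data: np.ndarray
    provenance: str = "temporal_sv"
    n_scans: int = 0

    _PROVENANCES = ("temporal_sv", "spatial_sv", "model")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"expected rank-3 [S,Z,X], got rank {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("angiogram must be finite")
        if np.any(self.data < 0):
            raise ValueError("angiogram must be non-negative")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def S(self) -> int:
        return self.data.shape[0]


@dataclass
class LayerSurfaces:
    """Named depth boundaries, each a rank-2 ``[S, X]`` grid of z coordinates.

    A slab named ``L`` is delimited by surfaces ``L_top`` and ``L_bottom``.
    ``filled`` flags labels where missing CSV entries were completed by
    nearest-neighbor interpolation.
    """

    surfaces: dict[str, np.ndarray]
    filled: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.surfaces = {k: np.asarray(v, dtype=np.float64) for k, v in self.surfaces.items()}
        shapes = {v.shape for v in self.surfaces.values()}
        if len(shapes) > 1:
            raise ShapeError(f"surfaces have inconsistent shapes: {shapes}")

    def slab(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (top, bottom) grids for slab ``label``; validates ordering."""
        try:
            top = self.surfaces[f"{label}_top"]
            bottom = self.surfaces[f"{label}_bottom"]
        except KeyError as e:
            raise KeyError(f"slab {label!r}: missing surface {e.args[0]!r}") from None
        if np.any(top > bottom):
            raise GeometryError(f"slab {label!r}: top surface crosses bottom")
        return top, bottom

    @property
    def labels(self) -> list[str]:
        """Slab labels for which both bounding surfaces are present."""
        return sorted(
            k[:-4] for k in self.surfaces
            if k.endswith("_top") and f"{k[:-4]}_bottom" in self.surfaces
        )


@dataclass
class EnFaceImage:
    """Rank-2 ``[S, X]`` projection of a depth slab."""

    data: np.ndarray
    slab: str = ""
    normalized: bool = False
    bit_max: float = 255.0
    degenerate: bool = False  # set when normalization hit a constant image

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError(f"en-face image must be rank 2, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("en-face image must be finite")
        if self.normalized and (self.data.min() < 0 or self.data.max() > self.bit_max):
            raise ValueError("normalized image out of [0, bit_max]")


# ---------------------------------------------------------------------------
# volume read/write


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(vol: OCTVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF (slow-major pages) plus JSON sidecar."""
    path = Path(path)
    s, r, z, x = vol.shape
    pages = vol.data.reshape(s * r, z, x)
    tifffile.imwrite(path, pages)
    sidecar = {
        "S": s,
        "R": r,
        "Z": z,
        "X": x,
        "page_order": "slow_major",
        "dtype": str(vol.data.dtype),
        "bit_max": vol.bit_max,
        "dz_um": vol.dz_um,
        "dx_um": vol.dx_um,
        "ds_um": vol.ds_um,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path, sidecar: dict | None = None) -> OCTVolume:
    """Read a TIFF or raw-binary volume into the canonical [S,R,Z,X] layout.

    TIFF files may omit the sidecar file only if ``sidecar`` is passed
    explicitly; raw files always require one.  The sidecar declares the page
    order (``slow_major``: repeats contiguous within a slow position).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sidecar is None:
        sc_path = _sidecar_path(path)
        if not sc_path.exists():
            raise FormatError(f"no sidecar {sc_path.name}; axis order cannot be inferred")
        sidecar = json.loads(sc_path.read_text())
    for key in ("S", "R", "Z", "X"):
        if key not in sidecar:
            raise FormatError(f"sidecar missing {key!r}")
    s, r, z, x = (int(sidecar[k]) for k in ("S", "R", "Z", "X"))
    if sidecar.get("page_order", "slow_major") != "slow_major":
        raise FormatError(f"unsupported page_order {sidecar.get('page_order')!r}")

    if path.suffix.lower() in (".tif", ".tiff"):
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        if pages.shape[0] != s * r:
            raise ShapeError(f"TIFF has {pages.shape[0]} pages, sidecar declares {s * r}")
        if pages.shape[1:] != (z, x):
            raise ShapeError(f"page shape {pages.shape[1:]} != declared ({z}, {x})")
        data = pages.reshape(s, r, z, x)
    else:
        dtype = np.dtype(sidecar.get("dtype", "float64"))
        raw = np.fromfile(path, dtype=dtype)
        if raw.size != s * r * z * x:
            raise ShapeError(f"raw file holds {raw.size} values, sidecar declares {s * r * z * x}")
        data = raw.reshape(s, r, z, x)

    return OCTVolume(
        data=data,
        dz_um=float(sidecar.get("dz_um", 1.0)),
        dx_um=float(sidecar.get("dx_um", 1.0)),
        ds_um=float(sidecar.get("ds_um", 1.0)),
        bit_max=float(sidecar.get("bit_max", 255.0)),
    )


def write_enface(img: EnFaceImage, path: str | Path) -> None:
    """Export a normalized en-face image as 8- or 16-bit grayscale PNG/TIFF."""
    import imageio.v3 as iio

    if not img.normalized:
        raise ValueError("en-face image must be normalized before export")
    path = Path(path)
    dtype = np.uint8 if img.bit_max <= 255 else np.uint16
    pixels = np.round(img.data).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


# ---------------------------------------------------------------------------
# layer surfaces


def read_surfaces(path: str | Path) -> LayerSurfaces:
    """Read a long-format CSV (surface_label, s, x, z) into dense [S,X] grids.

    Missing (s, x) cells are completed by nearest-neighbor propagation and
    the affected label is flagged in ``filled``.  Slabs whose top crosses
    bottom after completion raise :class:`GeometryError`.
    """
    df = pd.read_csv(path)
    required = {"surface_label", "s", "x", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"surface CSV must have columns {sorted(required)}")
    S = int(df["s"].max()) + 1
    X = int(df["x"].max()) + 1
    surfaces: dict[str, np.ndarray] = {}
    filled: set[str] = set()
    for label, grp in df.groupby("surface_label"):
        grid = np.full((S, X), np.nan)
        grid[grp["s"].to_numpy(int), grp["x"].to_numpy(int)] = grp["z"].to_numpy(float)
        if np.isnan(grid).any():
            grid = _fill_nearest(grid)
            filled.add(str(label))
        surfaces[str(label)] = grid
    out = LayerSurfaces(surfaces=surfaces, filled=filled)
    for lab in out.labels:
        out.slab(lab)  # raises GeometryError on crossing
    return out


def _fill_nearest(grid: np.ndarray) -> np.ndarray:
    from scipy.ndimage import distance_transform_edt

    mask = np.isnan(grid)
    idx = distance_transform_edt(mask, return_distances=False, return_indices=True)
    return grid[tuple(idx)]


def surfaces_to_csv(surf: LayerSurfaces, path: str | Path) -> None:
    rows = []
    for label, grid in surf.surfaces.items():
        S, X = grid.shape
        ss, xx = np.meshgrid(np.arange(S), np.arange(X), indexing="ij")
        rows.append(
            pd.DataFrame(
                {"surface_label": label, "s": ss.ravel(), "x": xx.ravel(), "z": grid.ravel()}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
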