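"""En-face slab projection and intensity normalization.

All quantitative evaluation happens on 2-D en-face images: a rank-3
volume [S, Z, X] reduced over a depth slab delimited by two layer
surfaces (superficial and deep vascular plexus by default).
"""

from __future__ import annotations

import numpy as np

from .io import EnFaceImage, LayerSurfaces


def project_slab(volume: np.ndarray, surfaces: LayerSurfaces, slab: str,
                 reducer: str = "max") -> EnFaceImage:
    """Reduce ``volume[s, z, x]`` over z in [ceil(top), floor(bottom)].

    The integer span is inclusive; fractional surfaces are not
    interpolated.  Empty spans (floor < ceil) produce 0 and set the
    ``degenerate`` flag.  ``reducer`` is one of max, mean, sum.
    """
    if reducer not in ("max", "mean", "sum"):
        raise ValueError(f"unknown reducer {reducer!r}")
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("expected rank-3 [S, Z, X] volume")
    top, bottom = surfaces.slab(slab)
    S, Z, X = volume.shape
    if top.shape != (S, X):
        raise ValueError(f"surface grid {top.shape} does not match volume ({S}, {X})")
    z_lo = np.ceil(top).astype(int)
    z_hi = np.floor(bottom).astype(int)
    z_lo = np.clip(z_lo, 0, Z - 1)
    z_hi = np.clip(z_hi, 0, Z - 1)
    empty = z_hi < z_lo

    zz = np.arange(Z)[None, :, None]
    inside = (zz >= z_lo[:, None, :]) & (zz <= z_hi[:, None, :])
    if reducer == "max":
        out = np.where(inside, volume, -np.inf).max(axis=1)
        out[empty] = 0.0
    elif reducer == "sum":
        out = np.where(inside, volume, 0.0).sum(axis=1)
    else:
        count = inside.sum(axis=1)
        out = np.where(inside, volume, 0.0).sum(axis=1)
        out = np.divide(out, count, out=np.zeros_like(out), where=count > 0)
    out[empty] = 0.0
    return EnFaceImage(data=out, slab=slab, normalized=False, degenerate=bool(empty.any()))


def normalize_enface(img: EnFaceImage, bit_max: float = 255.0,
                     saturation_pct: float = 0.1) -> EnFaceImage:
    """Linearly map the [p, 100 - p] percentile range to [0, bit_max].

    ``saturation_pct`` percent of pixels saturate at each tail (robust to
    hot pixels).  A constant image maps to all-zero with the degenerate
    flag set.  Deterministic.
    """
    data = img.data
    lo = np.percentile(data, saturation_pct)
    hi = np.percentile(data, 100.0 - saturation_pct)
    if hi <= lo:
        return EnFaceImage(data=np.zeros_like(data), slab=img.slab, normalized=True,
                           bit_max=bit_max, degenerate=True)
    out = np.clip((data - lo) / (hi - lo), 0.0, 1.0) * bit_max
    return EnFaceImage(data=out, slab=img.slab, normalized=True,
                       bit_max=bit_max, degenerate=img.degenerate)
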