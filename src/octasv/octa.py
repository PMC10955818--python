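"""Speckle-variance OCTA construction.

Flow contrast comes from the per-pixel variance of OCT intensity across a
set of B-scans: voxels with moving scatterers decorrelate between scans and
show high variance, static tissue stays correlated and shows low variance.
Two modes share one estimator:

* **temporal** (TVC): variance over the first ``n`` repeated B-scans at one
  slow position — the conventional multi-scan OCTA.
* **spatial** (SVC): variance over ``n`` *adjacent* slow positions in a
  single-scan volume, exploiting vessel continuity across neighboring
  B-scans.

The module also assembles the 1- or 3-channel neighbor stacks that a
learned OCTA constructor consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AngiogramVolume, OCTVolume


@dataclass
class SVConfig:
    """Speckle-variance configuration.

    ``edge_policy`` governs spatial-mode windows at the volume boundary:
    ``reflect`` mirrors indices (output length S), ``clamp`` repeats the
    edge frame (output length S), ``valid`` keeps only fully interior
    windows (output length S - n + 1).
    """

    mode: str = "temporal"            # temporal | spatial
    n_scans: int = 4                  # 2..4
    edge_policy: str = "reflect"      # reflect | clamp | valid
    variance_kind: str = "population" # population | sample
    single_repeat: bool = False       # spatial mode: use repeat 0 instead of repeat mean

    def __post_init__(self) -> None:
        if self.mode not in ("temporal", "spatial"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_scans not in (2, 3, 4):
            raise ValueError("n_scans must be 2, 3 or 4")
        if self.edge_policy not in ("reflect", "clamp", "valid"):
            raise ValueError(f"unknown edge_policy {self.edge_policy!r}")
        if self.variance_kind not in ("population", "sample"):
            raise ValueError(f"unknown variance_kind {self.variance_kind!r}")


@dataclass
class NeighborStack:
    """[Z, X, C] stack of OCT frames centered at slow position ``center_index``.

    For C = 3 the channel order is fixed: (s-1, s, s+1)."""

    data: np.ndarray
    center_index: int
    C: int

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[2] != self.C:
            raise ValueError(f"stack shape {self.data.shape} inconsistent with C={self.C}")


def speckle_variance(frames, variance_kind: str = "population") -> np.ndarray:
    """Per-pixel variance across a list/stack of equally shaped 2-D frames.

    Population kind divides by C, sample kind by C - 1.  At least two
    frames are required.
    """
    stack = np.asarray(frames, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected a stack of 2-D frames")
    c = stack.shape[0]
    if c < 2:
        raise ValueError("speckle variance needs at least 2 frames")
    ddof = 0 if variance_kind == "population" else 1
    return np.var(stack, axis=0, ddof=ddof)


# Spatial-mode window offsets relative to the center position s.  Centered
# where possible, forward-biased for even n.
_SPATIAL_OFFSETS = {2: (0, 1), 3: (-1, 0, 1), 4: (-1, 0, 1, 2)}


def _resolve_index(i: int, n: int, policy: str) -> int:
    """Map an out-of-range slow index into [0, n) per the edge policy."""
    if 0 <= i < n:
        return i
    if policy == "clamp":
        return min(max(i, 0), n - 1)
    if policy == "reflect":
        # mirror without repeating the edge: -1 -> 1, n -> n-2
        period = 2 * n - 2
        i = abs(i) % period
        return period - i if i >= n else i
    raise IndexError(f"index {i} outside [0, {n}) under 'valid' policy")


def collapse_repeats(vol: OCTVolume, single_repeat: bool = False) -> np.ndarray:
    """One frame per slow position: repeat mean, or repeat 0 to emulate a
    genuine single-scan acquisition."""
    if single_repeat:
        return vol.data[:, 0].astype(np.float64)
    return vol.data.mean(axis=1)


def construct_octa(vol: OCTVolume, cfg: SVConfig) -> AngiogramVolume:
    """Build an angiogram volume by speckle variance.

    Temporal mode uses the first ``n_scans`` repeats at each slow position
    (the volume should be intra-frame registered).  Spatial mode collapses
    repeats to one frame per position, then takes variance over ``n_scans``
    adjacent positions with the configured window placement and edge
    policy (the volume should be inter-frame registered).
    """
    if cfg.mode == "temporal":
        if cfg.n_scans > vol.R:
            raise ValueError(f"temporal {cfg.n_scans}N needs R >= {cfg.n_scans}, volume has R={vol.R}")
        ddof = 0 if cfg.variance_kind == "population" else 1
        sv = np.var(vol.data[:, : cfg.n_scans].astype(np.float64), axis=1, ddof=ddof)
        return AngiogramVolume(sv, provenance="temporal_sv", n_scans=cfg.n_scans)

    n, S = cfg.n_scans, vol.S
    if n > S:
        raise ValueError(f"spatial {n}N needs S >= {n}, volume has S={S}")
    frames = collapse_repeats(vol, cfg.single_repeat)
    offsets = _SPATIAL_OFFSETS[n]
    if cfg.edge_policy == "valid":
        centers = [s for s in range(S) if 0 <= s + offsets[0] and s + offsets[-1] < S]
    else:
        centers = list(range(S))
    out = np.empty((len(centers), vol.Z, vol.X))
    for k, s in enumerate(centers):
        idx = [_resolve_index(s + o, S, cfg.edge_policy) for o in offsets]
        out[k] = speckle_variance(frames[idx], cfg.variance_kind)
    return AngiogramVolume(out, provenance="spatial_sv", n_scans=n)


def assemble_neighbor_stack(vol: OCTVolume, s: int, C: int = 3,
                            edge_policy: str = "reflect",
                            single_repeat: bool = False) -> NeighborStack:
    """OCT input stack for the learned constructor at slow position ``s``.

    C = 1 gives the collapsed frame at ``s``; C = 3 gives frames at
    (s-1, s, s+1) with the edge policy applied at volume boundaries.
    """
    if C not in (1, 3):
        raise ValueError("C must be 1 or 3")
    if not 0 <= s < vol.S:
        raise IndexError(f"slow position {s} outside [0, {vol.S})")
    frames = collapse_repeats(vol, single_repeat)
    if C == 1:
        data = frames[s][:, :, None]
    else:
        idx = [_resolve_index(s + o, vol.S, edge_policy) for o in (-1, 0, 1)]
        data = np.stack([frames[i] for i in idx], axis=-1)
    return NeighborStack(data=data, center_index=s, C=C)
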