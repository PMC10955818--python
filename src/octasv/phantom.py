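"""Synthetic OCT speckle phantom with flow-dependent decorrelation.

The phantom emulates the statistical structure that speckle-variance OCTA
exploits: fully developed speckle (complex circular-Gaussian field, unit
mean intensity) that is strongly correlated across repeated B-scans and
across adjacent slow positions in static tissue, but decorrelated wherever
blood flows.  The scene is a stack of retinal-like reflectance layers with
3-D vessel tubes; the deep plexus sits between two hypo-reflective bands
(inner/outer nuclear layers), mirroring retinal anatomy.

Correlation is decomposed per voxel into a *distance* part (an anatomy
speckle field evolving as AR(1) along the slow axis — beam-displacement
decorrelation accumulates with lateral distance) and a *time* part
(independent per-frame innovations — noise and bulk micro-motion, identical
between any two frames since the inter-frame period is the same for
repeats and neighbors).  The resulting complex field satisfies

* ``corr(g[s, r1], g[s, r2]) = rho_repeat``            (any repeat pair)
* ``corr(g[s, .],  g[s+k, .]) = rho_adjacent ** k ...`` (decaying with k)

with ``rho`` selected per voxel by the flow mask.  For circular-Gaussian
speckle the induced *intensity* correlation is ``rho ** 2``.

Rigid per-frame motion (and an optional linear drift) is applied after
synthesis as subpixel shifts with the exact ground-truth displacements
recorded, so registration tests can score recovery.  A blink artifact
optionally attenuates a band of slow positions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from .io import GeometryError, LayerSurfaces, OCTVolume


@dataclass
class Tube:
    """A vessel: centerline control points (s, z, x) in pixels, interpolated
    linearly along s, with circular cross-section of ``radius_px`` in the
    (z, x) plane."""

    points: list[tuple[float, float, float]]
    radius_px: float
    plexus: str = "SVP"
    reflectance: float = 1.0


@dataclass
class PhantomSpec:
    S: int = 32
    R: int = 4
    Z: int = 64
    X: int = 64
    # (z_top, z_bottom, reflectance), z_bottom exclusive
    layer_profile: list[tuple[int, int, float]] = field(default_factory=lambda: _DEFAULT_LAYERS.copy())
    vessels: list[Tube] = field(default_factory=list)
    rho_static_repeat: float = 0.98
    rho_flow_repeat: float = 0.2
    rho_static_adjacent: float = 0.9
    rho_flow_adjacent: float = 0.2
    noise_floor: float = 0.05
    motion_sigma_z: float = 0.0
    motion_sigma_x: float = 0.0
    drift_z_per_frame: float = 0.0
    drift_x_per_frame: float = 0.0
    blink: tuple[int, int, float] | None = None  # (s_start, s_len, attenuation)
    seed: int = 0
    dz_um: float = 4.0
    dx_um: float = 6.0
    ds_um: float = 12.0
    bit_max: float = 255.0

    def __post_init__(self) -> None:
        for name in ("rho_static_repeat", "rho_flow_repeat", "rho_static_adjacent", "rho_flow_adjacent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rho_flow_repeat >= self.rho_static_repeat:
            raise ValueError("flow must decorrelate faster than static tissue (repeat axis)")
        if self.rho_flow_adjacent >= self.rho_static_adjacent:
            raise ValueError("flow must decorrelate faster than static tissue (slow axis)")
        if any(r < 0 for _, _, r in self.layer_profile):
            raise ValueError("layer reflectances must be non-negative")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")


# Depth profile loosely modelled on a rodent retina B-scan: bright inner
# retina (houses the superficial plexus), hypo-reflective inner nuclear
# layer, a mid band for the deep plexus, hypo-reflective outer nuclear
# layer, bright RPE.  z in pixels for the default Z=64 grid.
_DEFAULT_LAYERS: list[tuple[int, int, float]] = [
    (0, 8, 0.05),    # vitreous
    (8, 22, 1.0),    # NFL/GCL/IPL — SVP slab
    (22, 26, 0.25),  # INL (hypo)
    (26, 42, 0.7),   # OPL band — DVP slab
    (42, 52, 0.2),   # ONL (hypo)
    (52, 60, 1.2),   # RPE complex
    (60, 64, 0.05),  # below
]

# Slab boundaries implied by the default profile.
_DEFAULT_SLABS = {"SVP": (8.0, 22.0), "DVP": (26.0, 42.0)}


@dataclass
class PhantomTruth:
    """Simulator ground truth: what the estimator should recover."""

    flow_mask: np.ndarray        # [S, Z, X] bool
    reflectance: np.ndarray      # [S, Z, X]
    surfaces: LayerSurfaces
    applied_shifts: np.ndarray   # [S, R, 2] (dz, dx) per frame


def default_vessels(spec_S: int, spec_Z: int, spec_X: int, rng: np.random.Generator) -> list[Tube]:
    """Randomized vessel layout: a few oblique superficial vessels and a
    denser bed of thinner deep vessels.  The obliquity is what makes wide
    spatial-SV windows smear vessels laterally (pseudo-vessel doubling)."""
    vessels: list[Tube] = []
    svp_z = 0.5 * (_DEFAULT_SLABS["SVP"][0] + _DEFAULT_SLABS["SVP"][1]) * spec_Z / 64.0
    dvp_z = 0.5 * (_DEFAULT_SLABS["DVP"][0] + _DEFAULT_SLABS["DVP"][1]) * spec_Z / 64.0
    # Obliquity: per-frame lateral drift of a vessel cross-section is a
    # fraction of its radius (B-scan spacing << vessel diameter in a
    # densely sampled volume), i.e. ~0.2-0.5 px per slow step.
    for i in range(3):
        x0 = rng.uniform(8, spec_X - 8)
        slope = rng.uniform(0.2, 0.5) * rng.choice([-1, 1])
        x1 = np.clip(x0 + slope * (spec_S - 1), 3, spec_X - 4)
        z = svp_z + rng.uniform(-2, 2)
        vessels.append(
            Tube(points=[(0, z, x0), (spec_S - 1, z, x1)],
                 radius_px=rng.uniform(1.6, 2.4), plexus="SVP", reflectance=1.0)
        )
    for i in range(4):
        x0 = rng.uniform(7, spec_X - 7)
        slope = rng.uniform(0.2, 0.5) * rng.choice([-1, 1])
        x1 = np.clip(x0 + slope * (spec_S - 1), 3, spec_X - 4)
        z = dvp_z + rng.uniform(-3, 3)
        vessels.append(
            Tube(points=[(0, z, x0), (spec_S - 1, z, x1)],
                 radius_px=rng.uniform(1.0, 1.6), plexus="DVP", reflectance=0.9)
        )
    return vessels


def default_phantom_spec(seed: int, **overrides) -> PhantomSpec:
    """Study-condition phantom: 4 repeats per slow position, layered retina,
    oblique vessels in both plexuses, small per-frame motion."""
    rng = np.random.default_rng(seed + 1_000_003)
    spec = PhantomSpec(seed=seed, motion_sigma_z=0.3, motion_sigma_x=0.3, **overrides)
    spec.vessels = default_vessels(spec.S, spec.Z, spec.X, rng)
    return spec


def human_phantom_spec(seed: int, **overrides) -> PhantomSpec:
    """Awake-subject acquisition conditions.

    Bulk micro-motion between consecutive frames lowers the *time* part of
    the static correlation (the inter-frame period is identical for
    repeats and neighbors, so both drop together), while dense sampling
    keeps the distance decorrelation between neighboring B-scans small.
    The temporal ground truth is correspondingly noisier than under the
    anesthetized (default) conditions.
    """
    overrides.setdefault("rho_static_repeat", 0.88)
    overrides.setdefault("rho_static_adjacent", 0.85)
    return default_phantom_spec(seed, **overrides)


# ---------------------------------------------------------------------------
# scene rasterization


def rasterize_scene(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, LayerSurfaces]:
    """Build the noiseless scene: layered reflectance with vessel voxels
    overwritten, a flow mask marking tube interiors, and layer surfaces."""
    S, Z, X = spec.S, spec.Z, spec.X
    profile = np.zeros(Z)
    for z0, z1, refl in spec.layer_profile:
        profile[z0:z1] = refl
    reflectance = np.broadcast_to(profile[None, :, None], (S, Z, X)).copy()
    flow = np.zeros((S, Z, X), dtype=bool)

    zz, xx = np.meshgrid(np.arange(Z), np.arange(X), indexing="ij")
    for tube in spec.vessels:
        pts = np.asarray(tube.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError("tube control points must be (s, z, x) triples")
        order = np.argsort(pts[:, 0])
        pts = pts[order]
        zs = np.interp(np.arange(S), pts[:, 0], pts[:, 1])
        xs = np.interp(np.arange(S), pts[:, 0], pts[:, 2])
        r = tube.radius_px
        if r >= Z or r >= X:
            raise GeometryError(f"tube radius {r} exceeds grid")
        if np.any(zs - r < 0) or np.any(zs + r > Z - 1) or np.any(xs - r < 0) or np.any(xs + r > X - 1):
            raise GeometryError("tube leaves the grid")
        for s in range(max(0, int(np.floor(pts[0, 0]))), min(S, int(np.ceil(pts[-1, 0])) + 1)):
            disk = (zz - zs[s]) ** 2 + (xx - xs[s]) ** 2 <= r**2
            flow[s] |= disk
            reflectance[s][disk] = tube.reflectance

    surfaces = LayerSurfaces(
        surfaces={
            f"{lab}_{side}": np.full((S, X), float(val))
            for lab, (top, bot) in _slab_bounds(spec).items()
            for side, val in (("top", top), ("bottom", bot))
        }
    )
    return reflectance, flow, surfaces


def _slab_bounds(spec: PhantomSpec) -> dict[str, tuple[float, float]]:
    if spec.layer_profile == _DEFAULT_LAYERS:
        return dict(_DEFAULT_SLABS)
    # generic fallback: one slab per layer, named by index
    return {f"L{i}": (float(z0), float(z1 - 1)) for i, (z0, z1, _) in enumerate(spec.layer_profile)}


# ---------------------------------------------------------------------------
# speckle synthesis


def _correlated_complex(rng: np.random.Generator, rho_t: np.ndarray, rho_d: np.ndarray,
                        S: int, R: int, Z: int, X: int) -> np.ndarray:
    """Unit-variance complex circular-Gaussian field with the acquisition's
    correlation structure, decomposed into a *distance* and a *time* part.

    An anatomy speckle field ``A[s]`` evolves along the slow axis as an
    AR(1) chain with per-voxel coefficient ``rho_d`` (beam-displacement
    decorrelation, cumulative with lateral distance).  Every acquired frame
    then mixes that field with an independent innovation:

        g[s, r] = sqrt(rho_t) * A[s] + sqrt(1 - rho_t) * eps[s, r]

    where ``rho_t`` is the time-driven (noise / bulk-micro-motion)
    correlation — identical between any two frames because the inter-frame
    period is the same for repeats and for neighboring positions.  Hence

        corr(g[s,r1], g[s,r2])   = rho_t              (any repeat pair)
        corr(g[s,·],  g[s+k,·])  = rho_t * rho_d**k   (adjacent frames)
    """
    eps = (rng.standard_normal((S, R, Z, X)) + 1j * rng.standard_normal((S, R, Z, X))) / np.sqrt(2)
    zeta = (rng.standard_normal((S, Z, X)) + 1j * rng.standard_normal((S, Z, X))) / np.sqrt(2)
    A = np.empty_like(zeta)
    A[0] = zeta[0]
    for s in range(1, S):
        A[s] = rho_d[s] * A[s - 1] + np.sqrt(1 - rho_d[s] ** 2) * zeta[s]
    return np.sqrt(rho_t)[:, None] * A[:, None] + np.sqrt(1 - rho_t)[:, None] * eps


def synthesize_speckle(
    reflectance: np.ndarray,
    flow_mask: np.ndarray,
    spec: PhantomSpec,
    surfaces: LayerSurfaces | None = None,
) -> tuple[OCTVolume, PhantomTruth]:
    """Generate the speckled intensity volume and its ground truth.

    Intensity per voxel is ``reflectance * |g|^2 + noise_floor * |eta|``
    with ``g`` the correlated unit-variance complex field and ``eta``
    standard normal (half-normal noise term).  Per-frame rigid shifts and
    the blink attenuation are applied afterwards.  Deterministic given
    ``spec.seed``.
    """
    if reflectance.shape != flow_mask.shape:
        raise ValueError("reflectance and flow_mask shapes disagree")
    S, Z, X = reflectance.shape
    R = spec.R
    rng = np.random.default_rng(spec.seed)

    if spec.rho_static_adjacent > spec.rho_static_repeat or \
            spec.rho_flow_adjacent > spec.rho_flow_repeat:
        raise ValueError("adjacent-frame correlation cannot exceed repeat correlation "
                         "(adjacent frames decorrelate by time *and* distance)")
    rho_t = np.where(flow_mask, spec.rho_flow_repeat, spec.rho_static_repeat)

    def _dist(adj: float, rep: float) -> float:
        return adj / rep if rep > 0 else 0.0

    rho_d = np.where(flow_mask,
                     _dist(spec.rho_flow_adjacent, spec.rho_flow_repeat),
                     _dist(spec.rho_static_adjacent, spec.rho_static_repeat))
    g = _correlated_complex(rng, rho_t, rho_d, S, R, Z, X)

    intensity = reflectance[:, None] * np.abs(g) ** 2
    if spec.noise_floor > 0:
        intensity = intensity + spec.noise_floor * np.abs(rng.standard_normal(intensity.shape))

    shifts = np.zeros((S, R, 2))
    if spec.motion_sigma_z > 0 or spec.motion_sigma_x > 0:
        shifts[:, :, 0] = rng.normal(0, spec.motion_sigma_z, (S, R))
        shifts[:, :, 1] = rng.normal(0, spec.motion_sigma_x, (S, R))
    if spec.drift_z_per_frame or spec.drift_x_per_frame:
        shifts[:, :, 0] += spec.drift_z_per_frame * np.arange(S)[:, None]
        shifts[:, :, 1] += spec.drift_x_per_frame * np.arange(S)[:, None]
    if np.any(shifts):
        # Motion is synthesized as an exact Fourier phase ramp so the
        # recorded ground-truth displacements are exact; the slight ringing
        # around clipped structures is clipped back to zero.
        from scipy.ndimage import fourier_shift

        for s in range(S):
            for r in range(R):
                if shifts[s, r, 0] or shifts[s, r, 1]:
                    intensity[s, r] = np.fft.ifftn(
                        fourier_shift(np.fft.fftn(intensity[s, r]), shifts[s, r])
                    ).real
        np.clip(intensity, 0, None, out=intensity)

    if spec.blink is not None:
        s0, slen, atten = spec.blink
        intensity[s0 : s0 + slen] *= atten

    if surfaces is None:
        surfaces = rasterize_scene(spec)[2]
    vol = OCTVolume(intensity, dz_um=spec.dz_um, dx_um=spec.dx_um,
                    ds_um=spec.ds_um, bit_max=spec.bit_max)
    truth = PhantomTruth(flow_mask=flow_mask, reflectance=reflectance,
                         surfaces=surfaces, applied_shifts=shifts)
    return vol, truth


def simulate(spec: PhantomSpec) -> tuple[OCTVolume, PhantomTruth]:
    """Rasterize the scene and synthesize speckle in one call."""
    reflectance, flow, surfaces = rasterize_scene(spec)
    return synthesize_speckle(reflectance, flow, spec, surfaces)


def save_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Persist ground truth as an .npz plus surfaces CSV alongside."""
    from .io import surfaces_to_csv

    path = Path(path)
    np.savez(path, flow_mask=truth.flow_mask, reflectance=truth.reflectance,
             applied_shifts=truth.applied_shifts)
    surfaces_to_csv(truth.surfaces, path.with_suffix(".surfaces.csv"))


def spec_to_json(spec: PhantomSpec, path: str | Path) -> None:
    d = asdict(spec)
    Path(path).write_text(json.dumps(d, indent=1, default=list))


def spec_from_json(path: str | Path) -> PhantomSpec:
    d = json.loads(Path(path).read_text())
    d["vessels"] = [Tube(**t) if isinstance(t, dict) else Tube(*t) for t in d.get("vessels", [])]
    d["layer_profile"] = [tuple(t) for t in d["layer_profile"]]
    if d.get("blink") is not None:
        d["blink"] = tuple(d["blink"])
    return PhantomSpec(**d)
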