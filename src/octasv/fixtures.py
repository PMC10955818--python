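"""Deterministic micro-fixtures with hand-computable expected values.

Everything here regenerates bit-identically from code — no binary test
data.  The fixtures deliberately encode the package conventions
(population variance, 4-adjacency perimeter, padded-background border) so
a convention change breaks tests loudly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OCTVolume
from .phantom import PhantomSpec, simulate
from .vessel import VesselMask


@dataclass
class MicroVolume:
    volume: OCTVolume
    expected_sv: dict[int, np.ndarray]  # n_scans -> expected temporal SV [S, Z, X]
    case: str


def make_micro_volume(case: str = "static") -> MicroVolume:
    """Tiny volumes (<= 4x4x8x8) with closed-form temporal speckle variance.

    * ``static``: identical repeats -> SV is zero for every n.
    * ``two_value``: repeats alternate 0 and 2 -> population SV is 1 for
      even n, 8/9 for n = 3 (mean 2/3, deviations (2/3)^2 twice and
      (4/3)^2 once).
    * ``known_flow``: a seeded micro-phantom with one flow column; expected
      SV computed here by the independent two-pass definition.
    """
    if case == "static":
        data = np.full((2, 4, 8, 8), 3.0)
        vol = OCTVolume(data)
        zeros = np.zeros((2, 8, 8))
        return MicroVolume(vol, {2: zeros, 3: zeros, 4: zeros}, case)

    if case == "two_value":
        data = np.zeros((2, 4, 8, 8))
        data[:, 1::2] = 2.0  # repeats 0,2 -> 0; repeats 1,3 -> 2
        vol = OCTVolume(data)
        ones = np.ones((2, 8, 8))
        return MicroVolume(vol, {2: ones, 3: ones * (8.0 / 9.0), 4: ones}, case)

    if case == "known_flow":
        rng = np.random.default_rng(42)
        data = np.empty((2, 4, 8, 8))
        static = rng.exponential(1.0, (2, 8, 8))
        data[:] = static[:, None]  # perfectly correlated repeats
        data[:, :, :, 4] = rng.exponential(1.0, (2, 4, 8))  # decorrelated column
        vol = OCTVolume(data)
        expected = {}
        for n in (2, 3, 4):
            frames = data[:, :n]
            mean = frames.mean(axis=1, keepdims=True)
            expected[n] = ((frames - mean) ** 2).sum(axis=1) / n  # two-pass, population
        return MicroVolume(vol, expected, case)

    raise ValueError(f"unknown case {case!r}")


@dataclass
class MaskFixture:
    name: str
    mask: VesselMask
    vad: float
    vsd: float | None  # None: no closed form asserted (see vsd_bounds)
    vpi: float
    vsd_bounds: tuple[float, float] | None = None


def make_mask_suite() -> list[MaskFixture]:
    """Masks with analytic VAD/VSD/VPI under the package conventions."""
    out: list[MaskFixture] = []

    full = np.ones((10, 10), dtype=bool)
    # padded-background border: perimeter = 2*10 + 2*10 - 4 = 36
    out.append(MaskFixture("full_10x10", VesselMask(full), 1.0, None, 36 / 100.0,
                           vsd_bounds=(0.0, 1.0)))

    empty = np.zeros((10, 10), dtype=bool)
    out.append(MaskFixture("empty_10x10", VesselMask(empty), 0.0, 0.0, 0.0))

    band = np.zeros((10, 10), dtype=bool)
    band[2:7] = True  # 5x10 band
    out.append(MaskFixture("band_5x10_in_10x10", VesselMask(band), 0.5, None,
                           (2 * 10 + 2 * 5 - 4) / 100.0, vsd_bounds=(6 / 100, 10 / 100)))

    square = np.zeros((30, 30), dtype=bool)
    square[10:20, 10:20] = True  # 10x10 solid square, interior placement
    # a solid square thins to a near-point skeleton
    out.append(MaskFixture("square_10x10_in_30x30", VesselMask(square), 100 / 900.0, None,
                           36 / 900.0, vsd_bounds=(1 / 900, 12 / 900)))

    line = np.zeros((20, 20), dtype=bool)
    line[7, 3:17] = True  # unit-width line: skeleton equals the mask
    out.append(MaskFixture("line_1x14_in_20x20", VesselMask(line), 14 / 400.0,
                           14 / 400.0, 14 / 400.0))

    single = np.zeros((5, 5), dtype=bool)
    single[2, 2] = True
    out.append(MaskFixture("single_pixel_5x5", VesselMask(single), 1 / 25.0, 1 / 25.0, 1 / 25.0))

    wide = np.zeros((40, 40), dtype=bool)
    wide[10:15, 5:25] = True  # width-5, length-20 band
    # skeleton ~ a unit line of ~20 px (+-4 for end effects)
    out.append(MaskFixture("band_5x20_in_40x40", VesselMask(wide), 100 / 1600.0, None,
                           (2 * 20 + 2 * 5 - 4) / 1600.0, vsd_bounds=(16 / 1600, 24 / 1600)))
    return out


def miniature_phantom_bundle(seeds=(0, 1, 2), S: int = 8, Z: int = 32, X: int = 32):
    """Three tiny seeded phantoms for integration tests (generated, never stored)."""
    out = []
    for seed in seeds:
        spec = PhantomSpec(S=S, R=4, Z=Z, X=X, seed=seed,
                           layer_profile=[(0, Z, 0.8)], vessels=[])
        out.append(simulate(spec))
    return out
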