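"""Image-quality metrics and the statistical comparison harness.

PSNR, single-scale SSIM and multi-scale SSIM (MS-SSIM) on en-face images,
plus one-way ANOVA for multi-group comparisons and pairwise two-sided
Student's t-tests for post-hoc analysis.

SSIM is computed over *valid* Gaussian windows (11x11, sigma 1.5,
K1 = 0.01, K2 = 0.03), i.e. local means/variances from windows fully
inside the image and the mean taken over that interior — numerically
identical to the common reference implementations that filter with
boundary padding and then crop the filter radius.  The same formulation
is reused (differentiably) as the model's SSIM training loss.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import fftconvolve

from .io import EnFaceImage

#: Standard 5-scale MS-SSIM exponent weights.
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

_WIN_RADIUS = 5  # 11-tap Gaussian, sigma 1.5


def _as_array(img) -> np.ndarray:
    if isinstance(img, EnFaceImage):
        return img.data
    return np.asarray(img, dtype=np.float64)


def gaussian_window(sigma: float = 1.5, radius: int = _WIN_RADIUS) -> np.ndarray:
    x = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def psnr(ref, test, max_val: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(max^2 / MSE).

    Identical images return ``math.inf`` (the sentinel downstream code
    excludes from group statistics).
    """
    a, b = _as_array(ref), _as_array(test)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_val**2 / mse)


def ssim_map(a, b, L: float = 255.0, K1: float = 0.01, K2: float = 0.03,
             sigma: float = 1.5) -> tuple[float, np.ndarray]:
    """Mean SSIM and the per-window SSIM map over valid Gaussian windows."""
    mean, cs_mean, smap = _ssim_terms(_as_array(a), _as_array(b), L, K1, K2, sigma)
    return mean, smap


def _ssim_terms(x: np.ndarray, y: np.ndarray, L: float, K1: float = 0.01,
                K2: float = 0.03, sigma: float = 1.5) -> tuple[float, float, np.ndarray]:
    """(mean SSIM, mean contrast-structure term, SSIM map)."""
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    w = gaussian_window(sigma)
    if min(x.shape) < w.shape[0]:
        raise ValueError(f"image {x.shape} smaller than {w.shape[0]}x{w.shape[0]} window")
    f = lambda im: fftconvolve(im, w, mode="valid")
    mx, my = f(x), f(y)
    sxx = f(x * x) - mx * mx
    syy = f(y * y) - my * my
    sxy = f(x * y) - mx * my
    C1, C2 = (K1 * L) ** 2, (K2 * L) ** 2
    lum = (2 * mx * my + C1) / (mx * mx + my * my + C1)
    cs = (2 * sxy + C2) / (sxx + syy + C2)
    smap = lum * cs
    return float(smap.mean()), float(cs.mean()), smap


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x2 average pooling (trailing odd row/col dropped)."""
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(a, b, L: float = 255.0, weights=MS_SSIM_WEIGHTS) -> float:
    """Multi-scale SSIM: contrast-structure terms on a dyadic pyramid,
    luminance applied at the coarsest scale only, weights as exponents.

    If the image is too small for all requested scales (min dimension must
    stay >= 11 after each halving), the scale count is reduced and the
    leading weights renormalized to sum to one.  Negative mean
    contrast-structure terms are clipped to 0 before exponentiation.
    """
    x, y = _as_array(a), _as_array(b)
    n_scales = len(weights)
    while n_scales > 1 and min(x.shape) // (2 ** (n_scales - 1)) < 2 * _WIN_RADIUS + 1:
        n_scales -= 1
    w = np.asarray(weights[:n_scales], dtype=float)
    w = w / w.sum()

    mcs = []
    for level in range(n_scales):
        mean_ssim, mean_cs, _ = _ssim_terms(x, y, L)
        if level == n_scales - 1:
            mcs.append(mean_ssim)  # luminance included at coarsest scale
        else:
            mcs.append(mean_cs)
            x, y = _downsample2(x), _downsample2(y)
    vals = np.clip(mcs, 0.0, None)
    return float(np.prod(vals ** w))


# ---------------------------------------------------------------------------
# statistics


def one_way_anova(groups: list[list[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA (between/within decomposition); returns (F, p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    res = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(res.statistic), float(res.pvalue)


def pairwise_ttests(groups: list[list[float]], labels: list[str] | None = None) -> pd.DataFrame:
    """Two-sided two-sample Student's t-test (equal variance) for each pair.

    Returns a long table with raw p-values and a Bonferroni-adjusted
    column (the raw values are the primary report).
    """
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    rows = []
    pairs = list(combinations(range(len(groups)), 2))
    for i, j in pairs:
        a = np.asarray(groups[i], dtype=float)
        b = np.asarray(groups[j], dtype=float)
        if np.array_equal(a, b):
            t, p = 0.0, 1.0
        else:
            res = stats.ttest_ind(a, b, equal_var=True)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({"group_a": labels[i], "group_b": labels[j], "t": t, "p": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * len(pairs), 1.0)
    return df


def metric_report(rows: list[dict]) -> pd.DataFrame:
    """Long-format report: (volume_id, layer, method, metric, value)."""
    df = pd.DataFrame(rows, columns=["volume_id", "layer", "method", "metric", "value"])
    return df
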