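"""Organoid size quantification from binary masks and measurement tables.

Areas and volumes are plain foreground-pixel/voxel counts scaled by the
physical pixel/voxel size (mm^2 / mm^3); no segmentation is performed here
— masks are inputs produced upstream. The area-to-volume calibration is an
ordinary least-squares fit of volume against the area of the middle
z-plane, reported with R^2 and an F statistic on (1, n-2) degrees of
freedom so printed fits can be checked via R^2 = F / (F + df2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "LinearFit",
    "mask_area",
    "stack_volume",
    "middle_section_area",
    "fit_linear",
    "gray_matter_ratio",
]


def _as_binary(arr, ndim: int) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != ndim:
        raise ValueError(f"expected a {ndim}-D array, got {a.ndim}-D")
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be binary (0/1)")
        a = a.astype(bool)
    return a


def mask_area(mask, pixel_size: tuple[float, float] = (1.0, 1.0)) -> float:
    """Projected area: foreground pixel count times pixel area (mm^2)."""
    m = _as_binary(mask, ndim=2)
    dy, dx = (float(v) for v in pixel_size)
    if dy <= 0 or dx <= 0:
        raise ValueError("pixel_size must be positive")
    n = int(m.sum())
    if n == 0:
        warnings.warn("empty mask: area is 0")
    return n * dy * dx


def stack_volume(stack, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Volume: foreground voxel count times voxel volume (mm^3)."""
    s = _as_binary(stack, ndim=3)
    dz, dy, dx = (float(v) for v in voxel_size)
    if min(dz, dy, dx) <= 0:
        raise ValueError("voxel_size must be positive")
    n = int(s.sum())
    if n == 0:
        warnings.warn("empty stack: volume is 0")
    return n * dz * dy * dx


def middle_section_area(stack, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> float:
    """Area of the middle z-plane (0-based index floor(n_z / 2))."""
    s = _as_binary(stack, ndim=3)
    if s.shape[0] < 1:
        raise ValueError("stack needs at least one z-plane")
    plane = s[s.shape[0] // 2]
    return mask_area(plane, pixel_size=voxel_size[1:])


@dataclass(frozen=True)
class LinearFit:
    """Simple-regression summary: y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df1: int
    df2: int
    p_value: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fit_linear(x, y) -> LinearFit:
    """Ordinary least-squares fit of y on x with R^2, F(1, n-2) and p.

    For a perfect fit (zero residual) F is infinite and p is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("x is constant: slope is undefined")
    res = sps.linregress(x, y)
    r2 = float(res.rvalue**2)
    df2 = n - 2
    if 1.0 - r2 < 1e-15:
        r2 = 1.0
        f = math.inf
        p = 0.0
    else:
        f = r2 / (1.0 - r2) * df2
        p = float(sps.f.sf(f, 1, df2))
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        f_stat=float(f),
        df1=1,
        df2=df2,
        p_value=p,
    )


def gray_matter_ratio(gm_voxels: float, wm_voxels: float) -> float:
    """Gray matter over total brain volume, GM / (GM + WM).

    Voxel counts and tissue volumes are interchangeable here: the voxel
    volume cancels.
    """
    if gm_voxels < 0 or wm_voxels < 0:
        raise ValueError("voxel counts must be >= 0")
    total = gm_voxels + wm_voxels
    if total == 0:
        raise ValueError("GM + WM is zero: ratio undefined")
    return float(gm_voxels) / float(total)
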