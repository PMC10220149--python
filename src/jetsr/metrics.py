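"""Velocity-field evaluation: relative speed error, RMSE, SSIM, agreement.

The headline metric is the arctangent relative speed error: the mean over
fluid voxels of ``arctan(||v' - v|| / (||v|| + eps))`` with ``eps = 1e-4``.
The arctangent bounds the penalty for errors at near-zero true speeds by
pi/2, which a plain relative error would blow up on.  RMSE and SSIM are
reported per Cartesian velocity component, and SR/HR agreement is summarised
by ordinary least squares and Bland-Altman bias / limits of agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.metrics import structural_similarity

__all__ = [
    "EvalReport",
    "relative_speed_error",
    "rmse_components",
    "ssim_components",
    "regression_bland_altman",
    "evaluate_volume",
    "EPSILON",
]

EPSILON = 1e-4


def _check(pred, target, mask=None):
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ValueError("pred and target shapes differ")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != pred.shape[:-1]:
            raise ValueError("mask shape inconsistent with fields")
    return pred, target, mask


def relative_speed_error(pred, target, mask, epsilon: float = EPSILON) -> float:
    """Mean arctan relative speed error over fluid voxels, radians.

    Bounded in [0, pi/2); 0 iff the fields agree exactly on the fluid.
    """
    pred, target, mask = _check(pred, target, mask)
    if not mask.any():
        raise ValueError("empty fluid mask")
    diff = np.linalg.norm((pred - target)[mask], axis=-1)
    speed = np.linalg.norm(target[mask], axis=-1)
    return float(np.mean(np.arctan(diff / (speed + epsilon))))


def rmse_components(pred, target, mask) -> np.ndarray:
    """Per-component RMSE over fluid voxels, m/s: (rmse_x, rmse_y, rmse_z)."""
    pred, target, mask = _check(pred, target, mask)
    if not mask.any():
        raise ValueError("empty fluid mask")
    d = (pred - target)[mask]
    return np.sqrt((d ** 2).mean(axis=0))


def ssim_components(pred, target) -> np.ndarray:
    """Per-component 3D SSIM (Wang et al. settings).

    Gaussian 11-point window with sigma 1.5, population statistics, data
    range taken from the target component.  Volumes that are constant and
    identical score 1 by convention.
    """
    pred, target, _ = _check(pred, target)
    win = min(11, *target.shape[:-1])
    if win % 2 == 0:
        win -= 1
    out = []
    for j in range(pred.shape[-1]):
        p, t = pred[..., j], target[..., j]
        rng = float(t.max() - t.min())
        if rng == 0.0:
            out.append(1.0 if np.array_equal(p, t) else 0.0)
            continue
        out.append(structural_similarity(
            t, p, data_range=rng, gaussian_weights=True, sigma=1.5,
            win_size=win, use_sample_covariance=False,
        ))
    return np.asarray(out)


def regression_bland_altman(pred, target, mask=None):
    """OLS of SR on HR voxel values plus Bland-Altman agreement.

    Returns ``(slope, offset, ba_bias, (loa_lo, loa_hi))`` pooled over the
    selected voxels and components; ``loa = bias +/- 1.96 sd(SR - HR)``.
    """
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        pred, target = pred[mask], target[mask]
    x = target.ravel()
    y = pred.ravel()
    if x.size < 2:
        raise ValueError("need at least 2 points for regression")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate HR values: zero variance")
    fit = stats.linregress(x, y)
    d = y - x
    bias = float(d.mean())
    half = 1.96 * float(d.std())
    return float(fit.slope), float(fit.intercept), bias, (bias - half, bias + half)


@dataclass(frozen=True)
class EvalReport:
    """Per-volume evaluation summary.

    ``re`` is in radians; ``rmse`` m/s and ``ssim`` dimensionless, both per
    velocity component (x, y, z); regression/Bland-Altman are pooled over
    components within ``region`` ("all_fluid" or "constriction").
    """

    re: float
    rmse: tuple[float, float, float]
    ssim: tuple[float, float, float]
    slope: float
    offset: float
    ba_bias: float
    ba_loa: tuple[float, float]
    region: str = "all_fluid"

    def as_dict(self) -> dict:
        return {
            "re": self.re,
            "rmse_x": self.rmse[0], "rmse_y": self.rmse[1],
            "rmse_z": self.rmse[2],
            "ssim_x": self.ssim[0], "ssim_y": self.ssim[1],
            "ssim_z": self.ssim[2],
            "slope": self.slope, "offset": self.offset,
            "ba_bias": self.ba_bias,
            "ba_loa_lo": self.ba_loa[0], "ba_loa_hi": self.ba_loa[1],
            "region": self.region,
        }


def evaluate_volume(
    pred: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray,
    region: str = "all_fluid",
    axial_slab: tuple[int, int] | None = None,
) -> EvalReport:
    """Full evaluation of an SR volume against its HR reference.

    ``region="constriction"`` restricts RE/RMSE/regression to the fluid
    voxels whose axial (x) index lies in ``axial_slab``; SSIM is always
    computed on the full volumes (it is windowed, not masked).
    """
    pred, target, mask = _check(pred, target, mask)
    sel = mask
    if region == "constriction":
        if axial_slab is None:
            raise ValueError("constriction region requires axial_slab")
        sel = np.zeros_like(mask)
        sel[axial_slab[0]:axial_slab[1]] = mask[axial_slab[0]:axial_slab[1]]
    elif region != "all_fluid":
        raise ValueError(f"unknown region {region!r}")
    slope, offset, bias, loa = regression_bland_altman(pred, target, sel)
    return EvalReport(
        re=relative_speed_error(pred, target, sel),
        rmse=tuple(rmse_components(pred, target, sel)),
        ssim=tuple(ssim_components(pred, target)),
        slope=slope, offset=offset, ba_bias=bias, ba_loa=loa, region=region,
    )
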