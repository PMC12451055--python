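"""DTI-ALPS: diffusivity analysis along the perivascular space.

The ALPS index is a glymphatic-function proxy computed from diffusion
tensor maps in template space.  At the level of the lateral-ventricle
body, projection fibers (superior corona radiata, running
inferior-superior) and association fibers (superior longitudinal
fasciculus, running anterior-posterior) both lie perpendicular to the
left-right oriented medullary veins; water diffusivity along x in these
regions is therefore dominated by the perivascular space.  The index is

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

per hemisphere, and the "mean" index is the average of the left and
right hemispheric ratios.  An index near 1 indicates no preferential
diffusion along the perivascular axis; healthy adults typically sit
around 1.3.

This module provides the log-linear diffusion-tensor fit, spherical ROI
placement at the four published template coordinates, and the index
computation.  Inputs are assumed to already be in template space
(spatial normalization is upstream preprocessing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# 0-based voxel coordinates of the four ROI centers on the 1 mm
# JHU-ICBM-FA template (182 x 218 x 182).  The printed left/right pairs
# are not exactly mirror-symmetric; they are used as printed.
TEMPLATE_SHAPE = (182, 218, 182)
TEMPLATE_VOXEL_MM = 1.0
DEFAULT_ROI_CENTERS: dict[str, tuple[int, int, int]] = {
    "L-SCR": (116, 110, 99),
    "R-SCR": (64, 110, 99),
    "L-SLF": (128, 110, 99),
    "R-SLF": (51, 110, 99),
}
DEFAULT_ROI_DIAMETER_MM = 5.0


@dataclass
class TensorVolume:
    """Per-voxel axis diffusivities and FA on one template grid.

    Diffusivities are in mm^2/s.  Voxels excluded by the fit (any
    non-positive signal) are NaN in all maps and recorded in ``qc``.
    """

    dxx: np.ndarray
    dyy: np.ndarray
    dzz: np.ndarray
    fa: np.ndarray
    voxel_size: float = 1.0
    template: str = "JHU-ICBM-FA"
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.dxx.shape == self.dyy.shape == self.dzz.shape == self.fa.shape):
            raise ValueError("all tensor maps must share one grid")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.dxx.shape


@dataclass
class AlpsRois:
    """Four spherical ROIs: left/right SCR (projection) and SLF (association)."""

    centers: dict[str, tuple[int, int, int]]
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM

    def __post_init__(self) -> None:
        required = {"L-SCR", "R-SCR", "L-SLF", "R-SLF"}
        if set(self.centers) != required:
            raise ValueError(f"ROI labels must be exactly {sorted(required)}")
        if self.diameter_mm < 0:
            raise ValueError("diameter must be non-negative")


@dataclass
class AlpsResult:
    alps_left: float
    alps_right: float
    alps_mean: float
    #: mean diffusivity per ROI term, keys like "L-SCR:dxx", mm^2/s
    roi_means: dict[str, float] = field(default_factory=dict)


def default_rois(
    grid_shape: tuple[int, int, int] = TEMPLATE_SHAPE,
    voxel_size: float = TEMPLATE_VOXEL_MM,
    diameter_mm: float = DEFAULT_ROI_DIAMETER_MM,
) -> AlpsRois:
    """Published ROI centers, rescaled from the 1 mm template grid.

    Rescaled centers are floored to voxel indices.  A ValueError is
    raised if a center falls outside ``grid_shape``.
    """
    scale = TEMPLATE_VOXEL_MM / voxel_size
    centers = {}
    for label, c in DEFAULT_ROI_CENTERS.items():
        cc = tuple(int(np.floor(ci * scale)) for ci in c)
        if any(x < 0 or x >= s for x, s in zip(cc, grid_shape)):
            raise ValueError(f"scaled ROI center {label}={cc} outside grid {grid_shape}")
        centers[label] = cc
    return AlpsRois(centers=centers, diameter_mm=diameter_mm)


# --------------------------------------------------------------------------
# diffusion tensor fit
# --------------------------------------------------------------------------

def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx * gx,
            -bvals * gy * gy,
            -bvals * gz * gz,
            -2.0 * bvals * gx * gy,
            -2.0 * bvals * gx * gz,
            -2.0 * bvals * gy * gz,
        ]
    )


def fit_diffusion_tensor(
    dwi: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    mask: np.ndarray | None = None,
    voxel_size: float = 1.0,
) -> TensorVolume:
    """Ordinary log-linear least-squares tensor fit.

    Solves ln S = ln S0 - b g^T D g per voxel for the six unique tensor
    elements plus ln S0.  Voxels with any non-positive signal are
    excluded (NaN) and counted in ``qc["n_excluded"]``; the log is
    undefined there and clamping would bias the fit.

    Parameters
    ----------
    dwi : (x, y, z, v) signal array.
    bvals : (v,) b-values in s/mm^2; at least one must be ~0.
    bvecs : (v, 3) gradient directions, unit norm for b > 0.
    mask : optional boolean volume restricting the fit (e.g. ROI voxels
        only); outside voxels are NaN and not counted as excluded.
    """
    dwi = np.asarray(dwi, dtype=np.float64)
    bvals = np.asarray(bvals, dtype=np.float64)
    bvecs = np.asarray(bvecs, dtype=np.float64)
    if dwi.ndim != 4:
        raise ValueError("dwi must be 4D (x, y, z, volumes)")
    if bvals.shape[0] != dwi.shape[3] or bvecs.shape != (dwi.shape[3], 3):
        raise ValueError("bvals/bvecs do not match the number of volumes")
    b0 = bvals < 50.0
    if not b0.any():
        raise ValueError("need at least one b~0 volume")
    nz = ~b0
    dirs = bvecs[nz]
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("non-zero-b gradient directions must be unit norm")
    n_distinct = np.unique(np.round(np.abs(dirs), 6), axis=0).shape[0]
    if n_distinct < 6:
        raise ValueError(
            f"tensor fit needs >= 6 distinct non-zero directions, got {n_distinct}"
        )

    shape = dwi.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape:
            raise ValueError("mask grid does not match dwi grid")

    signals = dwi[mask]  # (nvox, v)
    valid = np.all(signals > 0.0, axis=1)
    n_excluded = int((~valid).sum())

    coef = np.full((signals.shape[0], 7), np.nan)
    if valid.any():
        X = _design_matrix(bvals, bvecs)
        logs = np.log(signals[valid])
        coef[valid] = np.linalg.lstsq(X, logs.T, rcond=None)[0].T

    dxx_f, dyy_f, dzz_f = coef[:, 1], coef[:, 2], coef[:, 3]
    dxy_f, dxz_f, dyz_f = coef[:, 4], coef[:, 5], coef[:, 6]

    # FA from tensor eigenvalues
    fa_f = np.full(signals.shape[0], np.nan)
    if valid.any():
        D = np.empty((int(valid.sum()), 3, 3))
        D[:, 0, 0] = dxx_f[valid]
        D[:, 1, 1] = dyy_f[valid]
        D[:, 2, 2] = dzz_f[valid]
        D[:, 0, 1] = D[:, 1, 0] = dxy_f[valid]
        D[:, 0, 2] = D[:, 2, 0] = dxz_f[valid]
        D[:, 1, 2] = D[:, 2, 1] = dyz_f[valid]
        lam = np.linalg.eigvalsh(D)
        fa_f[valid] = fractional_anisotropy(lam)

    def unflatten(flat: np.ndarray) -> np.ndarray:
        vol = np.full(shape, np.nan)
        vol[mask] = flat
        return vol

    qc = {"n_excluded": n_excluded, "n_fit": int(valid.sum())}
    return TensorVolume(
        dxx=unflatten(dxx_f),
        dyy=unflatten(dyy_f),
        dzz=unflatten(dzz_f),
        fa=unflatten(fa_f),
        voxel_size=voxel_size,
        qc=qc,
    )


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from tensor eigenvalues (last axis of length 3).

    FA = sqrt(1/2) * sqrt(sum of squared pairwise eigenvalue
    differences) / sqrt(sum of squared eigenvalues); 0 for a degenerate
    all-zero tensor.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l1 - l3) ** 2
    den = l1**2 + l2**2 + l3**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(0.5) * np.sqrt(num) / np.sqrt(den)
    return np.where(den > 0, fa, 0.0)


# --------------------------------------------------------------------------
# ROI placement
# --------------------------------------------------------------------------

def make_sphere_mask(
    center: tuple[int, int, int],
    diameter_mm: float,
    grid_shape: tuple[int, int, int],
    voxel_size: float = 1.0,
) -> np.ndarray:
    """Boolean sphere: voxel centers within ``diameter_mm / 2`` of ``center``.

    Membership is by center-to-center Euclidean distance <= radius
    (inclusive), which makes the mask deterministic across grid
    resolutions.  Diameter 0 degenerates to the single center voxel.
    A sphere clipped by the grid boundary triggers a warning and is
    truncated.
    """
    center = tuple(int(c) for c in center)
    if any(c < 0 or c >= s for c, s in zip(center, grid_shape)):
        raise ValueError(f"sphere center {center} outside grid {grid_shape}")
    radius = diameter_mm / 2.0
    rv = int(np.floor(radius / voxel_size))  # voxel-offset search half-width
    lo = [max(0, c - rv) for c in center]
    hi = [min(s, c + rv + 1) for c, s in zip(center, grid_shape)]
    if any(c - rv < 0 or c + rv + 1 > s for c, s in zip(center, grid_shape)):
        warnings.warn(
            f"sphere at {center} clipped by grid boundary; truncating",
            stacklevel=2,
        )
    mask = np.zeros(grid_shape, dtype=bool)
    xs = np.arange(lo[0], hi[0])
    ys = np.arange(lo[1], hi[1])
    zs = np.arange(lo[2], hi[2])
    dx, dy, dz = np.meshgrid(
        (xs - center[0]) * voxel_size,
        (ys - center[1]) * voxel_size,
        (zs - center[2]) * voxel_size,
        indexing="ij",
    )
    inside = dx**2 + dy**2 + dz**2 <= radius**2
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return mask


def roi_masks(rois: AlpsRois, grid_shape, voxel_size: float = 1.0) -> dict[str, np.ndarray]:
    return {
        label: make_sphere_mask(center, rois.diameter_mm, grid_shape, voxel_size)
        for label, center in rois.centers.items()
    }


# --------------------------------------------------------------------------
# ALPS index
# --------------------------------------------------------------------------

def compute_alps_index(tv: TensorVolume, rois: AlpsRois | None = None) -> AlpsResult:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc) per side.

    Each term is the mean diffusivity over the voxels of one spherical
    ROI (NaN voxels excluded); the headline "mean" index is the average
    of the two hemispheric ratios.
    """
    if rois is None:
        rois = default_rois(tv.shape, tv.voxel_size)
    masks = roi_masks(rois, tv.shape, tv.voxel_size)

    def roi_mean(volume: np.ndarray, label: str) -> float:
        vals = volume[masks[label]]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"ROI {label} has no valid voxels")
        return float(vals.mean())

    roi_means: dict[str, float] = {}
    per_side = {}
    for side in ("L", "R"):
        dxx_proj = roi_mean(tv.dxx, f"{side}-SCR")
        dxx_assoc = roi_mean(tv.dxx, f"{side}-SLF")
        dyy_proj = roi_mean(tv.dyy, f"{side}-SCR")
        dzz_assoc = roi_mean(tv.dzz, f"{side}-SLF")
        roi_means[f"{side}-SCR:dxx"] = dxx_proj
        roi_means[f"{side}-SLF:dxx"] = dxx_assoc
        roi_means[f"{side}-SCR:dyy"] = dyy_proj
        roi_means[f"{side}-SLF:dzz"] = dzz_assoc
        denom = 0.5 * (dyy_proj + dzz_assoc)
        if denom == 0:
            raise ValueError(
                f"zero ALPS denominator on side {side}: "
                f"Dyy_proj={dyy_proj}, Dzz_assoc={dzz_assoc}"
            )
        per_side[side] = 0.5 * (dxx_proj + dxx_assoc) / denom

    return AlpsResult(
        alps_left=per_side["L"],
        alps_right=per_side["R"],
        alps_mean=0.5 * (per_side["L"] + per_side["R"]),
        roi_means=roi_means,
    )
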