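"""Synthetic ground-truth data: DWI phantoms, coupled BOLD/CSF series, cohorts.

No subject-level data are deposited for this kind of study, so every
downstream stage is exercised on generators with known ground truth:

* :func:`generate_dwi_phantom` builds a diffusion-weighted volume whose
  signal follows the mono-exponential tensor model
  ``S = S0 * exp(-b g^T D g)`` exactly (before optional noise), with
  anisotropic diagonal tensors in boxes around the four ALPS ROI
  centers and an isotropic background — so the true ALPS index is a
  closed-form ratio of the prescribed diffusivities.
* :func:`generate_coupled_series` builds a gBOLD/CSF pair in which the
  CSF series is a sign-flipped, amplitude-scaled copy of the gBOLD
  series delayed by a prescribed number of samples, plus independent
  noise — the minimal model reproducing the observed lagged
  anti-correlation (no hemodynamic model is implied).
* :func:`generate_cohort` draws subject tables whose per-group means/SDs
  match the printed study summaries, with marker-HAMA correlations
  induced through a latent Gaussian block within the PD groups.

All draws come from one seeded generator per call; the seed is recorded
in the output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables as _tables
from .alps import (
    DEFAULT_ROI_CENTERS,
    TEMPLATE_VOXEL_MM,
    TensorVolume,
    fractional_anisotropy,
)
from .coupling import SignalPair, standardize

# ---------------------------------------------------------------------------
# DWI phantom
# ---------------------------------------------------------------------------

#: Default per-region diagonal tensor eigenvalues, mm^2/s, aligned to x/y/z.
#: SCR fibers run inferior-superior (largest Dzz), SLF fibers
#: anterior-posterior (largest Dyy); Dxx is elevated above the true
#: radial diffusivity by the perivascular contribution.  The implied
#: ALPS index is mean(0.55, 0.50)/mean(0.40, 0.40) = 1.3125, in the
#: healthy-adult range.
DEFAULT_REGION_TENSORS: dict[str, tuple[float, float, float]] = {
    "L-SCR": (0.55e-3, 0.40e-3, 1.60e-3),
    "R-SCR": (0.55e-3, 0.40e-3, 1.60e-3),
    "L-SLF": (0.50e-3, 1.60e-3, 0.40e-3),
    "R-SLF": (0.50e-3, 1.60e-3, 0.40e-3),
}


@dataclass
class PhantomSpec:
    """Configuration of a DWI phantom on a template-like grid.

    The default grid is the half-resolution template (91 x 109 x 91 at
    2 mm); regions are axis-aligned boxes centered on the published ROI
    centers rescaled to the grid, each wide enough to cover its 5 mm
    ROI sphere.
    """

    grid_shape: tuple[int, int, int] = (91, 109, 91)
    voxel_size: float = 2.0
    region_tensors: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_TENSORS)
    )
    #: label -> (center voxel triplet, half-extent in voxels); None derives
    #: boxes from the ROI centers.
    region_defs: dict[str, tuple[tuple[int, int, int], int]] | None = None
    background_diffusivity: float = 0.7e-3
    b_value: float = 1000.0
    n_directions: int = 64
    n_b0: int = 1
    s0: float = 1000.0
    noise_sd: float = 0.0
    rician: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.region_tensors = {k: tuple(v) for k, v in self.region_tensors.items()}
        if self.region_defs is not None:
            self.region_defs = {
                k: (tuple(c), int(h)) for k, (c, h) in self.region_defs.items()
            }
        if self.n_directions < 6:
            raise ValueError("tensor model needs >= 6 diffusion directions")
        if self.background_diffusivity <= 0 or any(
            d <= 0 for t in self.region_tensors.values() for d in t
        ):
            raise ValueError("all diffusivities must be positive")
        if self.region_defs is None:
            self.region_defs = self._default_region_defs()
        for label, (center, half) in self.region_defs.items():
            lo = [c - half for c in center]
            hi = [c + half for c in center]
            if any(l < 0 for l in lo) or any(
                h >= s for h, s in zip(hi, self.grid_shape)
            ):
                raise ValueError(f"region {label} extends outside the grid")
        if set(self.region_defs) != set(self.region_tensors):
            raise ValueError("region_defs and region_tensors labels must match")

    def _default_region_defs(self):
        scale = TEMPLATE_VOXEL_MM / self.voxel_size
        half = int(np.ceil(2.5 / self.voxel_size)) + 1  # covers a 5 mm sphere
        defs = {}
        for label, c in DEFAULT_ROI_CENTERS.items():
            center = tuple(int(np.floor(ci * scale)) for ci in c)
            defs[label] = (center, half)
        return defs

    def true_alps(self) -> dict[str, float] | None:
        """Hand-computable ground-truth ALPS indices from the region tensors.

        None when the phantom does not use the four standard ROI labels.
        """
        if set(self.region_tensors) != set(DEFAULT_REGION_TENSORS):
            return None
        out = {}
        for side in ("L", "R"):
            dxx_p, dyy_p, _ = self.region_tensors[f"{side}-SCR"]
            dxx_a, _, dzz_a = self.region_tensors[f"{side}-SLF"]
            out[side] = 0.5 * (dxx_p + dxx_a) / (0.5 * (dyy_p + dzz_a))
        out["mean"] = 0.5 * (out["L"] + out["R"])
        return out


@dataclass
class PhantomData:
    dwi: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    truth: TensorVolume
    labels: np.ndarray  # per-voxel region id (0 = background)
    meta: dict = field(default_factory=dict)


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic)."""
    k = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def generate_dwi_phantom(spec: PhantomSpec) -> PhantomData:
    """Simulate DWI volumes from diagonal tensors; returns ground truth too."""
    rng = np.random.default_rng(spec.seed)
    bvecs = np.vstack([np.zeros((spec.n_b0, 3)), fibonacci_directions(spec.n_directions)])
    bvals = np.concatenate(
        [np.zeros(spec.n_b0), np.full(spec.n_directions, spec.b_value)]
    )

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    region_order = sorted(spec.region_defs)
    for rid, label in enumerate(region_order, start=1):
        (cx, cy, cz), half = spec.region_defs[label]
        labels[
            cx - half : cx + half + 1,
            cy - half : cy + half + 1,
            cz - half : cz + half + 1,
        ] = rid

    bg = spec.background_diffusivity
    tensors = {0: (bg, bg, bg)}
    for rid, label in enumerate(region_order, start=1):
        tensors[rid] = spec.region_tensors[label]

    nvol = bvals.size
    dwi = np.empty(spec.grid_shape + (nvol,), dtype=np.float64)
    dxx = np.empty(spec.grid_shape)
    dyy = np.empty(spec.grid_shape)
    dzz = np.empty(spec.grid_shape)
    g2 = bvecs**2
    for rid, (tx, ty, tz) in tensors.items():
        # diagonal tensor: g^T D g = gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
        sig = spec.s0 * np.exp(-bvals * (g2[:, 0] * tx + g2[:, 1] * ty + g2[:, 2] * tz))
        sel = labels == rid
        dwi[sel] = sig
        dxx[sel], dyy[sel], dzz[sel] = tx, ty, tz

    if spec.noise_sd > 0:
        if spec.rician:
            # Gaussian noise on two quadrature channels -> Rician magnitude
            dwi = np.sqrt(
                (dwi + rng.normal(0.0, spec.noise_sd, dwi.shape)) ** 2
                + rng.normal(0.0, spec.noise_sd, dwi.shape) ** 2
            )
        else:
            dwi = dwi + rng.normal(0.0, spec.noise_sd, dwi.shape)

    lam = np.stack([dxx, dyy, dzz], axis=-1)
    truth = TensorVolume(
        dxx=dxx,
        dyy=dyy,
        dzz=dzz,
        fa=fractional_anisotropy(lam),
        voxel_size=spec.voxel_size,
        qc={"synthetic": True},
    )
    return PhantomData(
        dwi=dwi,
        bvals=bvals,
        bvecs=bvecs,
        truth=truth,
        labels=labels,
        meta={"seed": spec.seed, "true_alps": spec.true_alps()},
    )


# ---------------------------------------------------------------------------
# coupled BOLD/CSF series
# ---------------------------------------------------------------------------

@dataclass
class CoupledSeriesSpec:
    """Delay-and-scale coupling model for one subject's gBOLD/CSF pair.

    The latent gBOLD process is temporally smoothed unit-variance
    Gaussian noise; the CSF series is ``sign * amplitude`` times the
    latent process delayed by ``lag`` samples, completed to unit
    variance with independent smoothed noise, and both observed series
    receive additive white measurement noise of SD ``noise_sd``.  With
    amplitude a and noise_sd s the expected correlation at lag -lag is
    ``sign * a / (1 + s^2)``.
    """

    n_timepoints: int = 300
    tr: float = 1.5
    lag: int = 3
    amplitude: float = 0.4
    sign: int = -1
    smooth_fwhm: float = 6.0  # s; width of the latent process autocorrelation
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= abs(self.amplitude) <= 1.0:
            raise ValueError("|amplitude| must be <= 1")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.lag >= self.n_timepoints:
            raise ValueError("lag must be smaller than the series length")
        if self.n_timepoints <= 10 + 2 * max(self.lag, 5):
            raise ValueError("series too short for the requested lag range")

    def expected_strength(self) -> float:
        """Analytic |correlation| at the coupling lag (attenuation by noise)."""
        return abs(self.amplitude) / (1.0 + self.noise_sd**2)


def _smooth_noise(rng: np.random.Generator, n: int, fwhm_samples: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter1d

    x = rng.standard_normal(n)
    if fwhm_samples > 0:
        sigma = fwhm_samples / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        x = gaussian_filter1d(x, sigma, mode="wrap")
    return standardize(x)


def generate_coupled_series(spec: CoupledSeriesSpec) -> SignalPair:
    """Draw one gBOLD/CSF pair with the prescribed lagged coupling."""
    rng = np.random.default_rng(spec.seed)
    n, lag = spec.n_timepoints, spec.lag
    fwhm_samples = spec.smooth_fwhm / spec.tr
    latent = _smooth_noise(rng, n + lag, fwhm_samples)
    gbold = latent[lag:].copy()  # gbold(t) = latent(t + lag)
    a = spec.amplitude
    csf = spec.sign * (
        a * latent[:n] + np.sqrt(max(0.0, 1.0 - a * a)) * _smooth_noise(rng, n, fwhm_samples)
    )
    if spec.noise_sd > 0:
        gbold = gbold + rng.normal(0.0, spec.noise_sd, n)
        csf = csf + rng.normal(0.0, spec.noise_sd, n)
    return SignalPair(gbold=gbold, csf=csf, tr=spec.tr)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Latent correlation defaults for the marker block within PD groups.
DEFAULT_ALPS_HAMA_R = -0.28
DEFAULT_COUPLING_HAMA_R = -0.317
DEFAULT_ALPS_LR_R = 0.70
DEFAULT_ALPS_COUPLING_R = 0.35


@dataclass
class CohortSpec:
    """Cohort generator configuration; defaults mirror the printed tables.

    ``variable_params`` maps variable -> group -> (mean, sd); groups
    missing a variable get NaN (e.g. disease duration for controls).
    Marker-HAMA correlations are induced within each PD group through a
    latent Gaussian block; controls get independent draws.
    """

    group_sizes: dict[str, int]
    variable_params: dict[str, dict[str, tuple[float, float]]]
    sex_male_frac: dict[str, float]
    alps_hama_r: float = DEFAULT_ALPS_HAMA_R
    coupling_hama_r: float = DEFAULT_COUPLING_HAMA_R
    alps_lr_r: float = DEFAULT_ALPS_LR_R
    alps_coupling_r: float = DEFAULT_ALPS_COUPLING_R
    label_by_hama: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g}: n must be >= 2")
        for var, per_group in self.variable_params.items():
            for g, (_, sd) in per_group.items():
                if sd <= 0:
                    raise ValueError(f"{var}/{g}: sd must be positive")
        for r in (self.alps_hama_r, self.coupling_hama_r, self.alps_lr_r, self.alps_coupling_r):
            if not abs(r) < 1:
                raise ValueError("target correlations must satisfy |r| < 1")

    @classmethod
    def from_table(
        cls, table: str | dict = "table1", n_multiplier: int = 1, **kwargs
    ) -> "CohortSpec":
        """Build a spec from a bundled summary table (optionally scaled n)."""
        tab = _tables.load_table(table) if isinstance(table, str) else table
        sizes = {g: n * n_multiplier for g, n in tab["groups"].items()}
        params = {
            var: {g: tuple(ms) for g, ms in per_group.items()}
            for var, per_group in tab["variables"].items()
        }
        sex = {g: m / (m + f) for g, (m, f) in tab["sex_mf"].items()}
        return cls(group_sizes=sizes, variable_params=params, sex_male_frac=sex, **kwargs)


def _latent_block_corr(spec: CohortSpec, with_coupling: bool) -> np.ndarray:
    """Correlation matrix of (hama, alps_L, alps_R[, coupling]) latents."""
    rah, rlr = spec.alps_hama_r, spec.alps_lr_r
    if with_coupling:
        rch, rac = spec.coupling_hama_r, spec.alps_coupling_r
        corr = np.array(
            [
                [1.0, rah, rah, rch],
                [rah, 1.0, rlr, rac],
                [rah, rlr, 1.0, rac],
                [rch, rac, rac, 1.0],
            ]
        )
    else:
        corr = np.array([[1.0, rah, rah], [rah, 1.0, rlr], [rah, rlr, 1.0]])
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("infeasible correlation structure (not PSD)") from err
    return corr


MARKER_VARS = ("alps_left", "alps_right", "coupling")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a subject table; marginal means/SDs follow ``variable_params``.

    Columns: subject_id, group, sex_male plus every configured variable;
    alps_mean is derived as (alps_left + alps_right)/2 when both
    hemispheric indices are generated (its configured marginal is then
    implied, not drawn).  If ``label_by_hama`` is set, PD subjects are
    re-assigned to PD-A / PD-NA by the HAMA >= 14 rule after drawing.
    """
    rng = np.random.default_rng(spec.seed)
    with_coupling = "coupling" in spec.variable_params
    has_lr = {"alps_left", "alps_right"} <= set(spec.variable_params)
    latent_vars = ["hama", "alps_left", "alps_right"] + (
        ["coupling"] if with_coupling else []
    )

    rows = []
    sid = 0
    for group, n in spec.group_sizes.items():
        corr = (
            _latent_block_corr(spec, with_coupling)
            if group in _tables.PD_GROUPS
            else np.eye(len(latent_vars))
        )
        L = np.linalg.cholesky(corr)
        z_block = rng.standard_normal((n, len(latent_vars))) @ L.T
        z_by_var = dict(zip(latent_vars, z_block.T))

        data: dict[str, np.ndarray] = {}
        for var, per_group in spec.variable_params.items():
            if var == "alps_mean" and has_lr:
                continue  # derived below
            if group not in per_group:
                data[var] = np.full(n, np.nan)
                continue
            mean, sd = per_group[group]
            z = z_by_var.get(var)
            if z is None:
                z = rng.standard_normal(n)
            data[var] = mean + sd * z
        if has_lr:
            data["alps_mean"] = 0.5 * (data["alps_left"] + data["alps_right"])

        sex = (rng.random(n) < spec.sex_male_frac.get(group, 0.5)).astype(int)
        for k in range(n):
            rows.append(
                {"subject_id": f"sub-{sid + k:04d}", "group": group, "sex_male": sex[k]}
                | {var: data[var][k] for var in data}
            )
        sid += n

    df = pd.DataFrame(rows)
    if spec.label_by_hama:
        pd_mask = df["group"].isin(_tables.PD_GROUPS)
        df.loc[pd_mask, "group"] = np.where(
            df.loc[pd_mask, "hama"] >= _tables.HAMA_ANXIETY_CUTOFF, "PD-A", "PD-NA"
        )
    df.attrs["seed"] = spec.seed
    return df
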