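"""File IO: NIfTI volumes, FSL-style bval/bvec text files, cohort TSVs."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(volume: np.ndarray, path: str | Path, voxel_size: float = 1.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Return (data, isotropic voxel size in mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return np.asarray(img.get_fdata()), float(zooms[0])


def save_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, prefix: str | Path) -> None:
    """FSL dialect: one space-separated row of b-values; bvecs as 3 rows."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), np.asarray(bvals)[None, :], fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), np.asarray(bvecs).T, fmt="%.8f")


def load_bvals_bvecs(bval_path: str | Path, bvec_path: str | Path):
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvec shape does not match bval count")
    return bvals, bvecs


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
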