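"""NIfTI round-trip for lesion decays.

Synthetic lesions are bags of voxels; for interoperability each lesion can
be written as a toy-layout 4-D NIfTI volume (nx × ny × 1 × n_b, voxels laid
out row-major inside a rectangle), an FSL-style single-line ``.bval``
sidecar, and a binary ROI mask on the same grid. ``import_external_case``
reads the same trio (or any user-provided data shaped like it) back into
per-voxel decays.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .schemes import BValueScheme

__all__ = ["write_lesion_nifti", "import_external_case"]

_MIN_VOXELS = 3


def write_lesion_nifti(signals: np.ndarray, scheme: BValueScheme,
                       out_dir, stem: str) -> dict[str, Path]:
    """Write (n_voxels, n_b) signals as DWI + mask NIfTI and .bval sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    S = np.asarray(signals, dtype=float)
    n_vox, n_b = S.shape
    if n_b != len(scheme):
        raise ValueError("signal columns must match the b-value scheme")
    nx = int(np.ceil(np.sqrt(n_vox)))
    ny = int(np.ceil(n_vox / nx))
    vol = np.zeros((nx, ny, 1, n_b))
    mask = np.zeros((nx, ny, 1), dtype=np.uint8)
    flat_vol = vol.reshape(nx * ny, n_b)
    flat_vol[:n_vox] = S
    mask.reshape(-1)[:n_vox] = 1
    affine = np.eye(4)
    dwi_path = out_dir / f"{stem}_dwi.nii.gz"
    mask_path = out_dir / f"{stem}_mask.nii.gz"
    bval_path = out_dir / f"{stem}.bval"
    nib.save(nib.Nifti1Image(vol, affine), dwi_path)
    nib.save(nib.Nifti1Image(mask, affine), mask_path)
    bval_path.write_text(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")
    return {"dwi": dwi_path, "mask": mask_path, "bval": bval_path}


def import_external_case(dwi_path, bval_path, mask_path
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D DWI volume + .bval sidecar + ROI mask into voxel decays.

    Returns (signals, b_values) with signals of shape (n_masked_voxels,
    n_b), voxels ordered row-major. Validates grid agreement, the presence
    of b = 0 and the minimum ROI size of 3 voxels.
    """
    dwi = nib.load(str(dwi_path))
    mask_img = nib.load(str(mask_path))
    data = np.asarray(dwi.dataobj, dtype=float)
    mask = np.asarray(mask_img.dataobj) > 0
    if data.ndim != 4:
        raise ValueError(f"DWI volume must be 4-D; got shape {data.shape}")
    if mask.shape != data.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} does not match DWI grid {data.shape[:3]}")
    b = np.array(Path(bval_path).read_text().split(), dtype=float)
    if len(b) != data.shape[3]:
        raise ValueError(
            f".bval has {len(b)} entries but the DWI volume has "
            f"{data.shape[3]} diffusion volumes")
    if not np.any(b == 0):
        raise ValueError("acquisition must include a b = 0 volume")
    n_vox = int(mask.sum())
    if n_vox < _MIN_VOXELS:
        raise ValueError(
            f"ROI mask selects {n_vox} voxels; an ROI must contain at least "
            f"{_MIN_VOXELS} voxels")
    signals = data[mask]
    return signals, b
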