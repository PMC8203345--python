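"""NIfTI and sidecar I/O helpers (nibabel-backed)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .gfc import GFCMap, GrayMask, VolumeSeries


def load_volume_series(path, subject_id: str = "") -> VolumeSeries:
    """Load a 4D BOLD NIfTI; TR is read from the header's 4th zoom."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected 4D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    sid = subject_id or Path(path).name.split(".")[0]
    return VolumeSeries(data=data, affine=img.affine, tr=tr, subject_id=sid)


def load_volume_3d(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D image, got shape {data.shape}")
    return data, img.affine


def mask_checksum(mask: GrayMask) -> str:
    return hashlib.sha256(mask.member_voxels.astype(np.int64).tobytes()).hexdigest()


def save_gfc_map(gfc: GFCMap, path) -> None:
    """Write a GFC map as 3D float32 NIfTI plus a JSON sidecar.

    Background (non-mask) voxels are encoded as 0; the sidecar carries the
    subject id, z-transform convention, mask checksum and the mask's source
    threshold so maps are never interpreted against the wrong mask.
    """
    path = Path(path)
    vol = gfc.to_volume().astype(np.float32)
    nib.save(nib.Nifti1Image(vol, gfc.mask.affine), str(path))
    sidecar = {
        "subject_id": gfc.subject_id,
        "z_order": gfc.z_order,
        "mask_checksum": mask_checksum(gfc.mask),
        "gm_threshold": gfc.mask.source_threshold,
    }
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    path.with_name(name + ".json").write_text(json.dumps(sidecar, indent=2))


def save_stat_maps(stat, mask: GrayMask, out_dir) -> None:
    """Write the t map and a -log10(p) map as NIfTI volumes."""
    out = Path(out_dir)
    t_vol = mask.to_volume(stat.t).astype(np.float32)
    logp_vol = mask.to_volume(-np.log10(stat.p)).astype(np.float32)
    nib.save(nib.Nifti1Image(t_vol, mask.affine), str(out / "tmap.nii.gz"))
    nib.save(nib.Nifti1Image(logp_vol, mask.affine), str(out / "neglog10p.nii.gz"))
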