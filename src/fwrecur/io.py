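"""NIfTI and manifest I/O helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .schemes import GradientScheme
from .signal import DWIStudy

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_study",
    "load_study",
    "file_sha256",
    "Manifest",
]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_nifti(data: np.ndarray, voxel_size, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _affine(voxel_size))
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), voxel_size


def save_study(study: DWIStudy, directory) -> dict[str, str]:
    """Write one patient's DWI + gradient table; returns file name map."""
    from .schemes import write_fsl_gradients

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "dwi": "dwi.nii",
        "bval": "dwi.bval",
        "bvec": "dwi.bvec",
    }
    save_nifti(study.signal, study.voxel_size, directory / files["dwi"])
    write_fsl_gradients(study.scheme, directory / files["bval"], directory / files["bvec"])
    return files


def load_study(directory, patient_id: str) -> DWIStudy:
    from .schemes import read_fsl_gradients

    directory = Path(directory)
    signal, voxel_size = load_nifti(directory / "dwi.nii")
    scheme = read_fsl_gradients(directory / "dwi.bval", directory / "dwi.bvec")
    return DWIStudy(np.asarray(signal, dtype=float), scheme, voxel_size, patient_id)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Per-run record of stage outputs and their checksums.

    Downstream stages verify their declared inputs against the recorded
    checksums, so a corrupted or stale intermediate fails loudly.
    """

    def __init__(self, path):
        self.path = Path(path)
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {"stages": {}}

    def record_stage(self, stage: str, outdir, files: list[str], meta: dict | None = None):
        outdir = Path(outdir)
        entry = {
            "files": {f: file_sha256(outdir / f) for f in files},
            "meta": meta or {},
        }
        self.data["stages"][stage] = entry
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2)

    def check_stage(self, stage: str, outdir) -> None:
        if stage not in self.data["stages"]:
            raise RuntimeError(
                f"stage '{stage}' has not been run yet; run it first"
            )
        outdir = Path(outdir)
        for fname, digest in self.data["stages"][stage]["files"].items():
            fpath = outdir / fname
            if not fpath.exists():
                raise RuntimeError(f"missing output of stage '{stage}': {fname}")
            if file_sha256(fpath) != digest:
                raise RuntimeError(
                    f"checksum mismatch for {fname} (stage '{stage}'); "
                    "intermediate file corrupted or regenerated"
                )
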