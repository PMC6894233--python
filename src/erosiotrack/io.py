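"""Reading and writing volumes, transforms and tables.

MetaImage (``.mha``) goes through SimpleITK, NIfTI (``.nii``/``.nii.gz``)
through nibabel. Arrays are kept in ``(axial, row, col)`` index order with
physical coordinates ``index * spacing``; SimpleITK's (x, y, z) spacing is
reversed accordingly, and NIfTI files carry a diagonal spacing affine.
Transforms serialize as a plain-text 4x4 matrix with a convention header.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from .phantom import GroundTruthLesion
from .volume import RigidTransform, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_transform",
    "write_transform",
    "write_lesion_manifest",
    "read_lesion_manifest",
]


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".mha":
        img = sitk.GetImageFromArray(vol.data)
        img.SetSpacing(tuple(reversed(vol.spacing_mm)))
        sitk.WriteImage(img, str(path), useCompression=True)
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag(list(vol.spacing_mm) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(vol.data), affine), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return path


def read_volume(path: str | Path, frame: str = "baseline") -> Volume3D:
    path = Path(path)
    if path.suffix == ".mha":
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)
        spacing = tuple(reversed(img.GetSpacing()))
    elif path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(abs(img.affine[i, i])) for i in range(3))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    return Volume3D(data, spacing_mm=spacing, frame=frame)


def write_transform(T: RigidTransform, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rigid transform, convention: {T.convention}\n")
        fh.write("# homogeneous 4x4, physical mm, row-major\n")
        for row in T.as_matrix():
            fh.write(" ".join(f"{v:.12g}" for v in row) + "\n")
    return path


def read_transform(path: str | Path) -> RigidTransform:
    convention = "moving-to-fixed"
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("#"):
            if "convention:" in line:
                convention = line.split("convention:")[1].strip()
            continue
        if line:
            rows.append([float(v) for v in line.split()])
    M = np.asarray(rows)
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}")
    return RigidTransform.from_matrix(M, convention=convention)


def write_lesion_manifest(
    lesions: list[GroundTruthLesion], path: str | Path
) -> Path:
    rows = []
    for les in lesions:
        rows.append(
            {
                "lesion_id": les.lesion_id,
                "kind": les.kind,
                "compartment": les.compartment,
                "quadrant": les.quadrant,
                "center_zyx": ",".join(f"{c:g}" for c in les.center_vox),
                "vol_t0_mm3": les.volume_t0_mm3,
                "vol_t5_mm3": les.volume_t5_mm3,
            }
        )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_lesion_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["center_zyx"] = df["center_zyx"].apply(
        lambda s: tuple(float(v) for v in str(s).split(","))
    )
    return df
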