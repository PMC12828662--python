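"""Reading and writing cohort data in standard formats.

Module-level cohorts travel as per-subject T x M TSVs plus a subjects
table; voxel-level data as NIfTI (4D series, integer label atlas, binary
lesion mask) with a TSV lookup mapping atlas labels to modules.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .parcellation import ModuleScheme
from .synthetic import SubjectRecord, VoxelData

__all__ = [
    "read_cohort",
    "write_voxel_subject",
    "read_voxel_subject",
    "read_label_lookup",
]

_COVARIATE_COLS = ("age", "gender", "MMSE", "education", "NIHSS", "days_since_onset")


def read_cohort(indir: str | Path) -> list[SubjectRecord]:
    """Load a module-level cohort written by
    :func:`strokeconn.synthetic.write_cohort` (or assembled by hand in the
    same layout: ``subjects.tsv`` plus ``<id>_ts.tsv`` per subject)."""
    indir = Path(indir)
    subjects = pd.read_csv(indir / "subjects.tsv", sep="\t")
    records = []
    for row in subjects.to_dict("records"):
        ts = pd.read_csv(indir / f"{row['id']}_ts.tsv", sep="\t")
        covs = {
            c: row[c] for c in _COVARIATE_COLS if c in row and pd.notna(row[c])
        }
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                group=str(row["group"]),
                lesion_hemisphere=str(row["lesion_hemisphere"]),
                lesion_size=int(row["lesion_size"]),
                covariates=covs,
                module_ts=ts,
                TR=float(row.get("TR", 2.0)),
            )
        )
    return records


def write_voxel_subject(voxel: VoxelData, outdir: str | Path, stem: str) -> None:
    """Write a voxel fixture as NIfTI (4D series, atlas, lesion mask) plus
    a label-lookup TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(voxel.voxel_ts.astype(np.float32), affine),
             outdir / f"{stem}_bold.nii")
    nib.save(nib.Nifti1Image(voxel.atlas.astype(np.int16), affine),
             outdir / f"{stem}_atlas.nii")
    nib.save(nib.Nifti1Image(voxel.lesion_mask.astype(np.uint8), affine),
             outdir / f"{stem}_lesion.nii")
    pd.DataFrame(
        {
            "label": list(voxel.label_to_module),
            "module_index": list(voxel.label_to_module.values()),
        }
    ).to_csv(outdir / f"{stem}_labels.tsv", sep="\t", index=False)


def read_label_lookup(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path, sep="\t")
    return {int(r["label"]): int(r["module_index"]) for r in df.to_dict("records")}


def read_voxel_subject(
    bold_path: str | Path,
    atlas_path: str | Path,
    lookup_path: str | Path,
    lesion_path: str | Path | None = None,
) -> VoxelData:
    """Load a voxel-level subject from NIfTI files; without a lesion mask
    an all-false mask is assumed."""
    bold = np.asarray(nib.load(str(bold_path)).dataobj, dtype=float)
    atlas = np.asarray(nib.load(str(atlas_path)).dataobj).astype(np.int32)
    if bold.ndim != 4:
        raise ValueError("BOLD image must be 4D")
    if atlas.shape != bold.shape[:3]:
        raise ValueError("atlas grid does not match the BOLD grid")
    if lesion_path is not None:
        lesion = np.asarray(nib.load(str(lesion_path)).dataobj) > 0
        if lesion.shape != atlas.shape:
            raise ValueError("lesion mask grid does not match the atlas grid")
    else:
        lesion = np.zeros_like(atlas, dtype=bool)
    return VoxelData(
        voxel_ts=bold,
        atlas=atlas,
        lesion_mask=lesion,
        label_to_module=read_label_lookup(lookup_path),
    )
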