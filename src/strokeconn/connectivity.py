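"""Lesion-aware module time-series extraction and Fisher-z connectivity.

A subject's connectome is the M x M matrix of Pearson correlations between
module-mean BOLD series, variance-stabilised by Fisher's r-to-z transform
(z = arctanh r). Module series are averages over atlas voxels outside the
lesion mask; a module with no surviving voxels (or a constant series) is
flagged *missing* rather than imputed, and edges touching it are excluded
pairwise from group statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .parcellation import ModuleScheme
from .synthetic import SubjectRecord, VoxelData

__all__ = [
    "FCMatrix",
    "extract_module_ts",
    "pearson_matrix",
    "fisher_z",
    "compute_fc",
    "edge_vector",
]

logger = logging.getLogger(__name__)

_CLIP = 1e-7


@dataclass(frozen=True)
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix bound to a module scheme."""

    r: np.ndarray
    z: np.ndarray
    scheme: ModuleScheme
    subject_id: str
    missing_modules: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        m = self.scheme.total_count
        if self.r.shape != (m, m):
            raise ValueError(
                f"matrix is {self.r.shape}, scheme has {m} modules"
            )

    def edge_values(self) -> np.ndarray:
        """Upper-triangle z values in scheme edge order; NaN for edges
        touching missing modules."""
        iu = np.triu_indices(self.scheme.total_count, k=1)
        return self.z[iu]

    def to_tsv(self, path: str | Path, sidecar: bool = True) -> None:
        names = self.scheme.names
        pd.DataFrame(self.z, index=names, columns=names).to_csv(
            path, sep="\t", float_format="%.6f"
        )
        if sidecar:
            meta = {
                "subject_id": self.subject_id,
                "condition": self.scheme.condition,
                "missing_modules": sorted(self.missing_modules),
            }
            Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def extract_module_ts(
    voxel: VoxelData, scheme: ModuleScheme
) -> tuple[pd.DataFrame, frozenset[int]]:
    """Average voxel series per module, excluding lesioned voxels.

    Returns the T x M table and the set of modules with no surviving
    voxels (their columns are NaN).
    """
    labels = np.unique(voxel.atlas)
    labels = labels[labels != 0]
    unknown = [int(l) for l in labels if int(l) not in voxel.label_to_module]
    if unknown:
        raise ValueError(f"atlas labels absent from scheme lookup: {unknown}")
    t = voxel.voxel_ts.shape[-1]
    m = scheme.total_count
    out = np.full((t, m), np.nan)
    missing: set[int] = set(range(m))
    for label, module in voxel.label_to_module.items():
        sel = (voxel.atlas == label) & ~voxel.lesion_mask
        if sel.sum() == 0:
            logger.warning("module %d fully lesioned; flagged missing", module)
            continue
        out[:, module] = voxel.voxel_ts[sel].mean(axis=0)
        missing.discard(module)
    # modules whose label never occurs in the atlas also count missing
    return pd.DataFrame(out, columns=scheme.names), frozenset(missing)


def pearson_matrix(
    module_ts: pd.DataFrame,
) -> tuple[np.ndarray, frozenset[int]]:
    """Pearson correlation matrix between module series.

    Constant or all-NaN columns are flagged missing (their rows/columns are
    NaN), never silently zeroed.
    """
    y = np.asarray(module_ts, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 time points")
    sd = np.nanstd(y, axis=0)
    bad = (sd == 0) | ~np.isfinite(sd)
    missing = frozenset(np.flatnonzero(bad).tolist())
    r = np.full((y.shape[1], y.shape[1]), np.nan)
    good = ~bad
    if good.sum() >= 1:
        sub = np.corrcoef(y[:, good], rowvar=False)
        sub = np.atleast_2d(sub)
        gi = np.flatnonzero(good)
        r[np.ix_(gi, gi)] = sub
    return r, missing


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, z = arctanh(r).

    Values within 1e-7 of +/-1 are clipped (and logged); anything beyond
    that window is an error.
    """
    arr = np.asarray(r, dtype=float)
    with np.errstate(invalid="ignore"):
        over = np.abs(arr) > 1.0 + _CLIP
    if np.any(over & np.isfinite(arr)):
        raise ValueError("correlations outside [-1, 1]")
    near = np.abs(arr) > 1.0 - _CLIP
    if np.any(near):
        logger.info("clipping %d near-unit correlations before arctanh",
                    int(np.sum(near)))
        arr = np.clip(arr, -(1.0 - _CLIP), 1.0 - _CLIP)
    z = np.arctanh(arr)
    return z if isinstance(r, np.ndarray) else float(z)


def compute_fc(
    record: SubjectRecord,
    scheme: ModuleScheme,
    use_voxels: bool = False,
) -> FCMatrix:
    """Per-subject Fisher-z connectivity matrix.

    With ``use_voxels`` the module series are first extracted from the
    voxel fixture (lesion-aware); otherwise the record's module series are
    used directly.
    """
    if use_voxels:
        if record.voxel is None:
            raise ValueError(f"subject {record.id} carries no voxel data")
        ts, missing_extract = extract_module_ts(record.voxel, scheme)
    else:
        ts, missing_extract = record.module_ts, frozenset()
    r, missing_const = pearson_matrix(ts)
    missing = frozenset(missing_extract | missing_const)
    z = np.full_like(r, np.nan)
    ok = np.isfinite(r)
    z[ok] = fisher_z(r[ok])
    np.fill_diagonal(z, 0.0)
    return FCMatrix(
        r=r, z=z, scheme=scheme, subject_id=record.id, missing_modules=missing
    )


def edge_vector(matrices: Sequence[FCMatrix]) -> np.ndarray:
    """Stack upper-triangle z values into an (n_subjects, n_edges) array."""
    if not matrices:
        raise ValueError("no matrices supplied")
    return np.vstack([fc.edge_values() for fc in matrices])
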