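"""Synthetic cohorts with planted connectome effects.

Generates per-subject module-level BOLD-like time series from multivariate
normal distributions whose target correlation matrices encode the study
conditions: a block-structured base matrix shared by controls, additive
edge shifts for the stroke group (the planted group effect), per-subject
modulation of selected edges by clinical scores (planted FC-clinical
associations), and optional per-module hemodynamic lags for patients.

The base correlation matrix is a convention chosen to reproduce the block
structure a network parcellation assumes: correlation 0.5 between modules
of the same functional network, 0.6 for homotopic pairs (same network and
structure, opposite hemispheres), 0.1 otherwise. Target matrices that leave
the positive-semidefinite cone after shifts are repaired by eigenvalue
clipping followed by rescaling to unit diagonal.

Covariates are drawn to match the study cohort's published marginals:
age ~ N(58, 8) truncated to [30, 85]; MMSE ~ N(29.5, 1.2) truncated to
[25, 30]; NIHSS ~ N(3.23, 2.80) truncated at 0 and rounded; lesion size
log-uniform on [16, 1459] voxels; onset ~ N(6.6, 4.7) days truncated at 1;
36/65 of stroke lesions left-sided. All randomness flows through the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parcellation import (
    EdgeFamily,
    Hemisphere,
    ModuleScheme,
    Structure,
    classify_edge,
)

__all__ = [
    "ClinLink",
    "EffectSpec",
    "SubjectRecord",
    "VoxelData",
    "base_correlation",
    "nearest_correlation",
    "figure_pattern_effect",
    "generate_cohort",
    "generate_voxel_subject",
    "cohort_to_frames",
    "write_cohort",
]

# Eigenvalue floor for the positive-semidefinite repair.
_PSD_FLOOR = 1e-4


@dataclass(frozen=True)
class ClinLink:
    """A planted monotone association between one edge and one clinical
    variable, with target Spearman correlation ``rho`` in the stroke group."""

    edge: tuple[int, int]
    variable: str
    rho: float

    def __post_init__(self) -> None:
        if not abs(self.rho) < 1:
            raise ValueError("target rho must satisfy |rho| < 1")


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect structure for a synthetic cohort.

    Parameters
    ----------
    edge_deltas
        Additive shifts (correlation units) applied to the stroke group's
        target correlations. Keys are either :class:`EdgeFamily` members
        (shift every edge of the family) or explicit ``(i, j)`` pairs.
    clin_links
        FC-clinical associations to plant (stroke group only).
    lag_sd
        Standard deviation (seconds) of per-module hemodynamic lags in
        patients; 0 disables lag planting. When lags are planted the latent
        series are temporally smoothed (moving average) so that lags are
        identifiable by cross-correlation.
    noise_sd
        Scale of i.i.d. observation noise added on top of the latent series.
    """

    edge_deltas: Mapping = field(default_factory=dict)
    clin_links: tuple[ClinLink, ...] = ()
    lag_sd: float = 0.0
    noise_sd: float = 0.0


@dataclass(frozen=True)
class VoxelData:
    """Voxel-level fixture: a 4D array with an integer label atlas and a
    binary lesion mask on the same grid."""

    voxel_ts: np.ndarray  # (nx, ny, nz, T)
    atlas: np.ndarray  # (nx, ny, nz) int labels, 0 = background
    lesion_mask: np.ndarray  # (nx, ny, nz) bool
    label_to_module: dict[int, int]  # atlas label -> scheme module index


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: module (or voxel) time series plus phenotype."""

    id: str
    group: str  # "stroke" | "control"
    lesion_hemisphere: str  # "left" | "right" | "none"
    lesion_size: int
    covariates: dict[str, float]
    module_ts: pd.DataFrame  # T x M, columns = module names
    TR: float = 2.0
    motion_params: pd.DataFrame | None = None
    voxel: VoxelData | None = None

    def __post_init__(self) -> None:
        if self.group == "control" and self.lesion_hemisphere != "none":
            raise ValueError("controls cannot carry a lesion")

    @property
    def n_volumes(self) -> int:
        return len(self.module_ts)


def base_correlation(scheme: ModuleScheme) -> np.ndarray:
    """Block-structured base target correlation matrix for controls."""
    m = scheme.total_count
    corr = np.full((m, m), 0.1)
    for a in scheme.modules:
        for b in scheme.modules:
            if a.index == b.index:
                continue
            if a.network == b.network:
                homotopic = (
                    a.structure is b.structure and a.hemisphere is not b.hemisphere
                )
                corr[a.index, b.index] = 0.6 if homotopic else 0.5
    np.fill_diagonal(corr, 1.0)
    return nearest_correlation(corr)


def nearest_correlation(
    corr: np.ndarray, floor: float = _PSD_FLOOR, max_iter: int = 100
) -> np.ndarray:
    """Deterministic positive-semidefinite repair of a symmetric matrix.

    Alternates eigenvalue clipping (at ``floor``) with rescaling to unit
    diagonal until the smallest eigenvalue is at least ``floor``. Raises if
    the repair fails to converge.
    """
    c = (corr + corr.T) / 2.0
    np.fill_diagonal(c, 1.0)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(c)
        if w[0] >= floor:
            return c
        w = np.clip(w, floor, None)
        c = (v * w) @ v.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2.0
        np.fill_diagonal(c, 1.0)
    w = np.linalg.eigvalsh(c)
    if w[0] < floor / 2:
        bad = np.unravel_index(np.argmax(np.abs(c - corr)), c.shape)
        raise ValueError(
            f"positive-semidefinite repair did not converge; worst edge {bad}"
        )
    return c


def apply_edge_deltas(
    base: np.ndarray, scheme: ModuleScheme, edge_deltas: Mapping
) -> np.ndarray:
    """Stroke-group target matrix: base plus edge shifts, PSD-repaired."""
    target = base.copy()
    family_deltas = {
        EdgeFamily(k): v for k, v in edge_deltas.items()
        if isinstance(k, (EdgeFamily, str))
    }
    pair_deltas = {
        tuple(sorted(k)): v for k, v in edge_deltas.items()
        if isinstance(k, tuple)
    }
    for i, j in scheme.edges():
        delta = family_deltas.get(classify_edge(scheme, i, j), 0.0)
        delta += pair_deltas.get((i, j), 0.0)
        if delta:
            r = np.clip(base[i, j] + delta, -0.95, 0.95)
            target[i, j] = target[j, i] = r
    return nearest_correlation(target)


#: Direction pattern of the planted group effect, mirroring the observed
#: stroke phenotype: increased intra-hemispheric and decreased
#: inter-hemispheric cerebral connectivity, increased cerebellar
#: inter-module connectivity, decreased ipsilesional-cerebral-to-cerebellar
#: and increased contralesional-cerebral-to-cerebellar connectivity.
FIGURE_PATTERN_SIGNS: dict[EdgeFamily, int] = {
    EdgeFamily.CEREBRAL_INTRA_IL: +1,
    EdgeFamily.CEREBRAL_INTRA_CL: +1,
    EdgeFamily.CEREBRAL_INTER: -1,
    EdgeFamily.CEREBELLAR_INTRA_IL: +1,
    EdgeFamily.CEREBELLAR_INTRA_CL: +1,
    EdgeFamily.CEREBELLAR_INTER: +1,
    EdgeFamily.CBL_IL_TO_CONTRA_CBLM: -1,
    EdgeFamily.CBL_IL_TO_IPSI_CBLM: -1,
    EdgeFamily.CBL_CL_TO_CONTRA_CBLM: +1,
    EdgeFamily.CBL_CL_TO_IPSI_CBLM: +1,
}


def figure_pattern_effect(
    delta: float = 0.25,
    clin_links: Sequence[ClinLink] = (),
    lag_sd: float = 0.0,
    noise_sd: float = 0.0,
) -> EffectSpec:
    """EffectSpec planting the stroke direction pattern at magnitude
    ``delta`` on every edge of every family."""
    return EffectSpec(
        edge_deltas={fam: sign * delta for fam, sign in FIGURE_PATTERN_SIGNS.items()},
        clin_links=tuple(clin_links),
        lag_sd=lag_sd,
        noise_sd=noise_sd,
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, low, high)


def _draw_covariates(
    rng: np.random.Generator, n: int, stroke: bool
) -> list[dict[str, float]]:
    age = _truncated_normal(rng, 58.0, 8.0, 30, 85, n)
    gender = (rng.random(n) < 0.42).astype(int)  # 1 = female, ~27/65
    mmse = np.round(_truncated_normal(rng, 29.5, 1.2, 25, 30, n), 0)
    education = np.round(_truncated_normal(rng, 9.0, 3.0, 0, 20, n), 0)
    covs = []
    if stroke:
        nihss = np.round(_truncated_normal(rng, 3.23, 2.80, 0, 25, n), 0)
        onset = np.round(_truncated_normal(rng, 6.62, 4.74, 1, 30, n), 0)
    for k in range(n):
        c = {
            "age": float(age[k]),
            "gender": int(gender[k]),
            "MMSE": float(mmse[k]),
            "education": float(education[k]),
        }
        if stroke:
            c["NIHSS"] = float(nihss[k])
            c["days_since_onset"] = float(onset[k])
        covs.append(c)
    return covs


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Columnwise moving average with edge-padded 'same' output."""
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, ((pad, width - 1 - pad), (0, 0)), mode="edge")
    return np.apply_along_axis(lambda c: np.convolve(c, kernel, "valid"), 0, xp)


def _shift_series(x: np.ndarray, lag_s: float, tr: float) -> np.ndarray:
    """Delay a series by ``lag_s`` seconds (linear interpolation, edge
    replication): output(t) = input(t - lag)."""
    t = np.arange(len(x)) * tr
    return np.interp(t - lag_s, t, x)


def _clin_slope(rho: float, t_eff: int) -> float:
    """Slope (in Fisher-z units per standardised clinical score) so that the
    estimated-FC-vs-score correlation approaches ``rho``.

    The sample Fisher-z of an edge is approximately its subject-level target
    plus estimation noise of variance 1/(T-3); the planted target Spearman
    is first converted to the Pearson correlation of the underlying
    bivariate normal (Pearson's sin relation).
    """
    rho_p = 2.0 * math.sin(math.pi * rho / 6.0)
    sigma = 1.0 / math.sqrt(max(t_eff - 3, 1))
    return sigma * rho_p / math.sqrt(1.0 - rho_p**2)


def generate_cohort(
    scheme: ModuleScheme,
    n_stroke: int = 65,
    n_control: int = 72,
    T: int = 235,
    effect: EffectSpec | None = None,
    seed: int = 0,
    TR: float = 2.0,
    left_lesion_fraction: float = 36 / 65,
    base: np.ndarray | None = None,
) -> list[SubjectRecord]:
    """Generate a two-group cohort of module-level time series.

    Control series are drawn from a zero-mean multivariate normal with the
    block base correlation target; stroke series from the base plus
    ``effect.edge_deltas`` (PSD-repaired). Edges named in
    ``effect.clin_links`` are additionally modulated per subject by the
    standardised clinical score so the estimated FC-score Spearman
    correlation approaches the planted target. Fully reproducible per seed.
    """
    if n_stroke < 2 or n_control < 2:
        raise ValueError("need at least 2 subjects per group")
    if T < 50:
        raise ValueError("need at least 50 volumes")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)
    if base is None:
        base = base_correlation(scheme)
    stroke_target = apply_edge_deltas(base, scheme, effect.edge_deltas)

    smooth_width = 0
    if effect.lag_sd > 0:
        # temporal smoothing makes lags identifiable by cross-correlation
        smooth_width = max(3, int(round(2.0 * effect.lag_sd / TR)) * 2 + 1)

    records: list[SubjectRecord] = []
    names = scheme.names
    for group, n in (("stroke", n_stroke), ("control", n_control)):
        covs = _draw_covariates(rng, n, stroke=group == "stroke")
        # standardised clinical scores for link modulation
        link_scores: dict[str, np.ndarray] = {}
        if group == "stroke":
            n_left = int(round(left_lesion_fraction * n))
            sides = np.array(["left"] * n_left + ["right"] * (n - n_left))
            rng.shuffle(sides)
            lesion_size = np.exp(
                rng.uniform(math.log(16), math.log(1459), n)
            ).astype(int)
            for link in effect.clin_links:
                if link.variable == "lesion_size":
                    vals = np.log(lesion_size.astype(float))
                else:
                    vals = np.array([c[link.variable] for c in covs])
                sd = vals.std()
                link_scores[link.variable] = (
                    (vals - vals.mean()) / sd if sd > 0 else np.zeros(n)
                )
        for k in range(n):
            if group == "control":
                target = base
            else:
                target = stroke_target
                if effect.clin_links:
                    target = target.copy()
                    z = np.arctanh(np.clip(target, -0.999, 0.999))
                    for link in effect.clin_links:
                        i, j = link.edge
                        slope = _clin_slope(link.rho, T)
                        z[i, j] += slope * link_scores[link.variable][k]
                        z[j, i] = z[i, j]
                    np.fill_diagonal(z, np.inf)
                    target = nearest_correlation(
                        np.where(np.isinf(z), 1.0, np.tanh(z))
                    )
            chol = np.linalg.cholesky(target)
            latent = rng.standard_normal((T, scheme.total_count)) @ chol.T
            if smooth_width:
                latent = _moving_average(latent, smooth_width)
            if group == "stroke" and effect.lag_sd > 0:
                lags = rng.normal(0.0, effect.lag_sd, scheme.total_count)
                lags = np.clip(lags, -4 * TR, 4 * TR)
                for m in range(scheme.total_count):
                    latent[:, m] = _shift_series(latent[:, m], lags[m], TR)
            if effect.noise_sd > 0:
                latent = latent + rng.normal(0.0, effect.noise_sd, latent.shape)
            ts = pd.DataFrame(latent, columns=names)
            if group == "stroke":
                side = sides[k]
                if side == "right":
                    # store in anatomical orientation: mirror the IL/CL blocks
                    perm = scheme.mirror_permutation()
                    flipped = ts.iloc[:, perm].copy()
                    flipped.columns = ts.columns
                    ts = flipped
                rec = SubjectRecord(
                    id=f"stroke{k:03d}",
                    group="stroke",
                    lesion_hemisphere=str(side),
                    lesion_size=int(lesion_size[k]),
                    covariates=covs[k],
                    module_ts=ts,
                    TR=TR,
                )
            else:
                rec = SubjectRecord(
                    id=f"control{k:03d}",
                    group="control",
                    lesion_hemisphere="none",
                    lesion_size=0,
                    covariates=covs[k],
                    module_ts=ts,
                    TR=TR,
                )
            records.append(rec)
    return records


def generate_voxel_subject(
    record: SubjectRecord,
    grid: tuple[int, int, int] = (8, 8, 4),
    voxels_per_module: int = 4,
    lag: float = 0.0,
    lesion_fraction: float = 0.0,
    lesioned_modules: Sequence[int] = (0,),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SubjectRecord:
    """Attach a voxel-level fixture to a subject.

    Each module occupies ``voxels_per_module`` voxels of a 3D grid (labels
    1..M in scheme order, 0 background); every voxel's series is the
    module's latent series delayed by ``lag`` seconds plus i.i.d. noise. A
    lesion mask covers the first ``lesion_fraction`` of the voxels of each
    module in ``lesioned_modules``.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    m = record.module_ts.shape[1]
    t = record.n_volumes
    n_needed = m * voxels_per_module
    nx, ny, nz = grid
    if nx * ny * nz < n_needed:
        raise ValueError(f"grid {grid} too small for {n_needed} labelled voxels")
    atlas = np.zeros(grid, dtype=np.int32)
    lesion = np.zeros(grid, dtype=bool)
    voxel_ts = np.zeros(grid + (t,))
    flat_order = np.arange(nx * ny * nz)
    latent = record.module_ts.to_numpy()
    for mod in range(m):
        vox = flat_order[mod * voxels_per_module : (mod + 1) * voxels_per_module]
        series = latent[:, mod]
        if lag != 0.0:
            series = _shift_series(series, lag, record.TR)
        n_lesioned = int(round(lesion_fraction * voxels_per_module)) if mod in set(
            lesioned_modules
        ) else 0
        for rank, v in enumerate(vox):
            idx = np.unravel_index(v, grid)
            atlas[idx] = mod + 1
            noisy = series + (
                rng.normal(0.0, noise_sd, t) if noise_sd > 0 else 0.0
            )
            voxel_ts[idx] = noisy
            if rank < n_lesioned:
                lesion[idx] = True
    voxel = VoxelData(
        voxel_ts=voxel_ts,
        atlas=atlas,
        lesion_mask=lesion,
        label_to_module={mod + 1: mod for mod in range(m)},
    )
    return replace(record, voxel=voxel)


def cohort_to_frames(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Subjects table (one row per participant) for serialisation."""
    rows = []
    for rec in cohort:
        row = {
            "id": rec.id,
            "group": rec.group,
            "lesion_hemisphere": rec.lesion_hemisphere,
            "lesion_size": rec.lesion_size,
            "TR": rec.TR,
        }
        row.update(rec.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(
    cohort: Sequence[SubjectRecord], outdir: str | Path, seed: int | None = None
) -> None:
    """Write per-subject T x M TSVs plus the subjects table and a JSON
    sidecar recording the generation seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in cohort:
        rec.module_ts.to_csv(outdir / f"{rec.id}_ts.tsv", sep="\t", index=False)
    cohort_to_frames(cohort).to_csv(outdir / "subjects.tsv", sep="\t", index=False)
    sidecar = {"n_subjects": len(cohort), "seed": seed}
    (outdir / "generation.json").write_text(json.dumps(sidecar, indent=2))
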