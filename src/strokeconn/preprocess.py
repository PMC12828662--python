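"""In-scope rs-fMRI preprocessing stages on module- or voxel-level series.

Stage order follows the standard stroke rs-fMRI pipeline implemented here:
initial-volume discard -> motion quality control -> nuisance regression ->
band-pass filtering -> hemodynamic-lag correction (time-shift analysis).

Framewise displacement uses the Power convention: the sum of absolute
frame-to-frame differences of the six realignment parameters, with the
three rotations (degrees) converted to arc length on a 50 mm sphere.

Hemodynamic lag is estimated per series as the shift maximising the
cross-correlation with a reference signal over integer multiples of TR,
refined by parabolic interpolation through the peak; positive lag means the
series lags (is delayed relative to) the reference. Correction resamples
each series at t + lag by linear interpolation with edge replication, so a
planted integer-TR lag round-trips to a re-estimated lag of zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCResult",
    "LagMap",
    "discard_initial",
    "framewise_displacement",
    "motion_qc",
    "scrub",
    "friston24",
    "nuisance_regress",
    "bandpass",
    "estimate_lag",
    "estimate_lag_map",
    "apply_lag_correction",
]

_ROT_SPHERE_RADIUS_MM = 50.0


@dataclass(frozen=True)
class QCResult:
    keep: bool
    max_translation: float
    max_rotation: float
    mean_fd: float
    reason: str | None = None


@dataclass(frozen=True)
class LagMap:
    """Per-series hemodynamic lags (seconds); positive = series lags the
    reference."""

    lags: pd.Series  # index = series name
    search_range: float
    reference: str = "global_mean"

    def __post_init__(self) -> None:
        if (self.lags.abs() > self.search_range + 1e-9).any():
            raise ValueError("lags exceed the search range")

    def to_tsv(self, path) -> None:
        self.lags.rename("lag_s").to_csv(path, sep="\t", header=True)


def discard_initial(ts: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Drop the first ``k`` volumes (magnetisation equilibration)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if len(ts) <= k:
        raise ValueError(f"cannot discard {k} of {len(ts)} volumes")
    return ts.iloc[k:].reset_index(drop=True)


def framewise_displacement(motion_params: pd.DataFrame) -> np.ndarray:
    """Per-frame FD from a T x 6 table (3 translations mm, 3 rotations
    degrees). The first frame's FD is 0."""
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be a T x 6 table")
    diffs = np.abs(np.diff(p, axis=0))
    diffs[:, 3:] = np.deg2rad(diffs[:, 3:]) * _ROT_SPHERE_RADIUS_MM
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    return fd


def motion_qc(
    motion_params: pd.DataFrame,
    max_trans: float = 3.0,
    max_rot: float = 3.0,
    max_mean_fd: float = 0.5,
) -> QCResult:
    """Keep/exclude decision from head-motion parameters.

    Excludes when any translation exceeds ``max_trans`` mm, any rotation
    exceeds ``max_rot`` degrees, or mean FD exceeds ``max_mean_fd`` mm.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion parameters must be a T x 6 table")
    max_t = float(np.abs(p[:, :3]).max())
    max_r = float(np.abs(p[:, 3:]).max())
    mean_fd = float(framewise_displacement(motion_params).mean())
    reason = None
    if max_t > max_trans:
        reason = f"translation {max_t:.2f} mm > {max_trans} mm"
    elif max_r > max_rot:
        reason = f"rotation {max_r:.2f} deg > {max_rot} deg"
    elif mean_fd > max_mean_fd:
        reason = f"mean FD {mean_fd:.3f} mm > {max_mean_fd} mm"
    return QCResult(
        keep=reason is None,
        max_translation=max_t,
        max_rotation=max_r,
        mean_fd=mean_fd,
        reason=reason,
    )


def scrub(
    ts: pd.DataFrame,
    motion_params: pd.DataFrame,
    fd_threshold: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Censor frames whose FD exceeds ``fd_threshold`` mm.

    Off by default in the pipeline (kept as a robustness variant); returns
    the censored table and the boolean keep mask.
    """
    fd = framewise_displacement(motion_params)
    keep = fd <= fd_threshold
    if keep.sum() < 3:
        raise ValueError("scrubbing removed nearly all frames")
    return ts.loc[keep].reset_index(drop=True), keep


def friston24(motion_params: pd.DataFrame) -> pd.DataFrame:
    """24-parameter motion expansion: p, p(t-1), p^2, p(t-1)^2."""
    p = np.asarray(motion_params, dtype=float)
    lagged = np.vstack([np.zeros((1, p.shape[1])), p[:-1]])
    out = np.hstack([p, lagged, p**2, lagged**2])
    cols = (
        [f"p{i}" for i in range(6)]
        + [f"p{i}_lag" for i in range(6)]
        + [f"p{i}_sq" for i in range(6)]
        + [f"p{i}_lag_sq" for i in range(6)]
    )
    return pd.DataFrame(out, columns=cols)


def nuisance_regress(ts: pd.DataFrame, regressors: pd.DataFrame) -> pd.DataFrame:
    """Residualise every series on [intercept | regressors] by least
    squares. Residuals are orthogonal to every regressor column."""
    y = np.asarray(ts, dtype=float)
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if len(x) != len(y):
        raise ValueError("time series and regressors must have equal length")
    design = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify collinear columns by rank-revealing QR-style sweep
        bad = []
        cols = [design[:, 0]]
        for c in range(1, design.shape[1]):
            trial = np.column_stack(cols + [design[:, c]])
            if np.linalg.matrix_rank(trial) == len(cols):
                bad.append(list(regressors.columns)[c - 1] if hasattr(
                    regressors, "columns") else c - 1)
            else:
                cols.append(design[:, c])
        raise ValueError(f"rank-deficient nuisance design; collinear: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return pd.DataFrame(resid, columns=ts.columns, index=ts.index)


def bandpass(
    ts: pd.DataFrame, TR: float, low: float = 0.01, high: float = 0.08
) -> pd.DataFrame:
    """Zero-phase frequency-domain band-pass (hard FFT mask, DC removed)."""
    nyquist = 1.0 / (2.0 * TR)
    if not (0 <= low < high):
        raise ValueError("need 0 <= low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyquist} Hz")
    y = np.asarray(ts, dtype=float)
    t = len(y)
    freqs = np.fft.rfftfreq(t, d=TR)
    mask = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(y, axis=0)
    spec[~mask] = 0.0
    out = np.fft.irfft(spec, n=t, axis=0)
    return pd.DataFrame(out, columns=ts.columns, index=ts.index)


def estimate_lag(
    series: np.ndarray,
    reference: np.ndarray,
    TR: float,
    max_lag: float | None = None,
    return_peak: bool = False,
) -> float | tuple[float, float]:
    """Hemodynamic lag of ``series`` relative to ``reference`` (seconds).

    Cross-correlation is evaluated at every integer-TR shift within
    ``max_lag`` (default 4*TR); the integer peak (ties broken toward zero
    shift) is refined by parabolic interpolation through its two
    neighbours. Positive lag means the series is delayed.
    """
    x = np.asarray(series, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape or x.ndim != 1:
        raise ValueError("series and reference must be 1-D and equal length")
    if x.std() == 0 or ref.std() == 0:
        raise ValueError("zero-variance series")
    if max_lag is None:
        max_lag = 4 * TR
    max_shift = int(round(max_lag / TR))
    if max_shift < 1:
        raise ValueError("max_lag must be at least one TR")
    t = len(x)
    if t <= max_shift + 2:
        raise ValueError("series too short for the requested search range")
    shifts = np.arange(-max_shift, max_shift + 1)
    corrs = np.empty(len(shifts))
    for idx, s in enumerate(shifts):
        if s >= 0:
            a, b = x[s:], ref[: t - s]
        else:
            a, b = x[: t + s], ref[-s:]
        if a.std() == 0 or b.std() == 0:
            corrs[idx] = -np.inf
            continue
        corrs[idx] = np.corrcoef(a, b)[0, 1]
    best = np.flatnonzero(corrs == corrs.max())
    peak = best[np.argmin(np.abs(shifts[best]))]  # ties toward zero shift
    tau = shifts[peak] * TR
    if 0 < peak < len(shifts) - 1:
        cm, c0, cp = corrs[peak - 1], corrs[peak], corrs[peak + 1]
        denom = cm - 2 * c0 + cp
        if np.isfinite(denom) and abs(denom) > 1e-12:
            frac = 0.5 * (cm - cp) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
            tau = (shifts[peak] + frac) * TR
    tau = float(np.clip(tau, -max_lag, max_lag))
    tau = 0.0 if abs(tau) < 1e-9 else tau
    if return_peak:
        return tau, float(corrs[peak])
    return tau


def estimate_lag_map(
    ts: pd.DataFrame,
    TR: float,
    max_lag: float | None = None,
    reference: np.ndarray | None = None,
    integer: bool = False,
    min_peak_corr: float = 0.3,
) -> LagMap:
    """Per-column lag estimates against the global mean (or a supplied
    reference).

    With ``integer`` the lags are rounded to whole multiples of TR (the
    original time-shift-analysis convention of shifting by volumes), which
    also makes the subsequent correction an exact no-op on lag-free data.
    A series whose peak cross-correlation with the reference falls below
    ``min_peak_corr`` gets lag 0: its lag is not reliably estimable, so it
    is left unshifted (the usual cross-correlation masking of time-shift
    analysis).
    """
    if max_lag is None:
        max_lag = 4 * TR
    ref_name = "supplied"
    if reference is None:
        reference = np.asarray(ts, dtype=float).mean(axis=1)
        ref_name = "global_mean"
    lags = {}
    for col in ts.columns:
        tau, peak = estimate_lag(ts[col].to_numpy(), reference, TR, max_lag,
                                 return_peak=True)
        lags[col] = tau if peak >= min_peak_corr else 0.0
    if integer:
        lags = {col: round(tau / TR) * TR for col, tau in lags.items()}
    return LagMap(
        lags=pd.Series(lags), search_range=float(max_lag), reference=ref_name
    )


def apply_lag_correction(ts: pd.DataFrame, lags: LagMap, TR: float) -> pd.DataFrame:
    """Undo per-series lags: each column is resampled at t + lag by linear
    interpolation with edge replication."""
    t_grid = np.arange(len(ts)) * TR
    out = {}
    for col in ts.columns:
        tau = float(lags.lags[col])
        x = ts[col].to_numpy(dtype=float)
        out[col] = np.interp(t_grid + tau, t_grid, x) if tau != 0.0 else x
    return pd.DataFrame(out, columns=ts.columns, index=ts.index)
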