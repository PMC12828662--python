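"""Exploratory FC-clinical Spearman correlations and analytic power.

For every edge with a significant group difference, the Fisher-z value is
correlated (Spearman) with stroke severity (NIHSS) and lesion size within
the stroke group, plain and covariate-adjusted. The adjusted variant
rank-transforms the edge values, the clinical variable and the covariates,
residualises the two ranked targets on the ranked covariates (with
intercept), and correlates the residuals; its p-value uses the t
approximation with df = n - 2 - k. Significance is flagged at p < 0.01
uncorrected (exploratory) with an optional BH-FDR pass at q < 0.05 per
(variable x condition).

Analytic power for a correlation test uses the Fisher-z approximation:
power = Phi(|arctanh(rho)| * sqrt(n - 3) - z_{1 - alpha/2}).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import compute_fc, edge_vector
from .parcellation import ModuleScheme, flip_hemispheres
from .synthetic import SubjectRecord

__all__ = [
    "spearman",
    "partial_spearman",
    "correlate_significant_edges",
    "correlation_power",
    "sample_size_for_power",
]


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with two-sided t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need equal-length inputs with n >= 5")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame | None
) -> tuple[float, float]:
    """Covariate-adjusted Spearman correlation by rank residualisation.

    Ranks x, y and each covariate column (average ranks for ties),
    residualises ranked x and y on [intercept | ranked covariates], and
    returns the Pearson correlation of the residuals with a two-sided t
    p-value at df = n - 2 - k. With no covariates this equals plain
    Spearman exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or np.size(covariates) == 0:
        return spearman(x, y)
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    n, k = cov.shape
    if len(x) != n or len(y) != n:
        raise ValueError("covariates must align with x and y")
    if n <= k + 2:
        raise ValueError("too few observations for the covariate set")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rc = np.column_stack([stats.rankdata(c) for c in cov.T])
    design = np.column_stack([np.ones(n), rc])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    rho = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    rho_c = min(max(rho, -1 + 1e-15), 1 - 1e-15)
    t = rho_c * np.sqrt(df / (1 - rho_c**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def correlate_significant_edges(
    results: pd.DataFrame,
    cohort: list[SubjectRecord],
    scheme: ModuleScheme,
    variables: tuple[str, ...] = ("NIHSS", "lesion_size"),
    covariates: tuple[str, ...] = (
        "age", "gender", "MMSE", "education", "days_since_onset",
    ),
    alpha_unc: float = 0.01,
    fdr_q: float = 0.05,
    flip: bool = True,
) -> pd.DataFrame:
    """Spearman correlations of significant edges with clinical variables.

    Computed within the stroke group only (controls carry no NIHSS or
    lesion size), plain and covariate-adjusted, with uncorrected p < 0.01
    flags and BH-FDR at ``fdr_q`` applied per variable across the
    significant edges of this condition.
    """
    from .group_stats import fdr_bh

    sig = results[results["significant"]]
    if sig.empty:
        warnings.warn("no significant edges; returning empty table")
        return pd.DataFrame(
            columns=[
                "i", "j", "variable", "adjusted", "rho", "p", "q",
                "significant_unc", "significant_fdr",
            ]
        )
    stroke = [r for r in cohort if r.group == "stroke"]
    if flip:
        stroke = [flip_hemispheres(r, scheme) for r in stroke]
    z = edge_vector([compute_fc(r, scheme) for r in stroke])
    edge_index = {(i, j): e for e, (i, j) in enumerate(scheme.edges())}
    clin = {
        "NIHSS": np.array([r.covariates.get("NIHSS", np.nan) for r in stroke]),
        "lesion_size": np.array([float(r.lesion_size) for r in stroke]),
    }
    cov = np.array(
        [[r.covariates[c] for c in covariates] for r in stroke], dtype=float
    ) if covariates else None

    rows = []
    for var in variables:
        values = clin[var]
        for _, edge in sig.iterrows():
            e = edge_index[(int(edge["i"]), int(edge["j"]))]
            zvals = z[:, e]
            ok = ~np.isnan(zvals) & ~np.isnan(values)
            rho, p = spearman(zvals[ok], values[ok])
            rho_a, p_a = partial_spearman(
                zvals[ok], values[ok], None if cov is None else cov[ok]
            )
            for adjusted, (r_, p_) in (
                (False, (rho, p)), (True, (rho_a, p_a)),
            ):
                rows.append(
                    {
                        "i": int(edge["i"]),
                        "j": int(edge["j"]),
                        "module_i": edge["module_i"],
                        "module_j": edge["module_j"],
                        "family": edge["family"],
                        "variable": var,
                        "adjusted": adjusted,
                        "rho": r_,
                        "p": p_,
                    }
                )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    out["significant_unc"] = out["p"] < alpha_unc
    out["significant_fdr"] = False
    for (var, adjusted), idx in out.groupby(["variable", "adjusted"]).groups.items():
        q, flags = fdr_bh(out.loc[idx, "p"].to_numpy(), fdr_q)
        out.loc[idx, "q"] = q
        out.loc[idx, "significant_fdr"] = flags
    return out


def correlation_power(n: int, rho: float, alpha: float = 0.01) -> float:
    """Analytic power of a two-sided correlation test (Fisher-z
    approximation) at sample size ``n`` and true correlation ``rho``."""
    if n < 10:
        raise ValueError("need n >= 10")
    if not 0 < abs(rho) < 1:
        raise ValueError("need 0 < |rho| < 1")
    z_crit = stats.norm.ppf(1 - alpha / 2)
    effect = abs(np.arctanh(rho)) * np.sqrt(n - 3)
    return float(stats.norm.cdf(effect - z_crit))


def sample_size_for_power(
    rho: float, power: float = 0.8, alpha: float = 0.01
) -> int:
    """Smallest n whose analytic power reaches ``power`` for ``rho``."""
    z_crit = stats.norm.ppf(1 - alpha / 2)
    z_pow = stats.norm.ppf(power)
    n = ((z_crit + z_pow) / abs(np.arctanh(rho))) ** 2 + 3
    n = int(np.ceil(n))
    while correlation_power(max(n, 10), rho, alpha) < power:
        n += 1
    return n
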