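"""Covariate-adjusted permutation comparison of connectome edges.

For each inter-module edge, subjects' Fisher-z values are first
residualised on [intercept | covariates] pooled across both groups
(Freedman-Lane-style adjustment under a groupless null); the test statistic
is the stroke-minus-control mean of these residuals. Its null distribution
is built by randomly reallocating subjects to the two groups and
recomputing the mean difference (default 10,000 permutations); the
empirical two-tailed p-value carries the +1 correction,
p = (#{|delta_perm| >= |delta_obs|} + 1) / (P + 1). Benjamini-Hochberg FDR
is applied jointly across all edges of a matrix condition (378 or 2145
tests) at q < 0.01 by default.

Demographics helpers reproduce the standard cohort table: Pearson's
chi-square (no continuity correction) for categorical variables and the
two-sample t-test for continuous ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import compute_fc, edge_vector
from .parcellation import ModuleScheme, edge_families, flip_hemispheres
from .synthetic import SubjectRecord

__all__ = [
    "permutation_edge_test",
    "permutation_test_matrix",
    "fdr_bh",
    "compare_groups",
    "family_direction_counts",
    "chi_square_2x2",
    "two_sample_t",
    "demographics_tests",
]

DEFAULT_COVARIATES = ("age", "gender")


def _residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of each column of ``values`` on [intercept | covariates]."""
    n = values.shape[0]
    if covariates is None or covariates.size == 0:
        return values - values.mean(axis=0, keepdims=True)
    x = np.column_stack([np.ones(n), covariates])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear covariates in adjustment design")
    beta, *_ = np.linalg.lstsq(x, values, rcond=None)
    return values - x @ beta


def permutation_test_matrix(
    values_a: np.ndarray,
    values_b: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    tails: str = "two",
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation test of group mean differences, vectorised over edges.

    ``values_a``/``values_b`` are (n_a, E) and (n_b, E) arrays of edge
    values for the two groups (E may be 1). Covariates, if given, are the
    pooled (n_a + n_b, k) nuisance design, residualised out before label
    permutation; the same label permutations are shared across edges.

    Returns ``(delta, p)`` of shape (E,): observed adjusted mean
    differences (a minus b) and empirical p-values with the +1 correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("group value arrays must be (n, E) with equal E")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    pooled = np.vstack([a, b])
    n = n_a + n_b
    resid = _residualize(
        pooled, None if covariates is None else np.asarray(covariates, float)
    )
    delta = resid[:n_a].mean(axis=0) - resid[n_a:].mean(axis=0)

    rng = np.random.default_rng(seed)
    # indicator-based vectorisation: delta_perm = w @ resid where w encodes
    # 1/n_a for permuted group A and -1/n_b for permuted group B
    col_sum = resid.sum(axis=0)
    exceed = np.zeros(resid.shape[1], dtype=np.int64)
    block = max(1, min(n_perm, int(2e7) // max(resid.shape[1], 1) // n + 1))
    done = 0
    abs_obs = np.abs(delta)
    while done < n_perm:
        nb = min(block, n_perm - done)
        # uniform random relabelings: first n_a ranks of a random ordering,
        # encoded as a 0/1 indicator matrix so the group sums are one matmul
        picks = rng.random((nb, n)).argsort(axis=1)[:, :n_a]
        indicator = np.zeros((nb, n))
        indicator[np.arange(nb)[:, None], picks] = 1.0
        sum_a = indicator @ resid  # (nb, E)
        mean_a = sum_a / n_a
        mean_b = (col_sum - sum_a) / n_b
        dperm = mean_a - mean_b
        if tails == "two":
            exceed += (np.abs(dperm) >= abs_obs - 1e-12).sum(axis=0)
        elif tails == "greater":
            exceed += (dperm >= delta - 1e-12).sum(axis=0)
        else:
            exceed += (dperm <= delta + 1e-12).sum(axis=0)
        done += nb
    p = (exceed + 1) / (n_perm + 1)
    return delta, p


def permutation_edge_test(
    z_stroke: np.ndarray,
    z_control: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    tails: str = "two",
) -> tuple[float, float]:
    """Single-edge wrapper around :func:`permutation_test_matrix`."""
    delta, p = permutation_test_matrix(
        np.asarray(z_stroke, float)[:, None],
        np.asarray(z_control, float)[:, None],
        covariates=covariates,
        n_perm=n_perm,
        seed=seed,
        tails=tails,
    )
    return float(delta[0]), float(p[0])


def fdr_bh(
    p_values: np.ndarray, q_threshold: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance
    flags (classical step-up decision, i.e. q <= threshold at the
    boundary)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, reject


def compare_groups(
    cohort: list[SubjectRecord],
    scheme: ModuleScheme,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    n_perm: int = 10_000,
    q_threshold: float = 0.01,
    subgroup: str = "all",
    seed: int = 0,
    tails: str = "two",
    flip: bool = True,
) -> pd.DataFrame:
    """Edge-wise permutation comparison of stroke vs control connectomes.

    ``subgroup`` restricts the stroke group by lesion laterality ("all",
    "left", "right"); the control group is always used in full. Hemisphere
    standardisation (:func:`flip_hemispheres`) is applied unless the cohort
    is already flipped. Edges touching missing modules in any subject are
    tested on the subjects that carry them (pairwise exclusion) when
    possible, else reported as NaN.

    Returns one row per unordered edge with observed adjusted difference,
    permutation p, BH q, direction, family, and significance flag.
    """
    if subgroup not in ("all", "left", "right"):
        raise ValueError("subgroup must be 'all', 'left' or 'right'")
    stroke = [r for r in cohort if r.group == "stroke"]
    control = [r for r in cohort if r.group == "control"]
    if subgroup != "all":
        stroke = [r for r in stroke if r.lesion_hemisphere == subgroup]
    if flip:
        stroke = [flip_hemispheres(r, scheme) for r in stroke]
    fc_stroke = [compute_fc(r, scheme) for r in stroke]
    fc_control = [compute_fc(r, scheme) for r in control]
    z_a = edge_vector(fc_stroke)
    z_b = edge_vector(fc_control)
    cov = None
    if covariates:
        cov = np.array(
            [[r.covariates[c] for c in covariates] for r in stroke + control],
            dtype=float,
        )

    n_edges = scheme.n_edges
    delta = np.full(n_edges, np.nan)
    p = np.full(n_edges, np.nan)
    complete = ~(np.isnan(z_a).any(axis=0) | np.isnan(z_b).any(axis=0))
    if complete.any():
        delta[complete], p[complete] = permutation_test_matrix(
            z_a[:, complete], z_b[:, complete],
            covariates=cov, n_perm=n_perm, seed=seed, tails=tails,
        )
    # pairwise exclusion for edges with missing values in some subjects
    for e in np.flatnonzero(~complete):
        ok_a = ~np.isnan(z_a[:, e])
        ok_b = ~np.isnan(z_b[:, e])
        if ok_a.sum() < 2 or ok_b.sum() < 2:
            continue
        sub_cov = None
        if cov is not None:
            keep = np.concatenate([ok_a, ok_b])
            sub_cov = cov[keep]
        delta[e], p[e] = permutation_edge_test(
            z_a[ok_a, e], z_b[ok_b, e],
            covariates=sub_cov, n_perm=n_perm, seed=seed + 1 + e, tails=tails,
        )

    q = np.full(n_edges, np.nan)
    sig = np.zeros(n_edges, dtype=bool)
    tested = ~np.isnan(p)
    if tested.any():
        q[tested], sig[tested] = fdr_bh(p[tested], q_threshold)

    pairs = list(scheme.edges())
    names = scheme.names
    return pd.DataFrame(
        {
            "i": [i for i, _ in pairs],
            "j": [j for _, j in pairs],
            "module_i": [names[i] for i, _ in pairs],
            "module_j": [names[j] for _, j in pairs],
            "family": [f.value for f in edge_families(scheme)],
            "delta": delta,
            "p": p,
            "q": q,
            "direction": np.where(delta >= 0, "increase", "decrease"),
            "significant": sig,
        }
    )


def family_direction_counts(results: pd.DataFrame) -> pd.DataFrame:
    """Significant-edge counts per edge family, split by direction (the
    per-figure summary of a group comparison)."""
    sig = results[results["significant"]]
    counts = (
        sig.groupby(["family", "direction"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["increase", "decrease"], fill_value=0)
    )
    counts["total"] = counts.sum(axis=1)
    return counts


def chi_square_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 contingency table, no continuity
    correction, df = 1, two-sided p."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
        raise ValueError("counts must be non-negative with nonzero marginals")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test (equal variances), two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    stat, p = stats.ttest_ind(a, b)
    return float(stat), float(p)


def demographics_tests(subjects: pd.DataFrame) -> pd.DataFrame:
    """Cohort-table tests: chi-square for gender, two-sample t for
    continuous covariates present in both groups.

    ``subjects`` must carry 'group' plus covariate columns (as produced by
    :func:`strokeconn.synthetic.cohort_to_frames`).
    """
    rows = []
    grp = subjects.groupby("group")
    stroke = grp.get_group("stroke")
    control = grp.get_group("control")
    if "gender" in subjects:
        table = np.array(
            [
                [(stroke["gender"] == 0).sum(), (stroke["gender"] == 1).sum()],
                [(control["gender"] == 0).sum(), (control["gender"] == 1).sum()],
            ]
        )
        stat, p = chi_square_2x2(table)
        rows.append({"variable": "gender", "test": "chi2", "stat": stat, "p": p})
    for var in ("age", "MMSE", "education"):
        if var in subjects and subjects[var].notna().all():
            stat, p = two_sample_t(stroke[var], control[var])
            rows.append({"variable": var, "test": "t", "stat": stat, "p": p})
    return pd.DataFrame(rows)
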