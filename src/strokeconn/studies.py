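"""Desk-scale simulation studies of the pipeline's statistical behaviour.

Each function runs one self-contained study on synthetic cohorts and
returns summary numbers: type-I calibration of the edge-wise permutation
test, recovery of the planted stroke direction pattern, detection power
for planted FC-clinical links, lag-estimation accuracy, and the
template-applicability ARI. They are used by the test suite and the
acceptance script; problem sizes default to values that keep each study
within tens of seconds on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocess
from .clinical import spearman
from .connectivity import compute_fc, edge_vector
from .group_stats import fdr_bh, permutation_test_matrix
from .parcellation import build_scheme, flip_hemispheres
from .synthetic import (
    FIGURE_PATTERN_SIGNS,
    ClinLink,
    EffectSpec,
    base_correlation,
    figure_pattern_effect,
    generate_cohort,
)
from .validation import template_partition, detect_communities, adjusted_rand_index

__all__ = [
    "null_calibration",
    "pattern_recovery",
    "clinical_link_power",
    "lag_accuracy",
    "template_ari",
]


def _group_edges(cohort, scheme):
    stroke = [flip_hemispheres(r, scheme) for r in cohort
              if r.group == "stroke"]
    control = [r for r in cohort if r.group == "control"]
    z_a = edge_vector([compute_fc(r, scheme) for r in stroke])
    z_b = edge_vector([compute_fc(r, scheme) for r in control])
    cov = np.array(
        [[r.covariates["age"], r.covariates["gender"]]
         for r in stroke + control]
    )
    return z_a, z_b, cov


def null_calibration(
    n_cohorts: int = 500,
    n_per_group: int = 30,
    T: int = 150,
    n_perm: int = 500,
    alpha: float = 0.05,
    q_threshold: float = 0.01,
    seed: int = 0,
) -> dict:
    """Type-I behaviour of the permutation test on null cohorts.

    Generates ``n_cohorts`` two-group cohorts with no planted effects,
    tests every edge of the 28-module matrix, and pools: the per-edge
    rejection rate at ``alpha`` (should sit near alpha) and the mean
    BH-significant edge count per cohort at ``q_threshold`` (should be
    well below one under FDR control).
    """
    scheme = build_scheme("seven")
    base = base_correlation(scheme)
    rng = np.random.default_rng(seed)
    rejections = 0
    total = 0
    sig_counts = []
    for c in range(n_cohorts):
        cohort = generate_cohort(
            scheme, n_per_group, n_per_group, T=T,
            seed=int(rng.integers(2**31)), base=base,
        )
        z_a, z_b, cov = _group_edges(cohort, scheme)
        _, p = permutation_test_matrix(
            z_a, z_b, covariates=cov, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        rejections += int((p <= alpha).sum())
        total += p.size
        _, flags = fdr_bh(p, q_threshold)
        sig_counts.append(int(flags.sum()))
    return {
        "n_cohorts": n_cohorts,
        "n_tests": total,
        "rejection_rate": rejections / total,
        "mean_significant_count": float(np.mean(sig_counts)),
    }


def pattern_recovery(
    delta: float = 0.25,
    n_per_group: int = 60,
    T: int = 200,
    n_perm: int = 1000,
    q_threshold: float = 0.01,
    seed: int = 0,
) -> dict:
    """Recovery of the planted stroke direction pattern.

    Plants the full direction pattern at magnitude ``delta``, runs the
    group comparison, and measures the sign agreement between detected
    (FDR-significant) edges and the plant, plus whether every family's
    dominant detected direction matches its planted sign.
    """
    scheme = build_scheme("seven")
    cohort = generate_cohort(
        scheme, n_per_group, n_per_group, T=T,
        effect=figure_pattern_effect(delta), seed=seed,
    )
    from .group_stats import compare_groups

    res = compare_groups(cohort, scheme, n_perm=n_perm,
                         q_threshold=q_threshold, seed=seed)
    sig = res[res["significant"]]
    planted_sign = {f.value: s for f, s in FIGURE_PATTERN_SIGNS.items()}
    observed = np.where(sig["delta"] > 0, 1, -1)
    planted = sig["family"].map(planted_sign).to_numpy()
    agreement = float((observed == planted).mean()) if len(sig) else float("nan")
    families_ok = 0
    n_families = len(planted_sign)
    for fam, s in planted_sign.items():
        fam_sig = sig[sig["family"] == fam]
        if len(fam_sig):
            dominant = 1 if (fam_sig["delta"] > 0).mean() >= 0.5 else -1
            families_ok += int(dominant == s)
    return {
        "n_detected": int(len(sig)),
        "sign_agreement": agreement,
        "families_matching_plant": families_ok,
        "n_families": n_families,
    }


def clinical_link_power(
    rho: float = 0.41,
    n_stroke: int = 65,
    T: int = 235,
    n_replicates: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Monte-Carlo detection rate for a planted FC-clinical association.

    Plants a severity link of target Spearman ``rho`` on one
    inter-hemispheric cerebellar edge, regenerates the stroke group
    ``n_replicates`` times, and counts how often the exploratory Spearman
    test flags the edge at ``alpha`` two-sided.
    """
    scheme = build_scheme("seven")
    names = scheme.names
    i = names.index("Cb-IL-VN")
    j = names.index("Cb-CL-VN")
    edge = (min(i, j), max(i, j))
    link = ClinLink(edge=edge, variable="NIHSS", rho=rho)
    effect = EffectSpec(clin_links=(link,))
    e_index = [k for k, pair in enumerate(scheme.edges()) if pair == edge][0]
    rng = np.random.default_rng(seed)
    detected = 0
    rhos = []
    for _ in range(n_replicates):
        cohort = generate_cohort(
            scheme, n_stroke, 2, T=T, effect=effect,
            seed=int(rng.integers(2**31)),
        )
        stroke = [flip_hemispheres(r, scheme) for r in cohort
                  if r.group == "stroke"]
        z = edge_vector([compute_fc(r, scheme) for r in stroke])
        nihss = np.array([r.covariates["NIHSS"] for r in stroke])
        r_hat, p = spearman(z[:, e_index], nihss)
        rhos.append(r_hat)
        detected += int(p < alpha)
    return {
        "n_replicates": n_replicates,
        "detection_rate": detected / n_replicates,
        "mean_realized_rho": float(np.mean(rhos)),
        "target_rho": rho,
    }


def lag_accuracy(T: int = 400, TR: float = 2.0, seed: int = 0) -> dict:
    """Accuracy of the time-shift lag machinery on planted lags.

    Plants an integer lag of 2 TR and a sub-sample lag of 0.5 TR on
    band-limited signals; reports the integer-resolution recovery error,
    the post-correction re-estimated lag, and the sub-sample estimation
    error (seconds).
    """
    rng = np.random.default_rng(seed)
    noise = pd.DataFrame({"s": rng.standard_normal(T)})
    ref = preprocess.bandpass(noise, TR, 0.01, 0.08)["s"].to_numpy()
    t = np.arange(T) * TR

    lagged_int = np.interp(t - 2 * TR, t, ref)
    tau_int = preprocess.estimate_lag(lagged_int, ref, TR)
    integer_error = abs(round(tau_int / TR) - 2)

    ts = pd.DataFrame({"lagged": lagged_int})
    lag_map = preprocess.estimate_lag_map(ts, TR, reference=ref, integer=True)
    fixed = preprocess.apply_lag_correction(ts, lag_map, TR)
    tau_after = preprocess.estimate_lag(fixed["lagged"].to_numpy(), ref, TR)
    roundtrip_lag = abs(round(tau_after / TR))

    lagged_sub = np.interp(t - 0.5 * TR, t, ref)
    tau_sub = preprocess.estimate_lag(lagged_sub, ref, TR)
    subsample_error = abs(tau_sub - 0.5 * TR)

    return {
        "integer_lag_error_tr": float(integer_error),
        "roundtrip_residual_lag_tr": float(roundtrip_lag),
        "subsample_error_s": float(subsample_error),
        "subsample_tolerance_s": 0.25 * TR,
    }


def template_ari(
    n_stroke: int = 20, T: int = 300, seed: int = 0
) -> dict:
    """Template-applicability check on a synthetic patient group: ARI
    between the Louvain partition of the group-mean z matrix and the
    scheme's network template."""
    scheme = build_scheme("seven")
    cohort = generate_cohort(scheme, n_stroke, 2, T=T, seed=seed)
    stroke = [flip_hemispheres(r, scheme) for r in cohort
              if r.group == "stroke"]
    z = edge_vector([compute_fc(r, scheme) for r in stroke])
    m = scheme.total_count
    mean_z = np.zeros((m, m))
    iu = np.triu_indices(m, 1)
    mean_z[iu] = z.mean(axis=0)
    mean_z += mean_z.T
    part = detect_communities(mean_z, seed=seed)
    ari = adjusted_rand_index(part, template_partition(scheme))
    return {"ari": float(ari), "n_communities": part.n_communities}
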