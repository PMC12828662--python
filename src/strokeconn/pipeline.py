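"""End-to-end orchestration: simulate -> preprocess -> connect -> compare
-> correlate -> validate.

:class:`RunConfig` is a declarative description of one run (scheme
condition, cohort sizes, preprocessing toggles, statistical settings,
seed); :func:`run_pipeline` executes the stages in order and writes every
stage output plus a JSON report. Every output is derivable from the config
and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical, group_stats, preprocess, synthetic, validation
from .connectivity import compute_fc, edge_vector
from .parcellation import build_scheme, flip_hemispheres
from .synthetic import ClinLink, EffectSpec, figure_pattern_effect

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "preprocess_subject"]


@dataclass
class RunConfig:
    """Declarative settings for one pipeline run."""

    condition: str = "seven"
    n_stroke: int = 65
    n_control: int = 72
    n_volumes: int = 240  # raw volumes before the initial discard
    TR: float = 2.0
    # planted effect (synthetic mode)
    effect_delta: float = 0.25
    clin_links: list = field(default_factory=lambda: [
        # paper-style defaults: cerebrocerebellar SMN edge vs lesion size,
        # cerebellar inter-hemispheric VN edge vs stroke severity
        {"edge": "auto_lesion", "variable": "lesion_size", "rho": -0.41},
        {"edge": "auto_nihss", "variable": "NIHSS", "rho": 0.33},
    ])
    # preprocessing toggles
    discard_k: int = 5
    gsr: bool = True
    scrubbing: bool = False
    fd_threshold: float = 0.5
    bandpass: bool = True
    bp_low: float = 0.01
    bp_high: float = 0.08
    lag_correction: bool = True
    max_lag_tr: float = 4.0
    # statistics
    n_perm: int = 10_000
    q_threshold: float = 0.01
    covariates: tuple = ("age", "gender")
    clin_covariates: tuple = (
        "age", "gender", "MMSE", "education", "days_since_onset",
    )
    clin_alpha: float = 0.01
    subgroup: str = "all"
    seed: int = 0
    outdir: str = "strokeconn_run"

    def validate(self) -> None:
        if self.condition not in ("seven", "seventeen"):
            raise ValueError("condition must be 'seven' or 'seventeen'")
        if self.n_volumes - self.discard_k < 50:
            raise ValueError("too few volumes after the initial discard")
        if not 0 <= self.bp_low < self.bp_high < 1 / (2 * self.TR):
            raise ValueError("invalid band-pass corners")
        if self.subgroup not in ("all", "left", "right"):
            raise ValueError("subgroup must be all/left/right")
        if self.n_perm < 100:
            raise ValueError("need at least 100 permutations")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["clin_covariates"] = list(self.clin_covariates)
        return d


def _default_effect(config: RunConfig, scheme) -> EffectSpec:
    """Planted effect with paper-style direction pattern and clinical
    links resolved onto concrete edges of the scheme."""
    links = []
    names = scheme.names
    for spec in config.clin_links:
        edge = spec["edge"]
        if edge == "auto_lesion":
            # ipsilesional cerebral SMN <-> contralesional cerebellar SMN
            smn = "SMN" if config.condition == "seven" else "SMN A"
            i = names.index(f"Ce-IL-{smn}")
            j = names.index(f"Cb-CL-{smn}")
        elif edge == "auto_nihss":
            # inter-hemispheric cerebellar VN edge
            vn = "VN" if config.condition == "seven" else "VN B"
            i = names.index(f"Cb-IL-{vn}")
            j = names.index(f"Cb-CL-{vn}")
        else:
            i, j = edge
        links.append(ClinLink(edge=(min(i, j), max(i, j)),
                              variable=spec["variable"], rho=spec["rho"]))
    return figure_pattern_effect(delta=config.effect_delta, clin_links=links)


def preprocess_subject(
    record: synthetic.SubjectRecord, config: RunConfig
) -> synthetic.SubjectRecord:
    """Apply the in-scope preprocessing stages to one subject's module
    series, in pipeline order."""
    ts = preprocess.discard_initial(record.module_ts, config.discard_k)
    motion = record.motion_params
    if motion is not None:
        motion = preprocess.discard_initial(motion, config.discard_k)
        if config.scrubbing:
            ts, keep = preprocess.scrub(ts, motion, config.fd_threshold)
            motion = motion.loc[keep].reset_index(drop=True)
    regressors = []
    if motion is not None:
        regressors.append(preprocess.friston24(motion))
    if config.gsr:
        regressors.append(
            pd.DataFrame({"global_signal": np.asarray(ts, float).mean(axis=1)})
        )
    if regressors:
        ts = preprocess.nuisance_regress(ts, pd.concat(regressors, axis=1))
    if config.bandpass:
        ts = preprocess.bandpass(ts, record.TR, config.bp_low, config.bp_high)
    if config.lag_correction:
        lag_map = preprocess.estimate_lag_map(
            ts, record.TR, max_lag=config.max_lag_tr * record.TR,
            integer=True,  # shift by whole volumes
        )
        ts = preprocess.apply_lag_correction(ts, lag_map, record.TR)
    return dataclasses.replace(record, module_ts=ts)


def run_pipeline(
    config: RunConfig,
    cohort: list | None = None,
) -> dict:
    """Execute all stages and write outputs to ``config.outdir``.

    With no ``cohort`` a synthetic one is generated from the config's
    planted-effect settings. Returns the run report (also written as
    ``report.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scheme = build_scheme(config.condition)
    scheme.to_tsv(outdir / "scheme.tsv")

    if cohort is None:
        logger.info("simulate: generating synthetic cohort")
        effect = _default_effect(config, scheme)
        cohort = synthetic.generate_cohort(
            scheme,
            n_stroke=config.n_stroke,
            n_control=config.n_control,
            T=config.n_volumes,
            effect=effect,
            seed=config.seed,
            TR=config.TR,
        )
    synthetic.cohort_to_frames(cohort).to_csv(
        outdir / "subjects.tsv", sep="\t", index=False
    )

    logger.info("preprocess: %d subjects", len(cohort))
    excluded = []
    kept = []
    for rec in cohort:
        if rec.motion_params is not None:
            qc = preprocess.motion_qc(rec.motion_params)
            if not qc.keep:
                excluded.append({"id": rec.id, "reason": qc.reason})
                logger.warning("excluding %s: %s", rec.id, qc.reason)
                continue
        kept.append(preprocess_subject(rec, config))
    cohort = kept

    logger.info("flip: standardising hemispheres")
    cohort = [flip_hemispheres(r, scheme) for r in cohort]

    logger.info("connect: Fisher-z matrices")
    matrices = {r.id: compute_fc(r, scheme) for r in cohort}
    missing_log = {
        rid: sorted(fc.missing_modules)
        for rid, fc in matrices.items() if fc.missing_modules
    }

    logger.info("compare: permutation tests (%d permutations)", config.n_perm)
    results = group_stats.compare_groups(
        cohort, scheme,
        covariates=config.covariates,
        n_perm=config.n_perm,
        q_threshold=config.q_threshold,
        subgroup=config.subgroup,
        seed=config.seed,
        flip=False,  # already standardised above
    )
    results.to_csv(outdir / "edge_results.tsv", sep="\t", index=False)
    counts = group_stats.family_direction_counts(results)
    counts.to_csv(outdir / "family_counts.tsv", sep="\t")

    logger.info("correlate: clinical associations")
    clin = clinical.correlate_significant_edges(
        results, cohort, scheme,
        covariates=config.clin_covariates,
        alpha_unc=config.clin_alpha,
        flip=False,
    )
    clin.to_csv(outdir / "clinical_correlations.tsv", sep="\t", index=False)

    logger.info("validate: template modularity check")
    stroke_z = edge_vector(
        [matrices[r.id] for r in cohort if r.group == "stroke"]
    )
    mean_z = np.zeros((scheme.total_count, scheme.total_count))
    iu = np.triu_indices(scheme.total_count, k=1)
    mean_z[iu] = np.nanmean(stroke_z, axis=0)
    mean_z = mean_z + mean_z.T
    template_check = validation.validate_template(mean_z, scheme, seed=config.seed)

    demo = group_stats.demographics_tests(synthetic.cohort_to_frames(cohort))

    report = {
        "config": config.to_dict(),
        "n_stroke": sum(r.group == "stroke" for r in cohort),
        "n_control": sum(r.group == "control" for r in cohort),
        "excluded_subjects": excluded,
        "missing_modules": missing_log,
        "demographics": demo.to_dict(orient="records"),
        "n_edges": int(len(results)),
        "n_significant": int(results["significant"].sum()),
        "family_counts": {
            fam: {
                "increase": int(row["increase"]),
                "decrease": int(row["decrease"]),
            }
            for fam, row in counts.iterrows()
        },
        "clinical": {
            "n_tested": int(len(clin)),
            "n_flagged_unc": int(clin["significant_unc"].sum()) if len(clin) else 0,
            "n_flagged_fdr": int(clin["significant_fdr"].sum()) if len(clin) else 0,
        },
        "template_validation": {
            "ari": template_check["ari"],
            "modularity": template_check["modularity"],
            "n_communities": template_check["n_communities"],
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "template_validation.json").write_text(
        json.dumps(template_check, indent=2, sort_keys=True)
    )
    return report
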