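# Methods

## The model

`strokeconn` treats the brain as a set of M functional *modules*: each of
the 7 (or 17) canonical resting-state networks, split by structure
(cerebrum / cerebellum) and hemisphere (ipsilesional / contralesional),
giving M = 28 or M = 66. In the fine scheme the cerebellar VN A module is
absent (too few voxels in the reference cerebellar parcellation), so the
66 modules decompose as 34 cerebral + 32 cerebellar. A subject's
connectome is the M×M matrix of Fisher-z-transformed Pearson correlations
between module-mean BOLD series. All group statistics operate on the
M(M−1)/2 unordered edges, each labelled with one of ten families defined
by the two endpoints' structures and hemispheres; for cerebro-cerebellar
edges the family records whether the cerebellar endpoint is contralateral
or ipsilateral to the cerebral one, since crossed cerebellar diaschisis is
specifically a crossed (contralateral) phenomenon.

Matrix ordering is a package convention (cerebrum before cerebellum, IL
block before CL, networks in canonical listing order) chosen so that
serialised matrices from different runs are comparable. Subjects with a
right-hemisphere lesion are standardised by swapping each module with its
opposite-hemisphere twin — the module-level equivalent of the image-level
left-right flip, exact under a hemisphere-symmetric atlas. Controls use
left = ipsilesional by convention.

## Statistical procedures

**Edge-wise group test.** Subjects' edge values are residualised on
[1 | covariates] pooled over both groups (Freedman–Lane-style: the
adjustment is estimated under the groupless null, so group labels remain
exchangeable). The statistic is the stroke-minus-control mean of the
residuals; its null distribution comes from random reallocation of
subjects to groups, sharing one set of label permutations across all edges
and computing each permutation's group means by an indicator-matrix
multiply. Two-tailed p-values carry the +1 correction,
p = (#{|Δπ| ≥ |Δ|} + 1)/(P + 1), so p ≥ 1/(P+1) always. One-tailed
variants and the covariate set are configurable. FDR control is
Benjamini–Hochberg across all edges of one matrix condition jointly; the
significance decision is the classical step-up rule (p(k) ≤ kq/m).

A practical resolution constraint follows from the +1 correction: a
*single* disrupted edge can only pass BH at q = 0.01 over 378 edges if
1/(P+1) ≤ 0.01/378, i.e. P ≳ 40,000. Broad disruption patterns raise the
step-up threshold and are detectable at much smaller P. Tests and studies
use P between 500 and 40,000 accordingly; the pipeline default is 10,000.

**Clinical correlations.** For each FDR-significant edge, Spearman
correlation with NIHSS and lesion size within the stroke group only,
flagged at exploratory p < 0.01 (two-sided, t approximation) plus an
optional BH pass at q < 0.05 per (variable × condition). The adjusted
variant has no canonical definition; here x, y and the covariates are all
rank-transformed (average ranks), the ranked targets are residualised on
the ranked covariates with intercept, and the residuals are Pearson
correlated with df = n − 2 − k. With an empty covariate set this reduces
exactly to plain Spearman.

**Power.** Analytic power for a two-sided correlation test uses the
Fisher-z approximation Φ(|atanh ρ|·√(n−3) − z₁₋α/₂); a Monte-Carlo test
confirms agreement within ±3 percentage points at n = 65. At n = 65,
ρ = 0.41, α = 0.01 the formula gives 80.3% — the smallest n reaching 80%
for that effect is 65.

**Template validation.** Louvain modularity maximisation (seeded,
positive weights only; negative z entries are zeroed because modularity is
defined for non-negative weights) on the patient group's mean z-matrix,
compared with the template partition — one community per network, pooling
hemispheres and structures — by the Hubert–Arabie ARI.

## Preprocessing conventions

Stage order: discard initial volumes (default 5) → motion QC → nuisance
regression → band-pass → lag correction.

- **Framewise displacement** is the Power convention: sum of absolute
  frame-to-frame differences of the six realignment parameters, rotations
  converted to arc length on a 50 mm sphere. Exclusion at >3 mm
  translation, >3° rotation, or mean FD >0.5 mm. Frame censoring
  (scrubbing) exists but is off by default, matching the main pipeline;
  it is exposed for robustness variants.
- **Band-pass** is a hard FFT mask on [0.01, 0.08] Hz (zero-phase, DC
  removed): pass-band power is preserved exactly, stop-band power removed
  exactly, and the operator is linear.
- **Hemodynamic lag** is estimated per series as the argmax over
  integer-TR shifts of the cross-correlation with a reference (default:
  the global mean series), refined by parabolic interpolation through the
  peak, ties broken toward zero, search range ±4·TR. Positive lag means
  the series is delayed. Correction resamples each series at t + τ by
  linear interpolation with edge replication. The pipeline applies
  correction at whole-volume resolution (integer TR) and leaves a series
  unshifted when its peak cross-correlation with the reference is below
  0.3 — such lags are not reliably estimable, and shifting by a noise
  estimate corrupts the series (visible after global-signal regression,
  which removes most module-to-reference coupling). Reference choice,
  search range, and the mask threshold are conventions, configurable in
  `estimate_lag_map`.

## The synthetic-data generator

The generator is the package's study-condition definition, not a test
fixture. Controls draw T×M samples from a zero-mean multivariate normal
whose correlation target has block structure: 0.5 between modules of the
same network, 0.6 for homotopic pairs (same network and structure,
opposite hemispheres), 0.1 otherwise. The stroke target adds edge shifts —
by family or by explicit edge — and is projected back to the correlation
cone by eigenvalue clipping (floor 1e-4) with unit-diagonal rescaling,
iterated to convergence. The default planted pattern puts |Δr| = 0.25 on
every edge with the stroke phenotype's direction signs (cerebral intra +,
cerebral inter −, cerebellar +, ipsilesional cerebro-cerebellar −,
contralesional cerebro-cerebellar +); this family-wide target happens to
remain positive-definite, so planted directions are exact. Bulk shifts
that leave the cone (e.g. +0.3 on one entire family) are legitimately
shrunk and smeared by the projection.

FC–clinical links are planted by per-subject modulation of the target in
Fisher-z space: z_edge += s·(standardised clinical score), with the slope
s chosen from the target Spearman ρ via Pearson's sin relation
(ρ_P = 2 sin(πρ_S/6)) and the sampling noise of a correlation estimated
from T volumes (sd ≈ 1/√(T−3)). This modulates the *generative* target,
so the full pipeline — extraction, z-transform, ranking — is exercised;
at T = 235 and n = 65 the realised Spearman correlations centre on the
planted value (calibration study: mean realised ρ ≈ 0.41 for target
0.41).

Covariates match the study cohort's published marginals (age N(58,8),
NIHSS N(3.23,2.80) truncated at 0 and rounded, MMSE truncated N(29.5,1.2),
lesion size log-uniform on [16, 1459] voxels, 36/65 left lesions; onset
days N(6.6,4.7)). Defaults T = 235 kept volumes at TR = 2 s — a typical
rs-fMRI run length; scan duration and per-module voxel counts are
conventions, as is the voxel fixture's geometry (labels packed into a
small grid, equal voxels per module).

Module series are temporally *white* by default: correct for every
correlation-based statistic, but lags are then unidentifiable, so when
per-module lags are planted the latent series are moving-average smoothed
first. Band-passing white series reduces the effective temporal dof,
which inflates FC sampling variance without biasing the permutation test
(it is calibrated by construction).

**What the synthetic cohorts do not show.** No hemodynamic response
function, no spatial autocorrelation, no physiological noise, no real
lesion geometry, and subject-level FC heterogeneity only where links are
planted. Passing recovery tests therefore demonstrates the statistical
machinery is correct and calibrated under its assumed model — not that
the effect sizes or the template ARI of any real cohort will match.
Notably, under the maximal family-wide plant the cerebellar blocks merge
and the Louvain/ARI check drops: decreased segregation and template
agreement trade off, in the generator as in principle in data.

## Numerical choices

- Correlations within 1e-7 of ±1 are clipped before arctanh (noise-free
  fixtures would otherwise produce infinities); anything beyond the window
  errors.
- Constant or fully lesioned module series are flagged missing; edges
  touching them are excluded pairwise from the group test (tested on the
  subjects that carry them), never imputed or zeroed.
- Rank-deficient nuisance or covariate designs raise errors naming the
  collinear columns.
- Lag ties are broken toward zero shift; parabolic refinement is limited
  to ±half a shift step; |τ| < 1e-9 s snaps to 0.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); derived sub-seeds are drawn below 2^31.

## Problem sizes used in the studies

The simulation studies (`strokeconn.studies`) run at desk scale: type-I
calibration uses 500 null cohorts of 30+30 subjects, T = 150, P = 500
(189,000 pooled null p-values); pattern recovery one cohort of 60+60 at
T = 200, P = 1000; clinical-link power 100 replicate stroke groups of
n = 65 at T = 235; all chosen to finish in tens of seconds on one CPU
while keeping Monte-Carlo error small relative to the margins being
checked.

## Known limitations

- Real-data mode consumes any integer-label atlas plus a lookup table; the
  canonical cortical/cerebellar atlas volumes themselves are not shipped.
- The exact time-shift-analysis variant of the original studies (reference
  definition, search range, interpolation) is not public; the defaults
  here are documented conventions.
- Whether the published permutation test was one- or two-tailed, and the
  exact covariate-handling scheme, are not specified; both are exposed as
  options (defaults: two-tailed, pooled residualisation).
- The ARI of a data-driven partition against the template depends on the
  group matrix and the community-detection resolution; the value computed
  on synthetic cohorts is a surrogate, not a reproduction of any
  empirical value.
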