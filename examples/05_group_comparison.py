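"""Edge-wise permutation comparison of a cohort carrying the planted
stroke direction pattern, summarised per edge family."""

import strokeconn as sc

scheme = sc.build_scheme("seven")
cohort = sc.generate_cohort(
    scheme, n_stroke=40, n_control=40, T=200,
    effect=sc.figure_pattern_effect(delta=0.25), seed=2,
)
results = sc.compare_groups(
    cohort, scheme, covariates=("age", "gender"),
    n_perm=2000, q_threshold=0.01, seed=2,
)
print(f"{results.significant.sum()} of {len(results)} edges significant "
      "at q < 0.01 (BH over all 378 edges, age and gender adjusted)")

counts = sc.family_direction_counts(results)
print("\nsignificant edges per family and direction (stroke vs control):")
print(counts.to_string())
print("\nThe pattern mirrors the planted phenotype: increased "
      "intra-hemispheric / decreased inter-hemispheric cerebral edges, "
      "increased cerebellar edges, decreased ipsilesional and increased "
      "contralesional cerebro-cerebellar edges.")
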