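"""Robustness of an asymmetry effect across sparsity thresholds.

Re-thresholds each subject's weighted networks from S = 0.25 to 0.50
(step 0.01), integrates degree centrality over the range (trapezoid
AUC), and tests the case-control difference of the AUC asymmetry
(4999 permutations, so the minimum attainable p clears the node-tier
BH threshold). A real effect should not depend on the single threshold
chosen for the main analysis.
"""

from hemisnet import AnalysisConfig, SimConfig, generate_cohort, run_sparsity_sweep

table, subjects = generate_cohort(
    SimConfig(
        n_datasets=4, n_cases=40, n_controls=40, rng_seed=6,
        coupling_alpha={("fusiform", "R", "case"): 0.6},
    )
)
cfg = AnalysisConfig(n_permutations=4999, rng_seed=6)
curves, results = run_sparsity_sweep(
    table, subjects, cfg, node_metrics=("degree_centrality",)
)

print(f"sweep: {len(curves.thresholds)} thresholds from "
      f"{curves.thresholds[0]} to {curves.thresholds[-1]}")
top = sorted(results, key=lambda r: r.p_empirical)[:3]
for r in top:
    print(
        f"  {r.node:24s} AUC-HD coef {r.coefficient:+.3f}  d {r.cohens_d:+.2f}  "
        f"p {r.p_empirical:.4g}  significant={r.significant}"
    )
print("the coupled region (fusiform) should lead with a negative coefficient,")
print("showing the effect is not an artifact of the S = 0.4 choice")
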