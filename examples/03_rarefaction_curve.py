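"""Species accumulation over sampling units, with bootstrap CI.

For one scenario, interpolates expected richness below the observed 17
plots, passes exactly through the observed richness, and extrapolates to
twice the sample size with the Chao2-type estimate of undetected
species. The 95% band comes from resampling plots with replacement.
"""

from chorus_effort import (
    Scenario,
    SimulationConfig,
    bootstrap_ci,
    community_matrix,
    default_community,
    simulate_detections,
    subset_records,
)

config = SimulationConfig(seed=11)
records, _ = simulate_detections(default_community(50, seed=11), config)
scenario = Scenario(6, "both", 2)
matrix = community_matrix(subset_records(records, scenario), list(config.plot_ids))
print(f"scenario {scenario}: T={matrix.T} plots, S_obs={matrix.S_obs}, "
      f"Q1={matrix.Q1} uniques, Q2={matrix.Q2} duplicates")

curve = bootstrap_ci(matrix, B=200, seed=1)
print("\n   t  estimate   95% CI        kind")
for p in curve.points:
    if p.t in (1, 5, 9, 13, 17, 25, 34):
        print(f"  {p.t:>2}  {p.estimate:7.2f}  [{p.ci_lower:6.2f}, {p.ci_upper:6.2f}]  {p.kind}")
print("\nthe t=17 row is the observed pooled richness; beyond it the curve"
      "\napproaches the estimated asymptotic richness of the study area")
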