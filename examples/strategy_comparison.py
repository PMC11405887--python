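"""Compare the eight replication x loading-control strategies on one dataset.

The same simulated experiment (true group effect present, real gel-to-gel
variance) is analysed by every combination of replicate handling
(first-only, independent, mean, random effect) and loading-control handling
(ratio, covariate).
"""

from blotkit import SimulationParams, run_all_strategies, simulate_dataset

data = simulate_dataset(SimulationParams(group_effects=(0.0, 1.5), seed=7))
result = run_all_strategies(data, alpha=0.05, with_power=True, n_sim=300, seed=2)

print(f"{'strategy':32s} {'effect size':>11s} {'p':>8s} {'power':>7s}")
for label, cell in result.cells.items():
    print(f"{label:32s} {cell.effect_size_std:11.3f} {cell.p_group:8.4f} "
          f"{cell.observed_power:7.3f}")
print("\n'independent' looks best but is pseudoreplication (n is tripled);"
      "\n'random_effect'+'covariate' gets high power legitimately by"
      " modelling gel-run variance instead of ignoring or averaging it.")
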