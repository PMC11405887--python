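"""Fit the recommended mixed model to a replicated densitometry experiment.

Simulates 2 groups x 10 subjects x 3 technical replicate gels with a true
group effect of 1.5 density units, then fits the recommended strategy:
loading control as a covariate, subject and replicate gel as crossed random
intercepts (REML).
"""

from blotkit import (
    Loading,
    Replication,
    SimulationParams,
    StrategySpec,
    fit_lmm,
    prepare_table,
    simulate_dataset,
    summarize_groups,
)

data = simulate_dataset(SimulationParams(group_effects=(0.0, 1.5), seed=7))
table = prepare_table(data, StrategySpec(Replication.RANDOM_EFFECT, Loading.COVARIATE))
fit = fit_lmm(table)

print("fixed effects (density units):")
for name, b in fit.beta.items():
    print(f"  {name:12s} {b:8.3f}  (se {fit.se[name]:.3f})")
print("variance components:")
for name, v in fit.variance_components.items():
    print(f"  {name:12s} {v:8.3f}")
print(f"group p-value (likelihood ratio): {fit.p_group:.4f}")
print(f"standardized effect size:         {fit.effect_size_std:.3f}")
print()
for g in summarize_groups(data).groups:
    print(f"group {g.group}: mean {g.mean:.2f}, sem {g.sem:.2f}, "
          f"95% CI [{g.ci95_low:.2f}, {g.ci95_high:.2f}] (n={g.n} subjects)")
print("\nThe group contrast estimates the simulated 1.5-unit effect; the"
      " variance components separate subject, gel-run and lane noise.")
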