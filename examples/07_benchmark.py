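"""Desk-scale run of the synthetic hybrid-method benchmark.

Generates Gaussian datasets per the stated design, applies the six-method
roster, and aggregates good-solution rates (diversity within 0.1% of the
best attained per dataset) and restriction labels.
"""

from anticlustering import Sim2Config, run_simulation

cfg = Sim2Config(reps_per_K=5, restarts=100, seed=2)  # 20 datasets; scale up at will
table = run_simulation(cfg)

agg = (
    table.groupby("method")
    .agg(good_pct=("good", lambda s: 100 * s.mean()),
         mean_diversity=("diversity", "mean"))
    .sort_values("good_pct", ascending=False)
)
print(agg.round(2).to_string())
print("\nrestriction labels:",
      table.drop_duplicates(["K", "N", "P", "sd"])["restriction"].value_counts().to_dict())
# Every method is scored at the Pareto entry with maximum dispersion, which
# the hybrids guarantee to be the exact optimum; "good_pct" asks how often
# a method's diversity is within 0.1% of the best across methods.
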