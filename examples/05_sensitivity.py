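"""Sensitivity analyses: tornado, PSA/CEAC, subgroups, scenarios.

Sizes are kept small so the script runs in about a minute; the package
accepts larger n and draw counts for production analyses.
"""

from gcrss import EngineConfig, default_parameter_set, generate_life_table, run_psa, run_scenario, run_subgroup, tornado

ps = default_parameter_set()
lt = generate_life_table(seed=1)
cfg = EngineConfig(parameter_set=ps, life_table=lt, n=10_000, seed=2)

names = ["rr_progression_after_surgery", "cost_surgery", "cost_endoscopy",
         "spec_atrophy_serology", "utility_stage4", "cost_serology"]
print("one-way sensitivity of the 40-GCRSS vs no-screening ICER:")
df = tornado(cfg, parameter_names=names)
print(df.to_string(index=False))
print(f"(base-case ICER {df.attrs['base_icer']:,.0f} $/QALY; the span ranks "
      "the tornado bars)")

draws, ceac = run_psa(n_draws=100, n_individuals_per_draw=3_000, seed=3,
                      parameter_set=ps, life_table=lt,
                      wtp_grid=[0.0, 10_000.0, 37_655.0])
print("\nCEAC (probability each strategy is optimal by net monetary benefit):")
print(ceac.table.pivot(index="wtp", columns="strategy",
                       values="probability").to_string())

sub = run_subgroup("heavy", ("none", 40), seed=4, parameter_set=ps,
                   life_table=lt, n=10_000)
none, scr = sub["no screening"], sub["40-GCRSS"]
print(f"\nheavy smokers, n=10,000: {none.gc_cases} cases unscreened vs "
      f"{scr.gc_cases} under 40-GCRSS "
      f"({1 - scr.gc_cases / none.gc_cases:.0%} reduction)")

rep = run_scenario("healthy_china_2030", cfg)
print(f"\nhealthy-china-2030 (20% Hp and smoking prevalence): "
      f"ICER ${rep['icer']:,.0f}/QALY, below the ${rep['wtp_threshold']:,.0f} "
      f"threshold: {rep['below_threshold']}")
rep = run_scenario("surgery_rr_sweep", cfg, rr_grid=[0.5, 0.7, 0.9, 1.0])
print("post-surgery progression RR sweep -> ICER:",
      [f"{i:,.0f}" for i in rep["icers"]],
      "| threshold crossing at RR =", rep["crossing_rr"])
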