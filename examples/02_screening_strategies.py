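"""Risk-stratified screening at seven starting ages: benefit and harm.

Each cohort shares the no-screening cohort's individuals and random
substreams (common random numbers), so differences between rows are
strategy effects.  Earlier starting ages avert more gastric-cancer deaths
at the price of many more endoscopies; the benefit-to-harm ratio
(complication events per death averted) rises with the starting age.
"""

from gcrss import comparative_metrics, default_parameter_set, generate_life_table, simulate_cohort
from gcrss.natural_history import build_arrays

ps = default_parameter_set()
lt = generate_life_table(seed=1)
arr = build_arrays(ps, lt)
n, seed = 50_000, 1

ref, _ = simulate_cohort(n, None, ps, lt, seed, arrays=arr)
print(f"no screening: {ref.gc_cases} cases, {ref.gc_deaths} GC deaths "
      f"(n={n:,})\n")
hdr = f"{'start':>5} {'averted':>8} {'endoscopies':>12} {'NNS':>5} {'B:H':>6} {'stage I %':>9}"
print(hdr)
for start in (40, 45, 50, 55, 60, 65, 70):
    res, _ = simulate_cohort(n, start, ps, lt, seed, arrays=arr)
    m = comparative_metrics(res, ref)
    rep = m.report()
    print(f"{start:>5} {m.deaths_averted:>8} {res.endoscopies:>12,} "
          f"{rep['nns']:>5} {rep['benefit_to_harm_ratio']:>6.3f} "
          f"{100 * res.stage_counts[0] / res.gc_cases:>9.1f}")
print("\nStage I share at diagnosis rises sharply under screening "
      f"(unscreened: {100 * ref.stage_counts[0] / ref.gc_cases:.1f}%): "
      "endoscopy finds asymptomatic early disease before it surfaces.")
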