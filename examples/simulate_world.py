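"""Generate a small synthetic deployment and look at what it contains.

A "world" bundles per-seal daily truth (position, condition expressed as
drift rate DR, its daily change dDR = foraging success), summarised
dives in the satellite-tag format, noisy ARGOS fixes and a bathymetry
grid.  Everything downstream is testable against the truth table.
"""

from driftforage import SimConfig, simulate_world

cfg = SimConfig(n_seals=4, days_per_seal=60, seed=7)
bundle = simulate_world(cfg)

dives = bundle.dives
print(f"seals: {cfg.n_seals}, days each: {cfg.days_per_seal}")
print(f"dives generated: {len(dives)}, transmitted: {int(dives['transmitted'].sum())}")
print(f"drift-dive fraction: {dives['is_drift'].mean():.3f} "
      f"(configured {cfg.drift_dive_prob})")
t = bundle.truth
start = t[t['day'] < 5].groupby('seal_id')['dr_true'].mean().mean()
end = t[t['day'] >= 55].groupby('seal_id')['dr_true'].mean().mean()
print(f"mean drift rate, first 5 days: {start:.3f} m/s; last 5 days: {end:.3f} m/s")
print("-> seals depart negatively buoyant and gain condition over the trip;")
print("   ~3.5% of dives carry a passive drift segment revealing that trajectory.")
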