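"""Relate dive-effort metrics to foraging success with the mixed model.

Each metric is modelled as a linear effect of dDR (foraging success)
plus a spline smooth of DR (buoyancy control), per-seal random
intercept/slope, and continuous-time AR(1) errors.
"""

from driftforage import SimConfig, coefficient_table, fit_pamm, build_design
from driftforage.pipeline import replicate_dataset
from driftforage.responsemodel import ModelSpec

data = replicate_dataset(SimConfig(n_seals=12, days_per_seal=90, seed=2),
                         windows=(1,))
records = data["records"][1]
gammas = data["bundle"].truth_params

fits = []
for metric in ("descent", "ascent", "dive_res", "surf_res"):
    fits.append(fit_pamm(build_design(records, ModelSpec(metric=metric))))
table = coefficient_table(fits)
print(table[["metric", "beta1", "se", "p", "flag", "phi"]].round(4).to_string())
print(f"generative effects: descent/ascent {gammas['gamma_descent']:+.1f}, "
      f"dive_res {gammas['gamma_diveres']:+.0f}, "
      f"surf_res {gammas['gamma_surfres']:+.0f}")
print("-> transit rates respond positively, dive residual negatively, and")
print("   the surface residual shows no significant response - the headline")
print("   pattern, after the smooth absorbs the buoyancy trend.")
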