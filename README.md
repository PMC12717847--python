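# driftforage

Dive-effort responses to foraging success in deep-diving seals, inferred
from satellite-relayed dive summaries — as a tested, fully synthetic,
end-to-end pipeline.

## The scientific problem

Southern elephant seals spend months at sea, and the tags they carry can
only relay heavily summarised data: each dive compressed to four
inflection points, and a handful of noisy ARGOS positions per day.  Yet
these animals offer something rare: an *in-situ* measure of foraging
success.  A few percent of dives contain passive **drift segments**
where the seal stops swimming and sinks or rises at a rate set by its
buoyancy.  The vertical **drift rate** DR (m/s, positive upward) tracks
the blubber:lean ratio, so its change over time,

    dDR_n = DR_n − DR_{n−1}        (windows of 1, 2, 3, 7, 10 days)

is a proxy for net energy gain — foraging success.  The question the
pipeline answers: *how do dive-effort metrics respond to foraging
success, once the direct physiological effect of buoyancy on diving is
accounted for?*  The four metrics are descent rate, ascent rate, the
**dive residual** (residual of a duration~depth regression; relatively
long or short dives for their depth) and the **surface residual**
(observed post-dive surface interval minus the minimum interval expected
for that duration, a tau=0.05 quantile-regression envelope).

The core model, per metric y, seal i and window t:

    y_it = β0 + β1·dDR_it + f(DR_it) + a_i + c_i·dDR_it + e_it
    e_it continuous-time AR(1) within seal:  corr = φ^|Δt|  (days)

with f a penalized spline (buoyancy control), (a_i, c_i) correlated
per-seal random intercept and slope, and everything — smoothing
parameter, variance components, φ — estimated by one REML criterion
through the mixed-model representation of penalized splines.

Because the field datasets behind such analyses are rarely deposited,
the package ships a first-class **synthetic world generator** with known
effect sizes (γ per metric), so every stage — broken-stick dive
abstraction, exclusion filtering, continuous-time correlated-random-walk
(CTCRW) track estimation, robust Kalman screening of drift segments,
windowing, and the mixed model — is validated by parameter recovery.

## Worked example

```python
from driftforage import SimConfig, build_design, coefficient_table, fit_pamm
from driftforage.pipeline import replicate_dataset
from driftforage.responsemodel import ModelSpec

data = replicate_dataset(SimConfig(n_seals=12, days_per_seal=90, seed=2),
                         windows=(1,))
records = data["records"][1]
fits = [fit_pamm(build_design(records, ModelSpec(metric=m)))
        for m in ("descent", "ascent", "dive_res", "surf_res")]
print(coefficient_table(fits)[["metric", "beta1", "se", "p", "flag"]])
```

prints (`python examples/response_model.py` for the full script):

```
     metric      beta1        se       p flag
0   descent     1.4090    0.0982  0.0000  sig
1    ascent     1.4120    0.0974  0.0000  sig
2  dive_res -2075.2028  110.3264  0.0000  sig
3  surf_res   -17.1163   18.3503  0.3509   ns
```

Reading: with generative effects of +2.0 (m/s per m/s dDR) on transit
rates, −3000 s on the dive residual and 0 on the surface residual, the
fitted w=1 coefficients recover the correct signs — dives get *steeper
and shorter* when foraging improves — while the surface residual is
correctly flagged non-significant.  The magnitudes sit below the
generative values because the predictor is itself estimated from
screened drift segments (classical errors-in-variables attenuation; see
`docs/methods.md`).  Refitting across windows of 1–10 days shows the
coefficients shrinking monotonically toward zero as block averaging
dilutes the day-scale signal.

Each capability has a narrative script under `examples/`; the
`driftforage` command exposes the same stages for shell use
(`driftforage run --seed 4 --out demo/`, plus `simulate`, `abstract`,
`filter`, `trackfit`, `driftrate`, `model`, `recover`).

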