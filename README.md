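# densitycal

Estimating bird **density** (birds/ha) and **population size** from
opportunistic community-science checklists (eBird-style data), by borrowing
detection information from structured point counts.

Community checklists record how many birds an observer reported, but not how
large an area was effectively surveyed nor how likely a present bird was to
be detected — so raw counts cannot be converted to densities. `densitycal`
implements the detection-offset approach: availability and perceptibility
models fitted to structured 5-min point counts (with time-of-detection and
distance-bin records) yield a per-survey correction factor that links the
expected count to density, and that correction is carried into
community-science count models. A fully seeded simulator generates
landscapes, bird populations, structured surveys and community checklists so
the whole analysis runs — and is validated against known truth — at desk
scale.

## The model

For a count of duration `T` at a survey point, the expected count of a
species with local density `D` (birds/ha) is

```
E[Y] = D · A · p · q
```

* **availability** `p = 1 − e^{−φT}`: a present bird gives a detectable cue
  at rate `φ` per minute. `φ` is estimated from *removal* data — the first
  1-min interval in which each individual was detected — via the conditional
  multinomial `π_j = (e^{−φ t_{j−1}} − e^{−φ t_j}) / (1 − e^{−φ T})`,
  with log-linear effects of Julian day and time of day.
* **perceptibility** `q`: an available bird at distance `r` is perceived
  with half-normal probability `g(r) = e^{−r²/τ²}`. `τ` is estimated from
  50-m distance bins (unlimited last bin) via
  `π_k = e^{−r_{k−1}²/τ²} − e^{−r_k²/τ²}`, with log-linear covariate
  effects (noise sources, land cover).
* **effective area** `A = πρ²`: with unlimited distances, the effective
  detection radius `ρ` — at which birds missed inside equal birds detected
  outside — equals `τ` for a half-normal `g`, and `q = 1` within `A` by
  definition.

Candidate detection models are ranked by small-sample AICc; the top models
give each survey its correction `C = A·p·q` (hectares). `log C` then enters
a zero-inflated count model: an occurrence model thresholded at sample
prevalence defines suitable habitat, and a Poisson count model with offset
`log C`, fitted to counts from suitable habitat only, predicts density per
landscape cell. Population = Σ density × cell area over suitable cells.

Four **frameworks** differ in where the correction comes from:

| framework    | offsets                                                     |
|--------------|-------------------------------------------------------------|
| benchmark    | structured surveys model everything (best practice)         |
| fixed        | fixed 200-m radius, perfect detection (no structured data)  |
| independent  | detection models from a full, independent structured dataset|
| calibration  | detection models from a small supplemental sample with `n`  |
|              | positive surveys (10/30/100/250), optionally *pooled* into  |
|              | the community training data                                 |

Endpoints (AUC, suitable area, mean density, population) are summarized as
percent of the benchmark's median across ten iterations.

## Worked example

```python
import numpy as np
from densitycal import synthetic as syn, frameworks as fw, io as dio

scenario = syn.make_fixture_scenario("common", seed=1)
print(f"true population: {scenario.true_population:.0f} birds")
data = dio.prepare_datasets(scenario, seed=1)

bench = fw.run_benchmark(data["benchmark"], data["detections"], data["test"],
                         scenario.landscape, seed=1, iterations=10)
indep = fw.run_independent(data["cs"], data["structured_full"], data["detections"],
                           data["test"], scenario.landscape, seed=1, iterations=10)
fixed = fw.run_fixed(data["cs"], data["test"], scenario.landscape, seed=1,
                     iterations=10)
print(fw.compare(indep, bench).median_percent["population"])
```

prints (numbers produced by this code):

```
true population: 889 birds
community checklists after filtering + 200-m sampling: 267
benchmark surveys: 267, test surveys: 233
benchmark    AUC=0.885  suitable=753 ha  density=1.40/ha  population=1054
independent  AUC=0.858  suitable=774 ha  density=1.18/ha  population=912
fixed        AUC=0.858  suitable=774 ha  density=0.13/ha  population=102
independent population = 87% of benchmark
fixed population = 10% of benchmark
```

The detection offsets carry the correction: the independent framework's
population estimate lands near the truth (912 vs 889) while the fixed-radius
framework — which assumes perfect detection over π·200² m² — is biased
extremely low, by roughly the factor `(τ² p)/200²` that the offsets undo.

The same pipeline is scriptable from a shell:

```bash
densitycal simulate --scenario common --seed 1 --out sim/
densitycal filter --in sim/community.csv --grid 200 --seed 1 \
    --out filtered.csv --report removals.json
densitycal run --scenario common --framework calibration --n-occ 30 \
    --pooling --iterations 10 --seed 1 --out results/calib30
densitycal compare --benchmark results/bench --framework results/calib30
```

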