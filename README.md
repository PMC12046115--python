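# isogeoloc

Isotope-based forensic geolocation in Python: compile human-tissue oxygen
(δ¹⁸O) and strontium (⁸⁷Sr/⁸⁶Sr) isotope records, build a tap-water δ¹⁸O
isoscape by difference kriging, calibrate tissue–environment regressions,
diagnose and remove systematic per-study and per-tooth-group biases from the
regression residuals, and quantify how geographically specific assignments
from the data can be.

## Who this is for

Forensic anthropologists and isotope geochemists who work with compiled
reference datasets of human hair, nail, bone and tooth-enamel isotope values
and need to (a) normalize heterogeneous published data onto common reference
frames, (b) relate tissue values to environmental isoscapes, and (c) state —
with a validation-backed accuracy curve — how much geographic information a
tissue measurement actually carries.

## The model

Tissue values `y` at origin `x` are modeled as an affine function of the
environmental isoscape value `e(x)` plus noise:

    y = α + β·e(x) + ε,  ε ~ N(0, σ²)

fit by weighted least squares (site-frequency weights by default, so densely
sampled sites do not dominate). The tap-water isoscape itself is built from a
base precipitation surface `P(x)` and station observations `tᵢ`:

    T(x) = P(x) + OK[ tᵢ − P(xᵢ) ](x)

where `OK[·]` is ordinary kriging of the station differences under a fitted
semivariogram — this keeps the base surface's fine structure between
stations. Geographic assignment inverts the calibration: the posterior
probability that a sample with value `y` originated at cell `x` is the normal
density `N(y; α + β·e(x), σ)` normalized with cos(latitude) cell-area
weights. Quality assessment (QA) is an iterated split-sample test reporting
the fraction of held-out samples whose true origin falls inside the
highest-posterior region covering an area fraction `q`, for a grid of `q`.

Systematic inter-study or tooth-mineralization-age offsets appear as shifted
group means of the calibration residuals (tested with one-way ANOVA;
dispersion differences with Levene/Brown–Forsythe). Subtracting each group's
mean residual from its published values removes the offsets and measurably
improves the QA curve.

## Worked example

```python
import numpy as np
from isogeoloc import (
    SyntheticScenario, synth_raster, synth_dataset, calibrate,
    build_bias_table, apply_bias_correction, qa, QAConfig,
)

scenario = SyntheticScenario(
    seed=1, n_sites=80, n_per_site=5, slope=0.43, intercept=28.0,
    noise_sd=1.0, study_biases={"S1": 1.5, "S2": 0.0, "S3": -1.5},
    grid_shape=(25, 25),
)
env = synth_raster(scenario)
dataset, _ = synth_dataset(scenario, env)

fit = calibrate(dataset, env, weighting="unit")
print(f"slope={fit.slope:.3f}  R2={fit.r_squared:.3f}  RSE={fit.rse:.3f}")

grouping = {r.sample_id: r.study_id for r in dataset}
table = build_bias_table(fit, grouping)
corrected = apply_bias_correction(dataset, table, grouping, uncorrected_groups=())

cfg = QAConfig(n_iterations=8, seed=2, q_grid=np.round(np.arange(0.02, 1.001, 0.02), 2))
print(f"accuracy@10% area: raw={qa(dataset, env, cfg).accuracy_at(0.10):.3f} "
      f"corrected={qa(corrected, env, cfg).accuracy_at(0.10):.3f}")
```

prints (exactly, for these seeds):

```
slope=0.434  R2=0.653  RSE=1.580
accuracy@10% area: raw=0.258 corrected=0.375
```

The fitted slope recovers the injected tissue–water slope 0.43; the residual
standard error 1.58‰ reflects the 1‰ measurement noise inflated by the
±1.5‰ study offsets. At the 10% area quantile, bias correction raises
assignment accuracy from 0.26 to 0.38 — removing inter-study offsets buys
real geographic specificity, the central practical point of the residual
framework.

A thin CLI mirrors the library: `isogeoloc compile | build-isoscape |
calibrate | diagnose | correct | qa | qa-compare | synth` (see `--help`).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the whole pipeline from scratch on a seeded synthetic world —
isoscape construction from stations, calibration, residual diagnostics, bias
correction, and the corrected-vs-uncorrected QA comparison — printing the
fitted and validated quantities it computes along the way and writing the
results JSON to `--out`.
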