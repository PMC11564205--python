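# tribomove

Movement-trait analysis for experimentally evolved dispersal lines of the
red flour beetle (*Tribolium castaneum*) — and, more generally, for any
study that scores multi-animal video tracks, dispersal assays and
morphometrics across artificial-selection regimes.

Divergent selection on dispersal propensity produces lines that differ not
just in dispersal but in a whole syndrome of correlated traits: activity,
path tortuosity, edge use, surface affinity and body size. This package
implements the quantitative pipeline for such a study:

* **Trajectory metrics** per replicate recording: path-length rate
  (px s⁻¹), thigmotactic **edge affinity** (proportion of detections
  within a physical margin, default 10 mm, of the arena's coordinate
  extremes), and **Benhamou sinuosity**

  $$S = 2\,\bigl[\,p\bigl(\tfrac{1+c}{1-c} + b^2\bigr)\bigr]^{-1/2},$$

  where `p` is the constant step length after chord-based
  **rediscretization** of the track, `c` the mean cosine of turning
  angles and `b` the step-length coefficient of variation (0 after
  rediscretization). `S = 0` for a straight path; units px⁻¹ᐟ².
* **Assay scoring**: mean dispersals per individual out of three
  standardized opportunities (0–3); dispersive / non-dispersive phenotype
  classes; surface-affinity counts and the one-generation
  selection-response comparison.
* **Morphometrics**: Spearman repeatability screening of repeated
  measurements, complete-case filtering, PCA of the trait correlation
  matrix with a fixed sign convention (PC1 increases with body size), and
  the relative-leg-length construct (femur + tibia, with PC1 as the size
  covariate).
* **Regime statistics**, statsmodels-style: a `RegimeModel` built from a
  tidy DataFrame and a `ModelSpec` whose `fit()` returns `RegimeResults`
  with coefficients, SEs, p-values, variance components, pairwise regime
  contrasts and a `summary()`; mixed models (REML, crossed random
  intercepts for block / line / camera) where the design calls for them;
  an interaction-pruning rule; and `run_table1_battery` covering all
  eight standard analyses.
* **Synthetic data** for every input, with known ground truth: bounded
  correlated random walks (von Mises turning concentration κ, Gamma step
  lengths, specular wall reflection, optional wall-following), binomial
  dispersal and surface tallies, and a latent-size-factor morphometrics
  generator. Scenarios: `paper_like` (regime effects mimicking the
  published means) and `null` (calibration).

## Worked example

```python
import numpy as np
from tribomove import CrwParams, gen_crw_track, sinuosity
from scipy.special import i0, i1

# a 10-minute correlated random walk with turning concentration kappa=1,
# constant 2 px steps, recorded at 25 fps
params = CrwParams(kappa=1.0, step_mm_per_frame=2.0, step_cv=0.0,
                   arena_mm=5000.0, mm_per_px=1.0, duration_s=600.0,
                   n_individuals=1)
track = gen_crw_track(params, np.random.default_rng(20240917))
S_hat = sinuosity(track.xy, p=2.0)

c = i1(1.0) / i0(1.0)                      # analytic mean turn cosine
S_true = 2.0 / np.sqrt(2.0 * (1 + c) / (1 - c))
print(f"estimated S = {S_hat:.4f}, analytic S = {S_true:.4f}")
```

prints

```
estimated S = 0.8748, analytic S = 0.8749
```

the estimator recovering the analytic sinuosity of a κ = 1 walk to a
fraction of a percent. At study scale the same machinery runs end to end
from a shell:

```bash
tribomove run --seed 1 --outdir out/
```

which simulates the `paper_like` study (16 high / 16 low / 12 control
lines), computes movement metrics, assay scores and the size PCA, fits
the eight-analysis battery and writes `battery_report.txt`,
`battery_contrasts.csv`, `regime_summary.csv` and a reproducibility
`manifest.json` (config hash, seeds, per-file checksums). The dispersal
row of the report, for example, shows the three pairwise regime contrasts
(low − high ≈ −1.74 when line means sit at the published values 0.70,
2.44, 1.94 for low / high / control).

Each stage is also available separately (`tribomove simulate`, `metrics`,
`score`, `morph`, `models`) and re-runs from its predecessor's CSVs with
identical results under the same seed.

## Layout

```
src/tribomove/
  tracking.py    # Track / ReplicateRecording containers, CSV I/O, exclusions
  metrics.py     # path length, rediscretization, sinuosity, edge affinity
  assays.py      # dispersal + surface-affinity scoring
  morphology.py  # repeatability, size PCA, leg length
  regime.py      # RegimeModel / RegimeResults, contrasts, battery
  simulate.py    # CRW + assay + morphometrics generators, scenarios
  pipeline.py    # stage orchestration, config, manifest
  cli.py         # tribomove command-line interface
docs/methods.md  # models, assumptions, parameter choices, limitations
```
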