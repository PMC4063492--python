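# bearfall

Habitat-selection and movement analysis for GPS-collared grizzly bears
during the fall whitebark pine (WBP) season, built for studying how bears
respond to landscape-scale WBP decline. The package bundles the full
analysis chain — adaptive local convex hull (a-LoCoH) fall home ranges,
fix-success-weighted Manly–Chesson selectivity, NDVI-impact-adjusted
availability, day-of-use timing, daily movement indices, and AICc trend-model
selection — together with a synthetic landscape/GPS-track generator with
known ground truth, so every stage is testable without any field data.

It is aimed at movement and habitat-selection ecologists who want a
reproducible, end-to-end reference implementation of these methods, and at
methodologists studying the behavior of selectivity estimators under
habitat-dependent GPS fix failure.

## The core statistic

For a two-habitat system the Manly–Chesson standardized selectivity index is

    MC = (U/A) / (U/A + (1−U)/(1−A))  =  sigmoid(logit U − logit A)

where *U* is the (certainty-weighted) proportion of a bear's locations in the
habitat and *A* the proportion of its 100% a-LoCoH fall range covered by it.
MC = 0.5 means use proportional to availability; MC > 0.5 means selection.
Temporal trends in MC (and in use timing and movement) are assessed by
ranking the candidate set {Base, Base + YEAR, Base + YEAR + YEAR×CONES} —
Base = CONES + SEX + CONES×SEX — by AICc with Akaike weights
exp(−Δᵢ/2)/Σ exp(−Δⱼ/2). See `docs/methods.md` for the full model
descriptions.

## Worked example

Simulate a 12-year cohort with a programmed selectivity decline and run the
whole pipeline:

```python
from bearfall import RunConfig, run_pipeline

cfg = RunConfig(years=tuple(range(2000, 2012)), bears_per_year=5,
                seed=3, outdir="demo_run")
summary = run_pipeline(cfg)
print(summary["n_bears"], summary["n_eligible_wbp"])
print(summary["top_models"]["MC index for WBP habitat"])
```

Or from the shell (`bearfall all --seed 3 --outdir demo_run`). With this
seed the run simulates and retains 60 bear-seasons (none fail the
≥95%-monitoring filter), assigns per-bear fix-success weights of 0.94–1.00,
and ranks a YEAR-containing model top for the WBP selectivity response
(`demo_run/model_table.csv`), matching the decline programmed into the
generator; `demo_run/contrasts.csv` reports the model-predicted 12-year
change:

```
MC index for WBP habitat  Base + YEAR + YEAR x CONES  year 2011 vs 2000  -0.209  (95% CI -0.300 .. -0.118)
```

against a programmed decline of −0.21, and the movement table gives a median
daily net displacement of 1.23 km. Single functions work standalone:

```python
>>> from bearfall import mc_index, akaike_weights
>>> mc_index(U=0.6, A=0.3)
0.7777777777777778
>>> akaike_weights([0, 2.19, 6.95]).round(2)
array([0.73, 0.25, 0.02])
```

## Layout

| module | contents |
| --- | --- |
| `bearfall.synthetic` | landscape / impact-surface / cone-series / GPS-track generators |
| `bearfall.layers` | WBP and secure-habitat layers, impact grid, point classification |
| `bearfall.homerange` | a-LoCoH ranges, adaptive-a selection, availability |
| `bearfall.habitat_use` | fix weighting, use proportions, MC indices, day-of-use |
| `bearfall.movement` | daily centers, net displacement, activity radius |
| `bearfall.models` | WLS / quantile / mixed fits, AICc ranking, contrasts |
| `bearfall.pipeline` | staged orchestration, config, logging |
| `bearfall.cli` | `bearfall` console entry point |
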