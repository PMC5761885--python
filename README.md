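# beatgrid

Tools for studying what makes a musical rhythm's beat hard to find.

In beat-perception experiments of this design, rhythms live on a grid of 16
isochronous positions — four beats (positions 1, 5, 9, 13) of four
sixteenth-note subdivisions. A **temporal rhythm** is a pattern of 9 tones
and 7 silences starting with a tone; perceptual accents follow the
Povel–Essens grouping rules (an isolated tone, the second of a pair, and the
first and last of a run of three or more tones are accented). An **intensity
rhythm** projects the same accent positions onto a fully isochronous tone
stream, with accented tones 8.5 dB louder. Counterevidence against the duple
beat is counted as **missing beats** (silent or unaccented beat positions)
and **off-beat accents** (accents on even positions; the metrically
ambiguous positions 3, 7, 11, 15 count toward neither). Participants rate,
on a 1–10 scale, how hard it would be to tap along with each rhythm.

The package provides, as library functions and a `beatgrid` CLI:

- **`beatgrid.grid`** — exhaustive enumeration of all constrained 16-grid
  temporal rhythms, accent annotation, counterevidence classification,
  projection to the intensity-rhythm inventory, and the per-condition
  inventory tables for both experiment presets;
- **`beatgrid.stimuli`** — assembly of 296-trial experiment sets (pairs of
  same-condition rhythms concatenated to 33 grid positions with a closing
  tone), dB-calibrated onset schedules and WAV rendering;
- **`beatgrid.ratings`** — synthetic raters drawn from the exact
  cumulative-logistic mixed law, with participant random intercepts,
  a musical-training covariate, and the dropout/inclusion filter
  (participants with < 60 ratings removed);
- **`beatgrid.design` / `beatgrid.clmm` / `beatgrid.inference`** — the
  analysis model, written from scratch: a cumulative-link mixed model

      P(rating ≤ k) = logistic(θ_k − x′β − b_i),   b_i ~ N(0, σ_b²)

  fitted by maximum marginal likelihood with adaptive Gauss–Hermite
  quadrature over the participant intercept; simple + orthogonal-polynomial
  contrasts for the full four-way fixed-effect expansion (47 columns) with
  rank-revealing elimination of the directions aliased by the non-factorial
  condition structure; drop-one-term likelihood-ratio tests with Friedman
  effect sizes (η² = χ²/N for 1 df, χ²/(χ²+N) otherwise); Wald contrasts
  with r = z/√N; latent-scale condition estimates;
- **`beatgrid.pipeline`** — a seeded, logged, fully reproducible
  enumerate → build → simulate → fit → report run.

## Worked example

```python
import dataclasses
from beatgrid import (experiment_table, build_experiment_stimuli, EXP1_CONFIG,
                      simulate_ratings, apply_inclusion_filter, fit_clmm,
                      ClmmSpec, ContrastScheme, lr_term_tests, contrast_wald)
from beatgrid.ratings import EXP1_SIM

space, table = experiment_table(1)
print(len(space.records))        # 670 temporal rhythms pass the constraints
print(table.to_string(index=False))
```

```text
 missing_beats  off_beat_accents  n_temporal  n_intensity category  used
             0                 0          12            6      few  True
             1                 0          36            6      few  True
             1                 1          98           18     some  True
             1                 2          56            6     many  True
             2                 0          11            3 not_used False
             2                 1          65           12      few  True
             2                 2         143           22     some  True
             2                 3         111           16     many  True
             2                 4          18            3 not_used False
             3                 2          10            2 not_used False
             3                 3          37            8      few  True
             3                 4          53           12     some  True
             3                 5          20            6     many  True
```

670 temporal rhythms collapse onto 120 distinct intensity rhythms; the ten
conditions with at least six rhythms of each type are usable. Build the
trial set, simulate a small panel of raters and fit the model:

```python
trials = build_experiment_stimuli(space, space.intensity_masks,
                                  dataclasses.replace(EXP1_CONFIG, seed=1))
sim = dataclasses.replace(EXP1_SIM, n_participants=12,
                          ratings_range=(60, 120), seed=2)
records = apply_inclusion_filter(simulate_ratings(sim, trials))
fit = fit_clmm(records,
               spec=ClmmSpec(scheme=ContrastScheme(training_center=11.0)))
print(f"loglik {fit.loglik:.2f}  sigma_b {fit.sigma_b:.3f}  N {fit.n_obs}")
print(lr_term_tests(records, fit).head(4))
```

```text
loglik -1657.39  sigma_b 1.041  N 1162
         term    chi2  df  eta2     p  converged
missing_beats 106.718   3 0.084 0.000       True
     off_beat   1.261   2 0.001 0.532       True
         type  39.787   1 0.034 0.000       True
     training   1.022   1 0.001 0.312       True
```

The likelihood-ratio table reads like an ANOVA: with the generator's default
effects, missing beats dominate (χ² = 106.7 on 3 df, η² = 0.084 at
N = 1162), accent type matters (temporal rhythms are rated harder), and the
off-beat term is null, as simulated. A planned contrast on the linear
missing-beats trend gives its Wald test and companion effect size:

```python
z, p, r = contrast_wald(fit, "mb_lin")   # z=6.98, p=3e-12, r=0.20
```

The same pipeline runs from the shell:

```sh
beatgrid enumerate --experiment 1 --out out/
beatgrid build-stimuli --experiment 1 --seed 1 --out out/ --audio
beatgrid simulate --preset exp1 --seed 2 --out out/ratings.tsv
beatgrid fit --ratings out/ratings.tsv --out out/fit/
beatgrid run --experiment 1 --out out/run/
```

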