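# Methods

## The rhythm space

A rhythm is a binary vector over 16 isochronous grid positions; beats fall
on positions 1, 5, 9, 13, the even positions are off the beat under either
duple reading, and positions 3, 7, 11, 15 are metrically ambiguous (on the
beat if the listener subdivides in eight) and are therefore excluded from
all counterevidence counts. Temporal rhythms have 9 tones and 7 silences
and start with a tone: 6435 candidate masks.

Temporal accents follow the Povel–Essens grouping rules, per maximal run of
consecutive tones: a lone tone is accented; in a pair, the second; in a run
of three or more, the first and last. "Isolated" is interpreted strictly as
a run of length one.

### Run-delimitation convention

The grouping rules need a convention for where runs begin and end, and in
this paradigm rhythms are never heard with a silent tail: each 16-grid
pattern is followed either by another pattern (which always starts with a
tone) or by a closing tone. We examined three conventions:

- **linear** — runs end at the grid edges;
- **cyclic** — runs wrap from position 16 to position 1;
- **continuation** (default) — a virtual tone is appended after position 16;
  a run touching the grid end extends one position, and an accent assigned
  to the virtual position belongs to the next pattern and is discarded.

Only the continuation convention reproduces the published per-condition
inventory (670 temporal rhythms; every cell of the Experiment-1 table) —
neither linear nor cyclic delimitation comes close (653/553 totals, many
cells off). The same convention is applied to the run-length constraints:
an event run is measured including the virtual continuation tone. The
convention was selected by this empirical criterion, not assumed; `linear`
and `cyclic` remain available as options. One consequence worth noting: the
published table's omission of rows with zero missing beats and nonzero
off-beat accents reflects genuine impossibility under this convention (no
such pattern passes the constraints), not under-reporting.

### Selection constraints

Experiment-1 preset, applied to each candidate mask:

1. starts with a tone (by construction of the candidate set);
2. event runs ≤ 5 and silence runs ≤ 3 (continuation convention);
3. the four beat quarters (positions 1–4, 5–8, 9–12, 13–16) are pairwise
   distinct event configurations;
4. exactly 6 accents;
5. no unaccented tone on a beat position (silence is the only allowed
   counterevidence on the beat in temporal rhythms).

Experiment-2 preset adds: event runs ≤ 3; the cyclic inter-onset multiset
must be {1,1,1,1,1,2,2,3,4} (five sixteenths, two eighths, one dotted
eighth, one quarter — the distribution of the strictly metric rhythms); and
one further exclusion recovered empirically: rhythms whose opening two notes
are an eighth followed by the quarter note. With only the two documented
extra constraints the enumeration yields 105 rhythms where the published
table prints 103, the difference being exactly two rhythms in the
one-missing-beat/zero-off-beat cell; an exhaustive search over local
structural predicates found the opening eighth+quarter figure as the unique
minimal rule matching every printed cell. No generative rationale for it is
stated in the source; we encode it as an explicit, flagged quirk of the
preset (`ConstraintSet.exclude_opening_eighth_quarter`) so that the
published inventory is reproduced bit-exactly while remaining separable.

### Intensity rhythms

An intensity rhythm is an accent mask rendered on an isochronous tone
stream. The inventory is the set of distinct accent masks arising from
candidate masks that pass constraints 1–4; constraint 5 is temporal-specific
(for an intensity rhythm an unaccented beat *is* the missing-beat
counterevidence, not grounds for exclusion). Masks whose downbeat is
unaccented are dropped, and each mask is classified by its own
counterevidence (unaccented beats, even-position accents). This yields 120
distinct intensity rhythms whose per-condition counts match every published
cell; projecting only from the final temporal space would give 110 and
contradict the published counts. Because the event-density and
note-duration constraints of Experiment 2 act on temporal structure only,
the Experiment-2 inventory table pairs the tightened temporal space with the
unchanged intensity inventory, as in the published table.

A condition enters an experiment when both its temporal and intensity counts
reach `min_patterns` (default 6): ten conditions in Experiment 1, eight in
Experiment 2.

## Stimulus assembly

Each trial concatenates two *different* same-condition rhythms into 32 grid
positions and appends a closing tone (33 positions, isochrony preserved).
Pair selection is "round-robin without replacement": the condition's pool is
shuffled (seeded), consumed two per trial, reshuffled when exhausted, and
within-trial duplicates are rejected — a deterministic reading of
"semi-random selection optimized for variety". Per-condition trial counts
follow the published design (148 per accent type, 296 per experiment). Each
trial draws one of five inter-onset intervals {140, 145, 150, 155, 160} ms
uniformly (600 ms between beats at the central tempo).

Levels are stated relative to the accented-intensity reference: intensity
rhythms use 0 / −8.5 dB for accented/unaccented tones; temporal rhythms play
every tone at −0.8 dB, equating overall loudness. The closing tone is an
isolated (hence accented) tone; its level follows its trial type (reference
for intensity trials, −0.8 dB for temporal trials) and is configurable,
since the source does not state it. Audio is rendered as 16-bit mono WAV at
44.1 kHz with a 30 ms exponentially decaying 1.2 kHz burst per onset, the
reference level at −6 dBFS, and 500 ms of lead silence; the woodblock timbre
of the original stimuli is out of scope.

## Synthetic raters

Ratings are drawn from exactly the analysis model (no latent-noise
discretization shortcut): per participant a normal random intercept with
spread σ_b, per trial the cumulative-logistic category law. The default
panel emulates the first experiment: 32 participants, each rating a
uniform-random 60–296 of the 296 trials without replacement. Training years
come from a two-component mixture — 25% novices uniform on [0, 1.5] years,
75% trained uniform on [3, 25] years — chosen to match the reported range
(0–25) and approximate mean (~11 years) while leaving the novice/expert
display split at 2 years meaningful; only mean and range are reported for
the real panels, so the mixture shape is this package's choice. Default
effects (see `ratings.DEFAULT_BETA`) reproduce the published *ordering*
qualitatively — harder with more missing beats with saturating curvature,
temporal harder than intensity, training amplifying the missing-beats
effect and shrinking the type effect, weak off-beat effects — but their
magnitudes are free generator parameters, never claimed as the study's
estimates. Default thresholds put the latent mass in the low categories,
giving the left-skewed marginal typical of single-item difficulty ratings.
The generator does not model dropout behaviour, response times, learning
effects, or tempo effects (tempo is carried through the schema but has no
coefficient by default); passing tests therefore certify the machinery on
correctly specified data, not robustness to the ways real raters deviate
from the model.

The inclusion filter removes all records of participants with fewer than 60
ratings (exactly 60 is kept).

## The analysis model

Fixed effects: missing beats (simple contrast of level 0 against the mean
of levels 1–3, plus orthonormal linear and quadratic polynomials over levels
1–3), off-beat category few/some/many (orthonormal linear and quadratic
polynomials), accent type (sum-coded; temporal = +1, a flagged choice since
the source does not state the coding), and training years centred at the
sample mean (or a supplied centre). The full four-way expansion has 47
columns. Because the condition structure is not factorial (zero missing
beats occurs only with "few"), the basis is rank deficient; columns are
eliminated greedily in a fixed lowest-order-first scan, seeding the basis
with the constant vector (the thresholds play the intercept's role), with a
relative tolerance of 1e-8. On the ten-condition structure this retains 39
columns and reproduces the published df for all 15 terms (3/2/1/1 for the
main effects, 4 rather than 6 for missing × off-beat, and so on); on the
eight-condition structure, 31.

The cumulative-link mixed model uses the logistic link by default (probit
behind a flag). The marginal likelihood integrates the participant
intercept by adaptive Gauss–Hermite quadrature: per participant, damped
Newton steps locate the mode of the log-integrand (strictly concave for
both links), the grid is centred and scaled there, and 15 nodes are used by
default (one node is the Laplace approximation; the 15- vs 25-node
log-likelihood difference is below 1e-4 at the default problem size).
Optimization is BFGS on an unconstrained parametrization — β, the first
threshold, log threshold increments, log σ_b — with an analytic gradient
computed holding the adaptive nodes fixed (on test problems it agrees with
finite differences to ~1e-8); convergence requires the gradient norm to
fall below 1e-6 (up to three jittered restarts; a stationary point with
max-gradient below 1e-4 is accepted as converged after restarts, and
anything else raises, never silently). Unobserved extreme rating
categories are collapsed before fitting and mapped back afterwards.
Standard errors come from the central-difference Hessian at the optimum,
mapped to the natural scale by the delta method; intervals for σ_b are best
formed on the log scale (the optimizer's own parametrization), the standard
choice for a positive dispersion parameter.

Term tests drop one term's retained columns from the full model (all other
columns kept — a Type-III-like reading, adopted because main effects are
reported alongside all interactions), refit with a warm start, and refer
2·Δlog-likelihood to χ² on the dropped-column count. Effect sizes use
Friedman's convention: η² = χ²/N for one df, χ²/(χ²+N) otherwise, with a
(numerically) negative likelihood ratio clamped to zero with a warning
rather than reproduced. Planned contrasts report Wald z = β̂/SE, two-sided
normal p, and r = z/√N with N the number of ratings — a convention not
stated in the source but inferred: it reproduces seven of the eight
printed (z, r) pairs after 2-decimal rounding; the eighth (z = 2.63 with
N = 5771, printed r = 0.04 where z/√N = 0.035 → 0.03) appears to be a
rounding slip in the source and is not reproduced. Condition estimates are
linear predictors x′β (random effect at zero; negative = easier), with
delta-method standard errors, and support the 2-year novice/expert display
split. A McFadden-style pseudo-R² can be computed from the fitted and null
log-likelihoods as an optional diagnostic; it is *not* the unexplained
"proportion of variance" statistic the source reports (0.17/0.08, formula
unstated), which we deliberately do not imitate.

## Numerical and testing choices

Problem sizes in the validation suite were chosen to exercise each property
at the smallest scale where it is meaningful: the likelihood oracle uses a
3-participant toy set against dense-trapezoid integration (agreement to six
significant digits); parameter recovery uses 100 seeded panels of 40
participants × 150 ratings each with a five-coefficient model (every true
parameter within two standard errors in ≥ 90% of fits — for σ_b the
two-SE criterion is close to its inherent ceiling, since at 40 participants
the sampling fluctuation of the realized intercept spread, SE ≈ σ/√(2G),
dominates the interval whatever the estimator does); type-I calibration of
the likelihood-ratio test uses 500 null simulations of 12 participants × 40
ratings (rejection rate within [0.03, 0.07] at α = 0.05); and the pipeline
tests run a reduced 10-participant panel. The full default pipeline (32
participants, full model, 15 term tests) runs in well under a minute.

## Known limitations

- The continuation run convention and the Experiment-2 opening-figure
  exclusion are empirical reconstructions of an under-specified generation
  procedure; they reproduce every published inventory cell exactly, but a
  different hidden rule could coincide on these tables.
- The fitter handles a single random intercept only — no random slopes, no
  category-specific (non-proportional) effects, no Bayesian estimation.
- Wald standard errors for σ_b are asymptotic; profile or bootstrap
  intervals would be preferable at very small panel counts.
- The synthetic raters are correctly specified by construction; conclusions
  about robustness to real-world misspecification (ordinal scale use,
  sequential effects, dropout) are outside what the test suite shows.
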