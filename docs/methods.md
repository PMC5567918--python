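# Methods

`atsea` implements a complete analysis chain for detecting and modelling
at-sea foraging associations between concurrently tracked central-place
seabirds (little penguins are the motivating system), together with a
seeded synthetic-study generator that makes every stage testable without
field data.

## Track preprocessing

Raw inputs are GPS fixes (nominally one per 2 min), time-depth-recorder
(TDR) samples at 4 s carrying a wet/dry flag, and deployment metadata
(colony, nest coordinates, sex, mass, flipper length, breeding stage and
clutch).

1. **Zero-offset correction.** TDR depth drift is removed by subtracting a
   rolling low-quantile "surface" estimate: the 0.10 quantile of depth over
   a centred 300-s window (an odd number of samples, edge-replicated), with
   corrected depths clamped at >= 0. The method assumes the bird surfaces
   for at least ~10 % of any 5-minute window, which holds for dive-bout
   foraging.
2. **Speed filter.** Fixes whose implied speed to *both* temporal
   neighbours exceeds `vmax` (default 3.0 m/s, a plausible sustained swim
   speed) are removed iteratively; track endpoints are never removed. The
   two-sided rule cannot remove runs of consecutive bad fixes — a known
   limitation shared with simple neighbour-speed filters.
3. **Trip segmentation.** Maximal wet runs become foraging trips; dry gaps
   shorter than 10 min (brief haul-outs, sensor chatter) merge adjacent wet
   runs, and trips must span at least 1 h of wet time. The departure time
   is the first wet timestamp.
4. **Interpolation.** Latitude and longitude are linearly interpolated,
   independently, onto a 4-s grid anchored at epoch multiples of the grid
   step, so concurrently tracked birds share timestamps exactly. No
   extrapolation beyond the first/last retained fix.
5. **Phase labelling.** Grid points within 1 km of the colony are labelled
   `commute_raft` and excluded from association detection; everything else
   is `foraging`. The original analysis excluded rafting and commuting
   phases by visual inspection; a colony-radius rule is the reproducible,
   automated substitute, and the radius is a config field so its influence
   can be checked.

All distances are great-circle distances on a sphere of radius
6 371 008.8 m; sub-metre geodesic accuracy is irrelevant at the 500-m
criterion scale. Timestamps are integer epoch seconds.

## Association detection

A foraging association is two birds within **500 m** of each other for at
least **748 s** during the foraging phase of concurrent trips (the radius
is the average horizontal distance travelled during foraging; the duration
is the mean dive-bout length). Distances are evaluated at the shared
foraging-phase timestamps of a track pair. Maximal runs of in-radius
samples are assembled into events; interruptions shorter than `max_gap`
(default 60 s — a GPS dropout bridge) do not split a run but do not count
toward its duration either, which keeps the 748-s test conservative.
Events are dyadic; larger groups appear as overlapping dyadic events.

Derived summaries: partners per bird-trip (with colony x stage means),
percentage of tracked individuals associating, and re-association
percentages at three temporal scales — within a breeding stage (short),
between the guard and post-guard stages of one clutch (medium), and
between clutches (long). Denominators are, respectively: birds with at
least two trips in some stage; birds tracked in both stages of a clutch;
birds tracked in both clutches. Each summary reports its denominator.

## Dyadic inference

One Bernoulli observation per unordered pair per calendar day on which
both birds' trips overlap (`dyad x day`; a `dyad` collapse is available).
The study-scale AICc correction implies roughly 205–236 observations from
121 pairs, consistent with multiple shared days per pair, which is why
dyad-day is the default unit. Predictors: ln(departure gap in minutes
+ 1) (the +1 offset handles zero gaps and is configurable), same/different
sex pairing (indicator for a same-sex pair), nest distance computed from
nest coordinates, and |delta BCI| where BCI = mass / flipper (g/mm). Note
that nest distances computed from GPS-surveyed coordinates (±3 m) will
differ from tape-measured distances at metre scales.

**Model.** Binomial GLMM with a logit link and crossed random intercepts:
dyad, plus one intercept per bird shared across all dyads containing the
bird. Fitting is by Laplace-approximate maximum likelihood, written
in-package (`_laplace.py`) because no installed Python library fits
crossed-random-effect binomial GLMMs by ML: random effects are scaled
(`u = sigma * b`, `b ~ N(0, I)`) so variances can reach zero smoothly; the
inner joint mode over (beta, b) is found by damped Newton iterations using
the sparse random-effect design; the outer optimisation runs over the two
standard deviations (square-root parameterisation, Nelder-Mead) on the
profiled Laplace likelihood. Fixed-effect covariances come from the
beta-block Schur complement of the joint curvature at the optimum. At
sigma = 0 the fit reduces exactly to logistic regression (verified to
1e-6 against an independent IRLS implementation), and the Laplace marginal
likelihood agrees with 21-point adaptive Gauss-Hermite quadrature to
within 0.1 on single-grouping toy data. Fits that hit the iteration cap or
show separation (|beta| > 15) are flagged and excluded from ranking.

**Multimodel inference.** The candidate set is every subset of the four
main effects plus the departure-time x sex interaction added to each
subset containing both parents (marginality), 20 models in all. Models are
ranked by AICc with k = fixed effects + 2 variance components and n = the
number of dyad-day rows. The confidence set is the smallest AICc-ordered
prefix with cumulative Akaike weight >= 0.95. Averaging is conditional
(per term, over the models containing it, weights renormalised within the
confidence set; `full` zero-substitution averaging is available), with the
unconditional standard error
`sum_i w_i * sqrt(se_i^2 + (beta_i - beta_bar)^2)` and relative importance
`sum_i w_i` over models containing the term. Conditional averaging is the
variant whose per-term model counts match a published table of this
analysis type. Predicted association probability versus departure gap uses
the averaged intercept and slope; its band propagates the unconditional
SEs with zero covariance between averaged terms (the averaged covariance
is not identified), a stated approximation.

The colony comparison is a Gaussian linear mixed model of per-trip
association counts with a two-level colony effect and a bird random
intercept, fitted by ML via statsmodels (exact for the Gaussian case); the
reported F is the 1-df Wald statistic and the contrast is the second
sorted colony relative to the first. Profile-likelihood intervals for
individual models are not implemented (Wald only) — a limitation.

## Synthetic studies

The generator emits deployments, GPS, TDR and per-pair-day truth as pure
functions of a seeded config.

* **Deployments.** Birds come in nest pairs (mates, F/M); nests scatter
  within 30 m of the colony; BCI is Normal(10.24, 0.36) g/mm by default
  (a `gi_like` preset uses 9.12 ± 0.17 with a low association intercept of
  −2.5, chosen once to put the percentage of birds associating in the
  published 18–32 % regime for that colony type).
* **Schedule.** Guard days put exactly one mate per nest at sea
  (alternation), post-guard days everyone; the default schedule covers two
  stages in each of two clutches so all three re-association scales have
  non-empty denominators.
* **Departures.** Pre-dawn, Normal(04:30, 35 min); gaps between two birds
  are therefore half-Normal with mean 2·sd/sqrt(pi) ≈ 39.5 min, bracketing
  the published associating / non-associating gap means (32.13 and
  46.67 min).
* **Truth.** Per concurrent pair-day,
  `associated ~ Bernoulli(logit^-1(2.78 − 0.38·ln(gap_min + 1) + u_dyad +
  v_a + v_b))` with both SDs 0.5; dyad and bird effects are drawn once and
  reused across days, which makes re-association sticky.
* **Movement.** Association is planted, not emergent. Each day runs as:
  radial commute to a private "home" zone; a series of rounds in which the
  day's association graph, covered greedily by clique "sessions", sends
  each session's birds to a shared zone where they co-wander for 900 s
  (the planted window); and a synchronized radial return. Zones live on a
  lattice with 3-km spacing inside a 4–16 km annulus (within the published
  40-km range). Three mechanisms make non-associated pairs provably fail
  the 500 m / 748 s criterion: zone exclusivity (a session zone must not
  be occupied by outsiders), transit staggering (movers whose planned legs
  would dwell within 700 m of a non-associated mover for more than 600 s
  have their start times shifted in 400-s steps, checked against the
  planned trajectories directly), and equal-speed radial returns (pairwise
  separation is preserved down to the colony exclusion zone). Positional
  texture comes from an Ornstein-Uhlenbeck wander (sd 35 m, 120-s
  correlation time), small relative to all margins.
* **Sensors.** Truth positions are thinned to the 120-s GPS duty cycle
  with optional Gaussian noise (default 10 m) and i.i.d. dropout (default
  5 %); TDR emits 4-s depths with square-wave dive bouts during sessions
  and a linear surface drift (1 m/day) for the ZOC stage to remove.

What the generator does *not* emulate: emergent aggregation at prey
patches, bathymetry or tides, partial associations shorter than a session,
group sizes beyond the clique cap, or GPS error autocorrelation. Passing
the recovery tests therefore demonstrates that the detector and models are
correct for data satisfying their assumptions, not that the assumptions
hold for any particular field dataset.

## Numerical choices and problem sizes

* Detection counts each in-radius grid sample as one 4-s step; an event's
  `duration_in_criterion` excludes bridged gap time.
* AICc requires n > k + 1 and raises otherwise; Akaike weights are
  computed from deltas for numerical safety.
* The GLMM inner Newton uses step-halving and a gradient tolerance of
  1e-10 (relative); the outer tolerance is 1e-6 on the objective.
* Test and acceptance problem sizes were chosen as the smallest that
  exercise study-scale structure: oracle equivalence on up to 5 000-point
  tracks, detection recovery at 20 birds x 5 days, parameter recovery at
  ~406 dyads x 5 days x 50 seeds, and the full pipeline at 20 birds x 8
  days. The acceptance script reruns the whole chain at these sizes from a
  command-line seed.

## Known limitations

* The candidate-model degrees of freedom count fixed effects plus two
  variance components; published df columns for this analysis type imply a
  larger random-effect parameterisation that is not recoverable from the
  description, so the package's counting is used consistently.
* Conditional model averaging reproduces per-term model counts, but
  published relative importances for the two weakest terms in this
  analysis type do not all recompute consistently from the printed
  weights; only the well-determined importances are asserted in tests.
* The speed filter's two-sided rule, the colony-radius phase rule and the
  ln(x+1) gap transform are artifact decisions where the original
  description is silent; all are exposed in configs.
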