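# atsea

Detection and modelling of at-sea foraging associations between
concurrently tracked central-place seabirds.

Colonial seabirds such as little penguins (*Eudyptula minor*) often forage
in groups, but whether individuals at sea keep company with specific
colony-mates — and what predicts who pairs with whom — is hard to measure.
`atsea` turns raw biologging records (GPS fixes every ~2 min, time-depth
recorder samples every 4 s with a wet/dry flag, and deployment metadata)
into regularised foraging tracks, detects pairwise associations, and fits
the statistical models that ask which dyadic factors predict association.

**Association criterion.** Two birds are associating when they are within
a radius *r* = 500 m of each other for at least *τ* = 748 s during the
foraging phase of concurrent trips (*r* is the average horizontal distance
travelled during foraging; *τ* the mean dive-bout duration).

**Inference.** For every unordered pair of birds at sea on the same day,
a Bernoulli response y (associated / not) is modelled as

    logit P(y = 1) = β₀ + β₁·ln(Δt + 1) + β₂·sexPair + β₃·nestDist
                     + β₄·|ΔBCI| + β₅·ln(Δt + 1)×sexPair
                     + u_dyad + v_bird(a) + v_bird(b)

where Δt is the departure-time gap in minutes, BCI is body condition
(mass / flipper, g/mm), and u, v are crossed Gaussian random intercepts
(birds nested within dyad). All 20 marginality-respecting submodels are
fitted by Laplace-approximate maximum likelihood, ranked by AICc, and the
smallest set with cumulative Akaike weight ≥ 0.95 is averaged
(conditional averaging with unconditional standard errors and per-term
relative importance). A Gaussian mixed model compares association counts
per trip between two colonies, and re-association is summarised within
stages, between stages, and between clutches.

A fully seeded synthetic-study generator (`atsea.synthetic_data`) emits
deployments, GPS, TDR and ground-truth association labels with the
statistical structure the analysis assumes, so the entire pipeline is
testable without any field data.

## Worked example

```python
from atsea import pipeline as pl, synthetic_data as sd

run = pl.RunConfig(sim=sd.SimConfig(seed=3))   # 20 birds, 8-day schedule
report = pl.run_pipeline(run)                  # simulate -> ... -> fit
print(report.tables["model_table"].head(3).to_string(index=False))
print(report.tables["averaged_coefficients"]
      .to_string(index=False, columns=["term", "estimate",
                                       "unconditional_se", "importance"]))
```

prints (abridged):

```
         model  df      logLik       AICc    dAICc   weight
          logT   4 -437.951845 883.946470 0.000000 0.343670
  logT + dCond   5 -437.879452 885.823144 1.876674 0.134471
logT + sexPair   5 -437.924212 885.912665 1.966195 0.128584

        term  estimate  unconditional_se  importance
 (Intercept)  3.420831          0.505246    1.000000
        logT -0.573238          0.115310    1.000000
       dCond  0.179005          0.493897    0.267395
     sexPair  0.161150          0.380653    0.315902
    nestDist -0.000775          0.007782    0.232268
logT:sexPair -0.121900          0.219436    0.078959
```

The departure-time term (`logT`) carries essentially all the weight: birds
that enter the water within a few minutes of each other are far more
likely to forage together, and the averaged slope (−0.57 ± 0.12 here) has
a confidence interval well away from zero, while sex pairing, nest
distance and body-condition difference do not. That is exactly the
structure the generator planted (β₁ = −0.38 with dyad/bird random effects
of SD 0.5); the residual difference is one study's sampling noise.

The same stages are available as a CLI:

```bash
atsea simulate --seed 1 --out-dir study/
atsea preprocess --gps study/gps.csv --tdr study/tdr.csv \
    --deployments study/deployments.csv --out-dir pre/
atsea detect --tracks pre/tracks.csv --out events.csv
atsea run --seed 1 --out-dir results/     # all stages on simulated data
```

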