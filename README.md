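# discnav

Orientation-behavior analysis for **drifting in situ chamber (DISC)**
deployments of larval fish.

A DISC is a transparent circular arena (20 cm diameter) that drifts with the
current while a camera films a single larva from below and compasses record
the slow rotation of the chamber. From the digitized larva positions,
`discnav` answers the questions such deployments are run for:

* Does an individual larva keep a preferred direction (**Rayleigh test of
  uniformity** on its 1 Hz position bearings)?
* Is an apparent preference genuine orientation or attraction to a chamber
  feature (**camera- vs cardinal-frame concentration comparison** after
  compass correction)?
* Does the population share a common bearing, either in cardinal space or
  relative to an environmental cue — **sun azimuth, current direction, wind
  direction, natal-reef bearing** (second-order Rayleigh tests)?
* How do swimming speed, path straightness and orientation success change
  with **age** (OLS trends and a logistic regression with a likelihood-ratio
  test)?

Because raw field recordings are rarely shareable, the package includes a
seeded synthetic cohort generator that emulates the whole observation
chain — biased correlated random-walk larvae in a rotating arena, compass
series, GPS drift of the surface float, deployment metadata — under the
competing orientation-strategy hypotheses (H0 no strategy, H1 single
bearing, H2 condition-dependent, H3 context-dependent, H4 mixed), with
ground truth for every downstream stage.

## Statistics in brief

For bearings θ₁…θₙ (degrees clockwise from north), the mean resultant
vector has length r ∈ [0, 1] and direction θ̄ (the mean bearing). The
Rayleigh statistic is Z = n r², with p-value from the standard series
approximation

p = e^(−Z) · [1 + (2Z − Z²)/(4n) − (24Z − 132Z² + 76Z³ − 9Z⁴)/(288n²)]

and circular standard deviation √(−2 ln r) (radians). Per-larva mean
bearings are pooled as unit vectors in the second-order test. A deployment
is **non-oriented** when the cardinal-frame Rayleigh test is not significant,
**device-biased** when it is significant but the camera-frame concentration
exceeds the cardinal-frame concentration, and **oriented** otherwise.

## Worked example

Simulate a 30-larva mixed-strategy cohort (half the larvae aim east, half
west) and analyze it:

```sh
discnav simulate --seed 42 --n 30 --strategy H4_mixed --out demo/cohort
discnav analyze demo/cohort --out demo/run
```

```
Deployment classification
  total:          30
  non-oriented:   0
  device-biased:  0
  oriented:       30 (100.0% of larvae; 30 out of 30)

Second-order Rayleigh tests by orientation hypothesis
  hypothesis     ages    n        mean±SD     r      p
  cardinal        all   30    269.7 ± 1.80  0.20   0.31
  cardinal       2-10   10     93.1 ± 1.79  0.20   0.68
  cardinal      12-20   10    270.4 ± 1.80  0.20   0.68
  cardinal      22-30   10    270.6 ± 1.01  0.60   0.02
  ...

speed ~ age: slope 0.003917, intercept 0.3922, t = 31.09, df = 28, p = 0.00
turning ~ age: slope 0.1389, intercept 84.41, t = 3.52, df = 28, p = 0.00
```

Every larva orients individually (all 30 classified oriented), yet the
pooled test over all ages finds no common cardinal bearing (r = 0.20,
p = 0.31) — exactly the signature of a population using alternative
strategies rather than one shared goal. (The significant 22–30 dph cell is
small-sample noise: with ten larvae a 7:3 split between the two goals is
common.) The age trend in speed is recovered; the printed mean ± SD pairs
mix a mean bearing in degrees with a circular SD in radians, the convention
of orientation tables.

The same run writes machine-readable outputs (`per_larva.csv`,
`group_summary.csv`, `trends.csv`, `run_summary.json`) to `demo/run`, and
`discnav report demo/run` pretty-prints them. All analysis stages are also
importable as plain functions (`discnav.rayleigh_test`,
`discnav.classify_deployment`, `discnav.hypothesis_battery`, ...).

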