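# Methods

## The measurement and its statistics

A DISC deployment yields one larva's positions in a 10 cm-radius circular
arena, filmed from below while the chamber drifts and slowly rotates. The
analysis treats the **angular position** of the larva within the arena — not
its instantaneous heading — as the behavioral signal: a larva holding a
preferred compass direction accumulates positions on that side of the
arena. Tracks are reduced to one position per second (nearest frame at or
before each integer-second tick) after discarding a 300 s acclimation
window; both choices are configurable. Speeds are Euclidean displacements
between consecutive 1 Hz points; turning angles are the unsigned exterior
angles of three consecutive points (0° = straight, 180° = reversal), with
zero-length steps skipped. Bearings are computed for points at least 0.5 cm
from the arena center, where the angle is well conditioned; nearer points
are excluded and logged. One code path produces the 1 Hz series used for
speeds, turning angles and bearings alike — whether speed should instead be
measured on raw video frames is ambiguous in field practice, and using the
1 Hz series everywhere keeps the quantities commensurable.

All public angles are degrees clockwise from geographic north. The mean
resultant length r, mean bearing, circular SD √(−2 ln r) and the Rayleigh
test Z = n r² with its fourth-order series p-value are implemented in
`circstats`; the series is validated in the tests against the exact Pearson
random-walk null (numerical Bessel integral), which bounds its absolute
error below 0.005 for n ≥ 5, and against a 100,000-draw resampling oracle.
At r = 0 the mean bearing is reported as undefined (NaN) and the SD as
infinite rather than as arbitrary numbers. The second-order (population)
test pools per-larva mean bearings as **unweighted** unit vectors; weighting
by per-larva concentration is a defensible alternative but produces a
statistic whose null distribution is no longer the plain Rayleigh one, and
published orientation tables report a single r per group consistent with
unweighted pooling. α = 0.05 throughout (conventional; configurable).

## Frame correction and the device-bias filter

The compass series ties the rotating camera frame to geography:
cardinal bearing = camera bearing + chamber heading (the heading is the
compass direction of the camera-frame "up" axis; hardware wired with the
opposite sense is ingested with `rotation_sign = -1`). Compass lookups are
nearest-neighbor with a 2 s gap tolerance, and redundant compass units can
be fused by circular mean.

Classification of a deployment follows from two quantities: the
cardinal-frame Rayleigh p and the camera- vs cardinal-frame concentrations.
Not significant → *non-oriented*. Significant with rho_camera >
rho_cardinal → *device-biased* (the larva tracked a chamber feature that
rotated with the camera). Significant otherwise → *oriented*. The
measure-zero tie counts as oriented and is logged. If the chamber never
rotates the two frames coincide and device bias is undetectable in
principle; less obviously, a net rotation near an integer multiple of 360°
over the scoring window is equally degenerate, because the cardinal-frame
smear of an arena-fixed attractor integrates to zero over whole turns. The
synthetic generator's default rotation (0.25°/s, 225° per 900 s
acquisition) sits well away from both degeneracies; irregularly rotating
real chambers avoid them naturally.

## Reference directions

Per deployment the battery uses: **sun azimuth** from a NOAA-class solar
position algorithm (Meeus-type series; cross-validated in the tests against
an independently coded Astronomical Almanac ephemeris to 0.5°), evaluated
at the trial midpoint since azimuth drifts only a few degrees in 15 min;
**current direction** as the great-circle initial bearing between the first
and last GPS fix of the float (net displacement is robust to per-fix
jitter; displacements under a configurable 5 m noise floor flag the
estimate unreliable and drop the larva from that hypothesis only); **wind**
as a direction-toward input; and **natal reef** as the initial bearing from
the deployment start to the fixed transect midpoint. Great-circle bearing
and haversine distance use the mean-radius sphere, adequate at the sub-km
study scale (tests pin them to an R geosphere oracle). For each hypothesis,
each oriented larva's mean bearing is re-expressed relative to its own
deployment's reference, so cue-following appears as clustering near 0°; the
cardinal hypothesis uses the raw bearings. Cells are computed for all ages
pooled and for the developmental age groups (pre-flexion 2–10, post-flexion
12–20, pre-settlement 22–30 days post-hatch); cells with fewer than two
larvae are omitted with a log entry. Because the transformation subtracts a
per-deployment constant, a reference that does not vary among deployments
cannot change r or p relative to the cardinal test — only per-deployment
variation in the cue can.

## Ontogenetic trends

Mean speed and mean turning angle are regressed on age (days post-hatch;
age, not size, is the covariate of record) by OLS with t-based 95% bands
for the mean prediction. Orientation success (oriented vs not) is a
logistic regression on age fitted by iteratively reweighted least squares
(tolerance 1e-8, max 100 iterations; the deviance trace is exposed and
tested for monotone descent), reported with a likelihood-ratio χ² (df = 1)
against the intercept-only model — the χ²/df phrasing of such results maps
naturally onto a likelihood-ratio, not a Wald, statistic. Complete or
quasi-complete separation flags the fit unreliable instead of reporting a
divergent slope.

## The synthetic cohort generator

Each larva is a biased correlated random walk at 1 s steps: the new heading
is drawn von Mises with concentration `kappa_goal` (default 2) around the
circular blend of the previous heading (weight `persistence_weight`,
default 0.5) and the goal direction, plus a wrapped-normal turning jitter
whose SD declines linearly with age (60° − 0.9°·age, floor 25°) — the
mechanism behind ontogenetic straightening. Step length is
speed(age)·dt with truncated-normal noise (SD 0.1 cm/s); speed(age) =
0.4379 + 0.00607·age cm/s anchors the observed means of 0.45 cm/s at 2 dph
and 0.62 cm/s at 30 dph. The arena wall reflects radially; the true
wall interaction of confined larvae is unobserved, and reflection is the
choice that keeps bearing statistics interpretable. Strategies set the
goal: none (H0, uniform headings), one shared compass bearing (H1, default
270°, toward the reef), a 180° flip at a switch age (H2, east early / west
late, switch at 16 dph), the bearing to the nearest point of a configured
north–south reef line (H3), or a per-larva draw from a discrete mixture
(H4, default 50/50 east/west). Independently, a configurable fraction of
larvae carry their goal in the arena frame — the ground-truth device-biased
individuals. Chamber rotation is constant-rate by default with a
random-walk option. Deployment metadata emulate the study setting: starts
≈500 m east of a reef transect at 16.813°N 88.081°W with 150 m scatter,
morning/afternoon start times (local noon avoided) over May–August 2016,
GPS fixes every 60 s advected by a 4.38 cm/s current plus 3 m jitter, and
per-deployment wind directions. Every deployment is a deterministic
function of (seed, larva index).

## What the simulations do and do not establish

Passing tests on synthetic cohorts demonstrate that the pipeline recovers
what the generator encodes — goal bearings, strategy mixtures, frame of the
goal, age trends — under the generator's assumptions. Three caveats define
the gap to real data. **(1) Autocorrelation.** The Rayleigh test assumes
independent bearings, but 1 Hz positions of a walker that crosses the arena
in minutes are strongly autocorrelated; for a goal-free walker the
per-larva test over-rejects badly (its effective sample size is far below
the nominal 900). This is a property of applying an i.i.d. test to
trajectory positions — shared by the field protocol this package
implements — not an implementation artifact. Consequently the generator's
H0 larvae are not a calibration standard for the per-larva test; type-I
control is verified on i.i.d. uniform position samples, and H0 calibration
is verified across larvae (per-larva mean bearings are uniform;
population-level rejection sits at the nominal rate). Inference about
*population-level* orientation, which is what the hypothesis battery does,
is unaffected because larvae are mutually independent. **(2) Confinement
artifacts.** Wall reflection shortens recorded displacements and adds
apparent turns for fast, strongly goal-directed larvae, so trajectory-level
kinematic trends can be attenuated or even inverted relative to the
generative parameters; the regression machinery itself is therefore
validated on summary-level simulations with known coefficients, and the
straightening trend on a persistence-only scenario where confinement is
mild. **(3) Real sensory behavior** — cue interaction, depth preference,
tidal timing — is outside the generator's scope; it emulates observation
geometry and simple goal-keeping, nothing more.

## Problem sizes and numerical choices

Simulation-based checks use 100 replicate 120-larva cohorts for
common-bearing recovery, 200 trajectories per class for the bias filter,
1,000 uniform trials of n = 900 for type-I control, and 30 seeded cohorts
of 40 larvae for H0 calibration; these sizes put Monte-Carlo error well
below the asserted margins while keeping the whole suite fast. Angles are
canonicalized to [0, 360); r is clipped to 1 against rounding; p-values are
clamped to [0, 1]; the mean bearing is declared undefined below r = 1e-12;
IRLS weights are floored at 1e-10. Human-readable reports print bearings to
1 decimal and r, p to 2 decimals; machine outputs keep full precision, and
the analysis path contains no randomness, so reruns are byte-identical.

## Known limitations

Second-order tests ignore per-larva concentration (unweighted pooling);
confidence intervals for mean bearings and circular-circular correlations
are out of scope; the geodesy is spherical; the solar position is accurate
to well under 0.1° but unrefracted (irrelevant for azimuth); and the
device-bias filter is blind when net chamber rotation over the scoring
window is a multiple of 360°, including the zero-rotation case.
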