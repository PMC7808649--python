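# Methods

This note records the model behind the simulator, the signal-processing
contract, the statistical procedures, and the numerical choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate frame and course model

All positions live in a slope-fixed Cartesian frame: `x` lateral
(horizontal, across the slope), `y` the horizontal projection of the
fall line, `z` altitude. The slope is a uniform plane of relief angle α
(default 25°). The skier's line in the slope plane is a pure sinusoid

    x(u) = A · sin(π u / G),

with `u` the fall-line distance in the plane, `G` the gate spacing
(default 24 m) and `A` the gate offset (default 4 m, scaled per athlete
by a *line_scale* factor). Turn switches — curvature sign changes — fall
exactly at `u = jG` and gates at the lateral apexes. A sinusoid was
preferred over piecewise arc blending because it is C∞, has closed-form
curvature, and makes every downstream truth quantity analytic; the
analysis needs curvature, speed and force consistency, not snow
mechanics. Ski–snow contact, ski bending, edge angles and aerodynamic
drag as a separate term are out of scope (drag is folded into the
dissipation coefficient).

## Energy balance and speed

Speed evolves by a one-parameter energy balance: a fraction `c`
(*dissipation_coeff*) of the potential-energy release is dissipated,

    v(u)² = v0² + 2 (1 − c) g sinα · u.

`c = 0` is a conservative run, `c = 1` steady speed, `c` slightly above
1 a decelerating run; the simulator refuses configurations that would
drive `v² → 0` before the finish. This makes the per-turn change in
specific mechanical energy exactly `−c·g·sinα·G`, so the normalized
dissipation statistic has the closed form `−c·g·sinα·G / v_in` and
frictionless runs satisfy Δe_mech/v_in ≡ 0 — the anchor for the
conservation tests. Defaults (v0 = 15 m/s, c ≈ 0.88–1.02 across a
cohort) put course times near 26 s, entry speeds near 15–19 m/s,
altitude drop ≈ 10 m per turn and Δe_mech/v_in between −5 and −6.5
J·s/kg/m — the scale a practitioner would call a race-paced GS run.

## Force realization

The specific radial force demanded by the line is the centripetal term
plus the in-plane gravity component resolved along the radial
direction:

    F_r = v²·|κ| − g_inplane · n̂,

with `n̂` the unit vector toward the instantaneous turn centre. For a
slope-plane path this equals the familiar `v²/r ± g·sinα·cosβ` where β
is the angle between the velocity and the across-slope (contour)
direction — the convention under which the formula is physically
coherent: traversing (β = 0) puts all of in-plane gravity on the
radial axis, falling straight down the fall line (β = 90°) none of it.
The sign is resolved from geometry (whether in-plane gravity points
toward or away from the centre), never guessed.

The athlete realizes `F_tot = max(F_r, 0) / RF_capability` (a skier
cannot pull on the snow; short phases just after each switch where the
demanded F_r is negative are clipped, which is why the measured
course-level RF sits 2–4% below the injected capability). Total force
is split `limb_split : 1` (default 2:1) between the outside plate — the
plate on the convex side of the turn — and the inside plate, switching
at the inflections. Each plate's force vector has a fixed direction in
its own frame and is converted to raw sensor units through the inverse
of a per-boot calibration matrix (an invertible scaled rotation stored
in the run manifest). Additive per-axis Gaussian noise (default
0.03 BW), band-limited >10 Hz "vibration" during the run (default
0.05 BW) and per-channel raw offsets complete the sensor model.

Both streams carry the synchronization jumps: a symmetric Gaussian
vertical excursion of the COM (0.35 m, σ = 0.18 s) while standing
before and after the run, visible as an acceleration impulse on the
force-side accelerometer channel and as a position/velocity bump in the
trajectory stream. The trajectory stream (10 Hz, position plus derived
velocity) runs on its own clock with a configurable offset (±5 s by
default).

What the generator does **not** emulate: GNSS multipath and slow drift,
non-stationary vibration spectra, pole pushes and skating at the start,
terrain irregularities, or athletes' tactical line variation beyond a
global amplitude scale. Passing tests therefore demonstrate the
correctness of the processing chain under the stated stochastic model,
not robustness to every field artifact.

## Conditioning

Stages, in order: calibration matrices map raw channels to Newtons;
each axis is zeroed on the unloaded pre-run baseline and divided by
bodyweight (system mass × g, from the manifest); the per-limb resultant
is the Euclidean norm of the zeroed axes, clipped at zero. Zeroing is
applied per axis rather than to the resultant: zeroing the norm would
subtract the rectified baseline noise from every loaded sample and
leave a bias set by the offset–direction geometry (≈10% of F_tot at the
default noise level), whereas per-axis zeroing removes sensor offsets
exactly.

Clock alignment: jump impulses are detected on the force-side
accelerometer magnitude and, on the trajectory side, on the altitude
signal gated to stationary segments (horizontal displacement rate
< 2 m/s) and median-detrended per segment. Coarse alignment uses the
impulse peak-time difference; the fine lag maximizes a windowed,
linearly detrended cross-correlation between the trajectory stream's
vertical-velocity bump and the once-integrated force-side acceleration,
within ±100 force frames of each peak, with parabolic sub-frame
interpolation, averaged over the two events. Correlating two signals
that are both symmetric about the jump centre makes the estimate
unbiased under shape mismatch; the measured recovery error is ~1–3 ms
median at the default noise level (one 200 Hz frame is 5 ms).

The trajectory is then cubic-spline resampled from 10 to 200 Hz onto
the force clock, smoothed with a 2nd-order Savitzky–Golay filter
(201-frame window, polynomial edge fit), and low-passed with a
2nd-order Butterworth at 1.5 Hz; force resultants are low-passed at
8 Hz. Filters default to zero-phase (forward–backward, reflected
padding) so the two streams stay aligned — phase lag would corrupt the
force/trajectory pairing; a single-pass option exists. Velocity and
heading come from central differences of the filtered position.

A consequence worth knowing: zero-phase low-passing attenuates even
in-band oscillations slightly, so on a steep course the lateral
velocity component loses ~1% amplitude and per-turn energy bookkeeping
acquires an artifact of order 0.1 J·s/kg/m. The conservation property
(frictionless ⇒ Δe_mech/v_in = 0 within 1e-4) is therefore verified on
a gentle course (8 gates, 30 m spacing, 0.5 m offset, 2° relief) whose
lateral period sits deep inside both passbands; on the race course the
artifact is documented, common to all athletes, and averages toward
zero over the 14 analysis turns.

## Segmentation

Turn switches are zero crossings of the second time-derivative of the
lateral coordinate (inflections), located by linear interpolation,
restricted to moving samples (> 2 m/s) and thinned to a minimum turn
duration (0.6 s, well under the ~1.4–1.7 s observed turn times; first
crossing in a cluster wins). A derivative-magnitude floor rejects the
float-level garbage an exactly straight series differentiates to. A
third-derivative variant is provided: its zero crossings sit a quarter
cycle away (at gate apexes) on any sinusoid-like line, which is why the
inflection method is the default — it is the one consistent with turn
boundaries. Turn indexing is 1-based from the first detected switch;
turns 3–16 are retained (start push and final gate excluded) and mapped
to sections speed {3–5, 15–16}, overspeed {6–10}, flat {11–14}.

## Per-turn metrics

Radii come from the circumscribed circle of sliding point triples
spaced 60 frames apart (consecutive native-rate samples on the
upsampled clock), capped at 1000 m for near-collinear triples and
flagged; edge samples reuse the nearest interior fit. The per-turn
radius is the samplewise mean — a cap-dominated statistic (every turn
contains a near-straight phase), so it is reported but treated with
care in tests: triples straddling the inflection fit a finite chord
circle where the analytic radius caps, a ~1.3% bias documented in the
test suite. The radial force series projects gravity onto the unit
vector toward the fitted circumcentre (identical to the ± closed form,
with the sign resolved geometrically), and samples at the cap carry no
gravity radial term. Peaks are taken on the 8 Hz-filtered force series;
the outside limb is the plate opposite the mean turn-centre side; the
limb-difference mean excludes unloaded samples (F = 0) and reports
their count; Δalt is the altitude difference between switches; L is the
cumulated 3-D displacement; turn-level RF divides the turn-averaged F_r
by the turn-averaged F_tot, and course/section RF averages the per-turn
ratios (not the ratio of averages). Course time is the duration of the
moving phase on the synced clock.

## Statistics

Shapiro–Wilk screens each course-level variable; outliers are flagged,
never auto-deleted — exclusion is an explicit configuration action.
Pearson correlations report Fisher-z 95% CIs and magnitude labels at
|r| thresholds 0.1 / 0.3 / 0.5 / 0.8. Sections are compared with
one-way repeated-measures ANOVA (pingouin; Greenhouse–Geisser ε
reported, uncorrected F primary) with Holm-corrected paired post-hocs;
Cohen's d uses the pooled SD of the two conditions as the primary
variant with the difference-SD variant alongside, labelled at
thresholds 0.2 / 0.5 / 0.8 (four bins; the top bin is "strong").

Stepwise regression uses forward selection with a backward check at
p-to-enter .05 and p-to-remove .10 (the common defaults of desktop
statistics software; both configurable). Standardized β comes from
refitting the selected model on z-scored variables, so with one
predictor β equals Pearson's r; R²-change is the sequential increment
in final entry order and sums to the unadjusted model R²; the model F,
degrees of freedom, and adjusted R² are reported. An empty selection is
reported as "no clear model prediction" rather than an error. The
individual fits go through statsmodels OLS; the selection loop is
validated in tests against an exhaustive all-subsets replay computed
from normal-equation SSRs.

The stepped report runs Levels 1–4 on four datasets (course, speed,
overspeed, flat) from the same athlete rows, flags degenerate
correlations (e.g. a frictionless cohort has no dissipation variance),
and attaches an under-power warning below 10 athletes.

## Problem sizes and determinism

The default study configuration is 15 athletes on an 18-gate course —
a ~26 s run is 5–7k force frames, so the full pipeline (simulate,
condition, segment, metricize, model) completes in a few seconds.
Every random draw descends from a single integer seed through
`numpy.random.SeedSequence`; identical configurations reproduce
byte-identical artifacts, which the test suite asserts on the report
files.

## Known limitations

- The force direction per plate is fixed in the plate frame; real boots
  rotate relative to the snow, which only matters here because
  resultants, not components, feed the analysis.
- The measured course-level RF understates the injected capability by
  the negative-F_r clipping (2–4%); cross-athlete correlations are
  unaffected.
- The turn-mean radius is cap-sensitive by construction; comparisons
  between estimators need continuous-time windowing (see tests).
- Section contrasts (speed vs overspeed vs flat) emerge from the
  course geometry only through speed evolution; the simulator does not
  calibrate per-section gate geometry to reproduce any particular
  section means.
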