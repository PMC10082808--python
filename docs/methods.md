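# Methods

## Observables

The analysis treats a frontal dyad-individual encounter as a two-body
scattering event. All quantities derive from the relative position
**r**(t) = **r**_i(t) − **r**_g(t) between the individual and the dyad's
geometrical center, and the relative velocity **v** = **v**_i − **v**_g.
Velocities come from central finite differences on the sample grid
(one-sided at segment ends), which is exact for uniform linear motion.

- Window entry t′ is the first sample with |x| ≤ W and |y| ≤ W in the
  group-centered frame (W = 4 m by default). Runs of in-window samples
  separated by less than `window_merge_gap` (1 s) are merged — positional
  noise otherwise flickers the boundary test and splits one pass into many
  spurious entries — and runs shorter than `min_inside_duration` (0.25 s)
  are dropped. Longer gaps are genuine re-entries and become separate
  encounters. Encounters whose series starts already inside the window
  (trajectory segment splits) have no genuine window crossing; they are
  flagged and excluded from the analysis stage.
- The straight-line distance r_b = |r(t′) × v̄|/|v̄| uses the mean of the
  `velocity_averaging_samples` (default 4) relative-velocity samples
  ending at t′ inclusive. The inclusive convention is one reading of an
  ambiguous prescription ("before t′"); both are supported.
- The minimum distance r₀ minimizes the per-interval linear model
  r(t_k) + (t − t_k)v(t_k) in closed form: the perpendicular-foot
  projection clamped to the interval, with the segment model (not the next
  sample) evaluated when the projection clamps to the right edge, plus all
  sampled distances. Ties resolve to the earliest closest-approach time.
  A minimum attained at the final in-window sample is flagged as possibly
  censored.

### Frame choice and heading noise

Distance observables are rotation invariant, and the package computes
them in the translation-only relative frame. This matters numerically:
rotating each sample by the *instantaneous* finite-difference group
heading injects angle noise σ_θ ≈ σ_v/|v_g| that displaces rotated
coordinates by |r|·σ_θ — about 0.3 m at the window edge for 1 cm
positional noise at 20 Hz — and biases r_b upward by a comparable amount.
The rotated frame (used for the window test and the 2D maps) therefore
takes its angle from the group velocity smoothed over 0.5 s; heading is a
low-frequency quantity and the smoothing leaves straight-walking groups
exact.

## Scaled distances and intrusion

Each social class's unit of distance is the unweighted mean over its
dyads of the per-dyad time-mean member separation. An individual with
scaled minimum distance r̄₀ < 1 passed closer to the dyad center than the
members stand from each other (intrusion); r̄₀ < 0.5 undercuts the mean
member-to-center distance itself. Intrusion probabilities are empirical
fractions per (class, r̄_b-bin); class independence is tested per bin with
Pearson's χ² (no continuity correction) on the class × {intrude, pass}
table, flagged unreliable when an expected count falls below 1. Per-bin
class differences in r̄₀ use classical one-way fixed-effects ANOVA; a bin
needs at least two classes with n ≥ 2, and zero between-class variance
returns F = 0, p = 1 rather than NaN.

## The straight-line-distance calibration

In environments that are not straight and open, the straight-line null
overestimates r̄_b at large separations. The calibration fits
r̄₀ = a·r̄_b + c by least squares on the regime r̄_b ≥ 2 (where avoidance
is assumed negligible) and replaces r̄_b by a·r̄_b + c everywhere. In an
unbiased environment it reduces to the identity (slope 1, intercept 0 to
rounding). Two caveats, both verified on synthetic data:

- For a power-law avoidance potential the calibration regime still
  contains genuine signal (r̄₀ − r̄_b ≈ K/2r̄_b), so in an *unbiased*
  environment the correction subtracts real long-range avoidance and
  steepens the apparent potential substantially. Simulator-based studies
  of straight corridors should run with `rb_correction=False`; the
  default keeps it on for field data.
- With too few calibration points the correction is skipped (identity)
  with a warning.

## The potential probe and its estimator

U′(r₀) = (r₀² − r_b²)/r₀² is evaluated per (class, bin) at the bin's mean
r̄₀, with the bin's mean r̄_b as the straight-line representative (the
bin midpoint is available via `rb_representative="midpoint"`; the mean is
the default because it makes the probe vanish identically when r₀ = r_b
per encounter). Only U′ < 1 is probeable — the kinetic scale is held
fixed — and the relative speed at entry is recorded per encounter so the
near-constant-speed assumption can be checked.

Fitting `k/r^β` and `a·e^{−cr}` uses weighted nonlinear least squares:

- per-point 1σ uncertainties propagate the standard errors of the two bin
  means, including their (positive) covariance;
- a systematic floor of 5% of the probe's dynamic range is added in
  quadrature — the probe carries bin-level systematics (see below) outside
  the two-parameter family, and without the floor near-zero tail points
  with tiny standard errors force runaway exponents;
- points with straight-line distance beyond the window half-width are
  flagged `censored` and excluded: such undisturbed paths can only clip
  the window near a corner, so their closest approach is truncated by the
  boundary rather than measured;
- negative-U′ points (noise around a small positive tail) are kept:
  dropping data by sign censors the noise asymmetrically and biases the
  fitted decay shallow. They stay flagged in outputs.

Known systematics of the probe, quantified on simulator ground truth:

- *Finite-window truncation.* The scattering relation assumes U → 0 where
  v∞ and r_b are measured, but entry happens at r ≈ W where
  U(W) > 0; the probe actually measures U(r₀) − U(r_entry), steepening
  the apparent decay. For β_true = 2 under the default conditions this
  inflates the apparent exponent by roughly 10–25%, most for weak
  potentials.
- *Quantization noise.* Binning on the measured (noisy) r̄_b mixes
  neighboring true values, inflating the first bin's probe.
- *Intrusion mixture.* Encounters where the individual walks straight
  through flatten the low-r̄_b bins.

These are properties of the estimator as defined, not of the
implementation; the parameter-recovery test documents where the recovered
exponent lands under the default study conditions.

## Synthetic encounter generator

The generator is a ground-truth harness, not a calibrated human model.
Each encounter integrates 2 + 1 pedestrians with fixed-step explicit
Euler at `sampling_period/10` (downsampled to `sampling_period`, default
0.05 s), under:

- goal attraction (v_des − v)/τ with τ = 2 s toward a fixed desired
  velocity of magnitude ~N(1.2, 0.2) m/s (truncated to [0.6, 2.9]) — τ is
  deliberately long so that steering is weak on the encounter timescale
  and the window-interior dynamics is close to conservative;
- a dyad cohesion spring about the per-dyad target separation
  d ~ N(d_class, sd_class); the goal term supplies the damping. The
  in-dyad interaction of real pedestrians is not known in this form — the
  spring is a stand-in that holds the abreast formation;
- a central repulsion with |dU/dr| for U = k_true/r^β_true between group
  center and individual, full strength on the individual and a mobility
  factor (default 0.5) on each dyad member — groups deviate less than
  individuals. A floor r ≥ 0.05 m avoids the singularity, far below any
  analysis scale. With probability `intrusion_propensity` the repulsion
  is suppressed for the whole encounter, the simplest mechanism producing
  the observed pass-through/avoid bimodality.

Individuals start `start_gap` = 10 m ahead on the opposing heading with a
lateral offset uniform in [0, 5] m (random side), spanning straight-line
distances from 0 to beyond the window. Sampled positions carry additive
Gaussian noise (default σ = 1 cm, a typical tracking accuracy). Encounters
occupy disjoint time blocks, so the pipeline's overlap-based pairing
reconstructs them without consulting ground truth. All encounters of a
class are integrated as one vectorized batch; one seeded generator drives
every random draw.

What the generator does *not* emulate: environment geometry (walls,
obstacles, curvature — hence no environment bias for the r̄_b calibration
to correct), multi-party interactions inside the window, anticipatory or
velocity-dependent avoidance, and cultural left/right asymmetries.
Passing tests therefore validate the measurement chain and the
qualitative class ordering, not behavioral realism.

## Problem sizes and defaults

Default study sizes keep every stage comfortably interactive: the
parameter-recovery experiment uses three classes × ~500 encounters
(~8 s simulated + analyzed), the null-equivalence check 200 encounters,
the kernel-oracle comparison 1000 random series at 1e-9 agreement. Maps
use a 10 cm grid over the ±4 m window. Speed filtering keeps
[0.5, 3.0] m/s segments of at least 1 s; frontal selection requires at
least 135° between group and individual headings at entry. Each default
is a config field and is logged with the run.

## Degenerate inputs and edge cases

Groups with no overlapping member support, or stationary throughout, skip
with a logged signal; zero averaged entry velocity excludes the encounter;
an analysis with zero surviving encounters raises an explicit
empty-analysis error rather than writing empty tables. Fits need three
usable points (otherwise skipped), an all-zero probe returns a degenerate
k = 0 fit, and non-convergence reports the log-log initializer flagged as
such. Every filtering stage logs before/after counts, and the counts are
asserted to reconcile in the test suite.
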