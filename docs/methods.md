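# Methods

This note documents the measurement model implemented by `dyadmotion`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the procedure was
genuinely open.

## Measurement model

**Input.** Uniformly sampled 3-D marker positions for two actors (mother,
infant), one marker set each: head, and wrists/elbows/shoulders on both
sides. Positions are stored in metres; files are typically exported in
millimetres by optical capture systems, so the reader takes an explicit
unit flag. Time is in seconds; frame *i* covers the half-open interval
[i/fs, (i+1)/fs), and all intervals in the package are half-open.

**Pre-processing.** Recordings are trimmed to the rated interaction window
(defaults: starting at 120 s; 180 s long for the 4-month age group, 300 s
for the 13-month group — the windows under which the behavioural ratings
are made). Missing samples are carried in a per-marker validity mask. If
any marker is invalid for ≥ 5% of the window, the dyad is rejected (the
standard missing-data policy for this kind of data; rejection reasons are
collected in a QC report). Otherwise missing runs are filled by
per-coordinate linear interpolation between the flanking valid samples;
runs touching the window edge, which lack one anchor, hold the nearest
valid sample instead of extrapolating. The filled series is low-pass
filtered with a 4th-order Butterworth at 10 Hz, applied forward–backward
(`sosfiltfilt`). Zero-phase filtering was chosen because phase lag would
systematically delay movement onsets, which the coordination features
compare against a 1.5 s response window; the effective magnitude response
is the squared single-pass response, 1/(1 + (f/f_c)^8), and tests check
against that closed form.

**Kinetic energy.** Each actor's upper body is modelled as up to seven
mass-carrying segments: head, forearm+hand and upper arm per side, and the
two shoulders. Segment masses are fractions of total body mass; the
defaults (head 0.081, forearm+hand 0.022/side, upper arm 0.028/side)
follow the Winter anthropometric tables. A discrete "shoulder" segment has
no entry in those tables; its default fraction (0.05/side) is a documented
configuration placeholder, and all fractions are configuration, not
constants — no test depends on their values. Infant fractions default to
the adult values with a config hook for rescaled values. Segment centres
of mass are estimated geometrically: head = centroid of the head markers,
forearm+hand = the point a configurable fraction (default 0.5) along
wrist→elbow, upper arm = the same along elbow→shoulder, shoulder = the raw
shoulder marker. Velocity comes from central finite differences on the
filtered positions (one-sided at the ends) — the 10 Hz low-pass already
suppresses differentiation noise, so no further smoothing is applied.
Energies are K = Σ ½ m v² over the segments entering a body part (head;
arms = forearms ± upper arms; upper body = all present segments), in
joules. At 4 months the infant's shoulder markers are unusable, so the
shoulder and upper-arm terms are dropped from that actor's model.

**Segmentation.** The movement threshold is 20% of the actor's own
spike-robust mean energy, per body part ("per-recording" thresholds; a
grand mean across a cohort could be supported by computing the mean
externally and is deliberately not the default). The robust mean removes
sparse spikes from impulsive movements by discarding samples above a
percentile (default 99th) — the removal method is not prescribed by the
procedure this implements, and a percentile cut is scale-free and
configurable. "Moving" is strict inequality (E > threshold), so
exact-equal frames are silence, and spikes — above threshold by definition
— never break a movement. Cleaning applies merge-then-discard, in that
order: pauses shorter than 350 ms are merged away left-to-right, then
movements shorter than 350 ms are discarded (350 ms being a typical visual
reaction time; shorter events would not register as movement to an
observer). Boundary reading is strict: exactly-350 ms gaps and movements
survive. A consequence of the order is that two 200 ms bursts 100 ms apart
survive as one 500 ms movement. Both cleaning rules are idempotent, and
cleaned lists satisfy min-duration ≥ 350 ms and min-gap ≥ 350 ms by
construction (property-tested).

**Features.** Activity, overlap and silence ratios are interval-measure
computations over the window and satisfy the inclusion–exclusion identity
infant + mother − overlap + silence = 1. Onset features use a 1.5 s
response window: an onset is *coactive* when it falls inside a partner
movement and within 1.5 s of that containing segment's onset (the
containing segment, not any earlier one, is the reference), and
*alternating* when the partner is still and the most recent partner offset
is within 1.5 s. "Within 1.5 s" is read inclusively (≤), and an onset
coinciding exactly with the partner's onset counts as coactive by default
(configurable, since the convention is not prescribed). The two conditions
partition time at the onset, so no onset is both. Ratios divide by the
target actor's movement count in the window; an actor with no movements
has undefined ratios, reported as missing values — never zero, which
would masquerade as "no coordination" — and excluded pairwise from
correlations.

**Rating statistics.** Composites are arithmetic means of their
constituent 1–5 scales after reversing any reversed-oriented scale
(r → 6 − r); membership differs by age group and lives in a YAML map
(shipped default in `dyadmotion/data/cib_composites.yaml`) rather than in
code, because the membership is a coding-manual decision, not an algorithm.
Cronbach's α uses the k/(k−1)·(1 − Σσ²ᵢ/σ²ₜ) form with n−1 variances.
ICC(2,1) is the two-way random effects, absolute agreement, single-measures
coefficient from the ANOVA mean squares, with the McGraw–Wong F-based 95%
interval; a degenerate table yields a coefficient ≤ 0 reported as-is.
Spearman correlations use average-tied ranks with the t-approximation
(n − 2 df) for the two-tailed p — appropriate at the sample sizes this
pipeline targets (tens of dyads) — plus an exact-permutation option for
n ≤ 9 used in tests. Cells are computed pairwise-complete with n reported
per cell, and no multiplicity adjustment is applied by default (matching
the per-cell convention of the correlation-table design); a
Benjamini–Hochberg option exists behind a flag for responsible reuse.

## Synthetic data

The generator emulates the recording regime (two actors × seven markers,
240 Hz) and plants exactly the structure the pipeline is supposed to
recover.

*Episodes.* Each actor alternates movement and pause via a renewal
process; durations are min + exponential (defaults: movements mean 1.5 s,
pauses mean 2.0 s, minimum 0.5 s). The 0.5 s floor guarantees planted
structure passes the 350 ms cleaning unchanged. During an episode, all of
an actor's markers translate together along a random direction at a
constant per-episode speed drawn from U(0.10, 0.20) m/s (displacement
amplitude = speed × duration). A constant-speed plateau — rather than a
smoothly peaked profile — keeps the energy unambiguously above the 20%
threshold for the entire episode and confines threshold-crossing error to
the onset/offset samples; a raised-cosine position profile was considered
and rejected because its speed dips through zero mid-episode (splitting
segments) and crosses the threshold tens of frames from the true onset.
The ≤ 2:1 speed range keeps every episode's plateau energy above the 20%
threshold regardless of the activity fraction. Episode boundaries are
snapped to the frame grid, so ground truth is recoverable to within one
sample.

*Coupling.* Infant onsets are re-timed to the mother's schedule: with
probability p_co the onset lands inside a mother episode at a latency
drawn from U(0.1, 1.4) s after her onset (coactive); with probability
p_alt it lands in a mother pause within the same latency of her offset
(alternating); the remainder are placed to violate both definitions (more
than 1.5 s after the relevant reference, with a 0.1 s safety margin so
one-sample boundary errors cannot flip a label). Ground truth is therefore
constructive — labels are planted, not inferred — and on noise-free data
the measured onset ratios equal the planted label fractions exactly.

*Degradations.* Sensor noise is i.i.d. Gaussian per coordinate (default
sd 0.3 mm, typical of optical capture; after the 10 Hz low-pass its
velocity contribution is ~0.01 m/s, an order below episode speeds).
Spikes are single-sample position jumps during movement episodes
(impulsive movements), scaled by an amplitude multiplier. Missing data are
contiguous runs per marker (occlusion behaviour), never exceeding the
requested fraction by more than one run length.

*Cohorts.* For end-to-end correlation recovery, `generate_cohort` sweeps
one generative episode duration linearly across dyads using deterministic
schedules (mother's schedule fixed across dyads), which makes the
extracted target feature strictly monotone in the parameter — adjacent
dyads differ by ~10 frames of movement time, far above the one-frame
boundary quantisation. A synthetic composite on the 1–5 scale is coupled
to the parameter through a Gaussian copula at Pearson r = 2 sin(πρ_s/6),
so the population Spearman correlation with the extracted feature is the
planted ρ_s — and exactly 1 when ρ_s = 1, since both sides are then
strictly monotone in the parameter. Only duration-parameterised targets
(silence, activity and overlap ratios) support planting: onset-ratio
features are integer-count-valued per dyad and cannot be made strictly
monotone across a continuum of dyads.

*What passing tests do not show.* The generator's kinematics are
deliberately minimal: rigid whole-body translation, no limb articulation,
no camera-geometry occlusion, no rater behaviour beyond a monotone
composite. Recovery results therefore validate the pipeline's algorithmic
contracts (thresholds, cleaning, onset logic, statistics), not its
behaviour on the full complexity of real infant movement — in real data,
body parts move differentially and segmentation boundaries are genuinely
uncertain at the tens-of-milliseconds scale.

## Numerical choices and edge cases

- Boundary-recovery checks run the energy/segmentation stages without the
  10 Hz low-pass: zero-phase filtering spreads a speed step over roughly
  1/f_c ≈ 25 ms (≈ 6 samples at 240 Hz), so one-sample agreement through
  the filter is physically impossible; the filter is verified separately
  against its closed-form magnitude. With filtering enabled, boundaries
  agree to ~25 ms, which leaves the features themselves essentially
  unchanged (the planted-correlation recovery runs with the filter on).
- Perfectly concordant or discordant rank vectors return Spearman ρ = ±1
  exactly rather than 1 − ε from floating-point rounding of the
  rank-Pearson form.
- The 5% missing rule is enforced per marker over the trimmed window (the
  strictest defensible reading; the threshold is configurable). A marker
  with zero valid frames always rejects.
- An all-silent energy series (robust mean 0) yields an empty segment
  list rather than dividing by zero; constant rating vectors yield missing
  correlations; correlation cells with n < 3 are missing.
- Problem sizes in tests and the acceptance script use 60 s synthetic
  windows and cohorts of up to 200 dyads — large enough that binomial and
  Fisher-z bounds are informative while keeping full runs to a few
  minutes; the study-length windows (180/300 s) remain the defaults for
  real recordings.

## Known limitations

- No rotational kinetic energy, leg features, or full-body models; no C3D
  binary input (TSV only); no gap-filling beyond linear/hold; no rigid-body
  relabeling of swapped markers.
- Infant mass fractions default to adult values pending better
  anthropometric configuration; results scale multiplicatively within an
  actor, so segmentation and features are unaffected by the choice.
- No windowed or time-varying synchrony measures (cross-correlation,
  wavelet coherence); coordination is summarised only through the onset
  definitions above.
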