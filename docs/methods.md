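# Methods

## Trajectory model and kinematics

Tracks are time-stamped centroid positions in arena-frame centimetres
(origin bottom-left, x right, y up).  Tracking dropouts arrive as blank
cells; gaps no longer than 0.5 s are linearly interpolated (and stay
flagged), longer gaps split the record into independent segments that
every downstream computation treats separately.  Coordinates that
overshoot a wall by at most 1 cm are treated as tracker jitter and
clipped to the boundary; larger excursions are rejected with the
offending rows, as is any file with non-monotone time or more than 50%
missing samples.

Speed is the displacement over one inter-sample interval divided by dt,
assigned to the interval's endpoint (the first sample copies the first
interval so every sample is classifiable).  Samples below 0.2 cm/s are
*resting*; the threshold applies to the raw one-interval speed with no
hysteresis, matching the single printed cut-off used by tracking
software.  Heading is the direction of the displacement across a centred
5-sample window (±2 samples, ≈ ±80 ms at 25 Hz); it is undefined while
resting, at segment edges, and when the window displacement is
degenerate.  Only the centroid is tracked, so "body midline" everywhere
means this smoothed motion direction.

## Wall-following scoring

The near-wall belt is the rectangular annulus within 0.5 SL of any wall;
membership uses the minimum wall distance with inclusive boundaries, so
a point exactly on the belt edge is inside and corners are counted once.
A candidate bout is a maximal run of consecutive in-belt samples within
one segment; its in-belt path is the summed displacement between
consecutive in-belt samples.  The bout becomes a wall-following event
only if that path reaches 2 SL — sub-threshold visits contribute nothing
to WF-Distance, WF-Time or WF-Frequency.  WF-Frequency counts qualifying
events by default; a permissive switch (`count_all_entries`) counts every
belt entry instead, since the verbal definition ("frequency at which fish
swam into wall-following range") admits both readings.  Resting frames
inside an event extend WF-Time but are excluded from WF-Speed's
denominator (it is the average *swimming* speed while wall-following);
WF-Max Speed and WF-Resting Time are whole-assay quantities.

## Stimulation metrics and approaches

The stimulation range is a 10 × 16 cm axis-aligned rectangle (16 cm along
x) centred on the stimulus, boundaries inclusive.  Zone time assigns each
interval to the membership of its endpoint so in-zone and out-of-zone
time sum exactly to the analysed time.  S-Speed and S-Max Speed are
per-interval speeds at in-zone samples (the average excludes resting
intervals).  S-Max Speed is deliberately an in-zone quantity here — the
internally consistent reading of an S-indicator — while WF-Max Speed
retains its whole-assay definition.

An approach bout runs from range entry to exit; only the first three are
kept.  Angle and distance are measured at the bout's frame of minimal
body-to-stimulus distance by default (`measure_at="entry"` gives the
alternative, since the original protocol does not state its frame).  The
fish body is a 1-D segment of length SL centred on the centroid along
the smoothed heading; approach distance is the segment-to-source-boundary
gap (source radius 2.5 cm by default, also for the vibration pump, whose
physical footprint is not recorded), clamped at zero on contact, in SL.
If the heading is undefined at the chosen frame the nearest frame with a
defined heading supplies it and the record is flagged.

## Swim simulator

The generator is a correlated random walk with behavioural states:

- **Speed.**  While mobile, per-step speeds are lognormal with the
  preset's mean and SD in SL/s (eyeless 0.52 ± 0.20, micro-eyed
  0.45 ± 0.21, normal-eyed 0.36 ± 0.20), scaled by the individual's SL.
- **Rest switching.**  A two-state Markov chain with per-second rates
  (`rest_on`, `rest_off`); stationary resting fraction
  `on/(on+off)`.  Presets rest more as eyes improve (0.02/0.50,
  0.04/0.40, 0.08/0.30 Hz), reproducing the resting-time indicator.
- **Turning.**  Wrapped-normal heading noise with per-step SD
  `sqrt(dt/κ)`, κ = 8 s — a standard correlated-random-walk choice; no
  empirical guidance exists for these species.
- **Wall attraction.**  Inside a 1 SL sensing range the heading relaxes
  toward a target blending the nearest-wall tangent (sign matched to the
  current heading) with a component toward the wall that grows with wall
  distance, at rate β·sin(target − heading) per second.  Preset gains
  β = 0.55 / 0.45 / 0.30 were fixed once, by a coarse scan, so that
  median WF-Time and WF-Distance sit near the observed per-morph levels
  (≈74/69/57 % and ≈220/170/100 SL over 600 s) while keeping the strict
  eyeless > micro-eyed > normal-eyed ordering; they were not revisited
  afterwards.
- **Stimulus attraction.**  An analogous γ·sin(bearing − heading) torque
  toward the stimulus centre.
- **Boundaries.**  Specular reflection, so path lengths stay well defined
  and positions never leave the arena.

What the simulator does *not* emulate: body orientation distinct from
motion direction, burst-glide micro-structure, hydrodynamic and
lateral-line sensing, inter-individual personality differences, and
tracking noise or dropouts (tests that need gaps construct them
explicitly).  Passing tests therefore demonstrate correctness of the
scoring, statistics and inference machinery under a plausible generative
model — not behavioural realism of any particular species.

## Statistics

Kruskal–Wallis uses mid-ranks and divides H by the tie factor
1 − Σ(t³−t)/(N³−N), with an upper-tail χ²(k−1) p-value.  Dunnett's T3
computes pairwise Welch statistics with Satterthwaite df and adjusts via
the studentized-maximum-modulus tail for m = k(k−1)/2 independent t
variates, `p_adj = 1 − (2F(|t|; ν) − 1)^m` — a Šidák-style bound for the
dependent case that reduces exactly to Welch's test at k = 2.  The
published Z-type T3 statistic has no stated construction and is not
reproduced.

The count regression is a fixed-effects NB2 GLM (log link, jointly
ML-estimated dispersion, via statsmodels) on per-trial rows; the
repeated-measures random-effect structure of a GLMM is deliberately out
of scope, and WF-Distance in SL is rounded to the nearest integer to
serve as the count response (the original analysis fit a negative
binomial to it without stating a discretisation).  Model averaging fits
candidate predictor subsets, computes AICc = −2logL + 2k + 2k(k+1)/(n−k−1)
(k counts the dispersion parameter), retains ΔAICc ≤ 2, normalises
Akaike weights over the retained set, and full-averages coefficients with
absent terms as zero; adjusted SEs fold in between-model spread,
Σᵢ wᵢ √(seᵢ² + (βᵢ − β̄)²), and a parameter is flagged important when its
95% CI excludes zero.  Candidates that cannot support AICc (n ≤ k+1) are
dropped with a warning.

## Phylogenetic signal

The Brownian covariance C has C_ij = root-to-MRCA path length and
diagonal root-to-tip depths; Pagel's λ multiplies only the off-diagonals.
λ is profiled by ML — μ and σ² have closed GLS forms at each λ — over a
21-point multistart grid refined by bounded scalar minimisation
(xatol 1e-9), with boundary snapping.  The search is bounded to [0, 1]
(the convention of the tool the original analysis used) even where larger
values would keep C(λ) positive definite.  On a star tree the likelihood
is flat in λ and 0 is returned by convention; zero-variance traits raise.
The LRT against λ = 0 uses a plain χ²(1) reference, conservative at the
boundary; the 50:50 mixture is available via `boundary_mixture=True`.
PGLS fits GLS with C(λ) (λ fixed or jointly profiled); coefficient SEs
use σ̂² = RSS/(n−p).  Species enter these analyses as trial means, and
clade summaries report per-clade mean ± SD with Kruskal–Wallis and
Dunnett-T3 comparisons, excluding clades with fewer than two trials.

## Pipeline and problem sizes

`run_study` drops trials whose mobile time is below 10% of the recorded
duration (configurable), logging each drop, and writes all tables with a
fixed float format so outputs are byte-reproducible for a given seed.
The fixture study uses the 13 assayed species (7 normal-eyed, 4
micro-eyed, 2 eyeless) on a synthetic ultrametric 13-tip chronogram
(root depth 10) whose four clades place the eyeless pair and most
stygomorphic species in clade B; it is a stand-in topology, not the
published tree.

Test and acceptance runs use deliberately modest problem sizes — e.g.
60–600 s simulated assays, 10–30 seeds per condition, 200 replicates of
λ recovery on a 64-tip tree, 100 replicates of NB recovery at n = 500 —
chosen as the smallest sizes at which the statistical assertions are
stable across seeds.

## Known limitations

- Heading from centroid displacement underestimates true body-axis
  orientation during turns and is undefined at rest; approach angles
  inherit this.
- The event definition resolves two genuine ambiguities (frequency
  reading; measurement frame of approaches) by documented defaults with
  switches, so absolute indicator values can differ from analyses that
  chose otherwise.
- The NB fixed-effects model ignores within-individual correlation;
  standard errors for repeated trials of the same fish are optimistic.
- χ²(1) boundary p-values for λ are conservative; with 13 species power
  to detect signal is low regardless.
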