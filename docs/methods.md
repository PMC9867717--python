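# Methods

`rheokit` reimplements a rheotaxis-profiling analysis for larval zebrafish:
from per-frame keypoint tracks of a single larva swimming in a 30 × 30 mm
flume working section, it derives rheotaxis event calls, circular statistics
of body angle, arena occupancy, trend/periodicity/noise decompositions with
power spectra, and lagged cross-correlations between linear and angular
kinematics.  A synthetic burst-and-glide swimmer with known ground truth
stands in for video-derived data, so every stage of the pipeline can be
validated by parameter recovery.

## Coordinate and stimulus conventions

The arena frame has its origin at the front-left corner with +y pointing
downstream; the upstream unit vector is (0, −1).  Heading is the signed
angle between the body axis (swim bladder → eye midpoint, single eye if one
is missing) and upstream: 0° = facing directly into the flow, positive =
right of upstream, wrapped to (−180°, 180°].  The default trial is 30 s:
no flow 0–10 s, initial flow 10–20 s, final flow 20–30 s, with flow at
9.74 mm s⁻¹ along +y.

## Track ingestion, QC, and binning

Pose tables are read either as the three-level-header wide table exported
by markerless trackers (scorer/bodyparts/coords; CSV or HDF5) or as a plain
long table (`frame, bodypart, x, y[, likelihood]`).  Pixel coordinates are
divided by `px_per_mm`; samples below the likelihood threshold
(default 0.6 — trackers rarely publish their operating point, so it is
configuration) become missing and are never zero-filled or imputed.

Outlier correction follows the movement/location two-rule scheme with
criteria expressed in body lengths (defaults 0.7 and 1.5; body length =
median eye-midpoint→tail-tip distance).  The location rule uses the
**median** frame centroid, which a single teleported keypoint cannot drag.
Flagged samples are replaced by the keypoint's last accepted value
(hold-last) rather than interpolated, because interpolation fabricates
motion that the event classifier would score.  The fraction of missing
samples is computed before any correction, and tracks above the 4 %
missing-data norm are flagged with a warning.

Tracks recorded at 200 or 60 fps are quantized into 100-ms bins (20 or 6
frames per bin), the lowest common bin of the two frame rates.  Per-bin
keypoint positions are means over valid frames.  Three frame-level features
are pre-aggregated during binning because the event rule needs them:

* **distance** — swim-bladder path length, with each inter-frame step
  assigned to the bin of its first frame (so per-bin distances sum to the
  total path, and uniform motion of 1 mm per bin reads exactly 1 mm);
* **upstream displacement** — net first-to-last valid frame displacement
  projected on upstream;
* **tail amplitude** — peak-to-peak lateral excursion of the tail tip
  about the **bin-mean** body axis.  A per-frame axis would leak eye and
  swim-bladder jitter into the tail amplitude through the ~2.8 mm lever
  arm of the tail tip (0.02 mm of keypoint noise maps to ~0.4 mm of
  apparent tail motion), which falsely classifies frozen fish as beating
  their tails.

Velocity is the magnitude of the first difference of the binned position
divided by the bin width; acceleration is the first difference of velocity.
Differences across missing bins stay missing.

## Rheotaxis events

A positive rheotaxis event is a maximal run of consecutive valid bins in
which the fish (i) holds |heading| ≤ 45°, (ii) shows tail-beat amplitude at
least `tail_amp_min` (default 0.3 mm; undocumented in the source assay,
exposed as configuration), and (iii) translates strictly upstream.  Runs
shorter than 100 ms are discarded; a single invalid bin breaks a run.  The
tail and translation requirements separate active swimming into flow from
passive downstream drift at a compliant body angle — drift at 9.74 mm s⁻¹
with heading 0° never classifies.  Under no flow the same angular band is
scored against the nominal flow axis, orientation-only by default (the
standardization "events" of the no-flow window); the full rule is available
as an option.

Events are summarized per trial × epoch (count, mean duration, total
distance).  Events spanning an epoch boundary are split at the boundary and
counted once in each epoch they touch, with distance apportioned by time;
the split pieces conserve the original duration and distance.  Latency is
the delay from flow onset to the start of the first event that overlaps a
flow epoch; non-responders report missing latency, not a censored 20 s.
The responder curve is the cumulative fraction of fish whose first in-flow
event has begun by each bin.

## Circular statistics

The unit of group analysis is one circular mean heading per fish (never
pooled frames — pooling would pseudoreplicate).  `mean_resultant` returns
the mean direction θ and mean resultant length ρ (angular variance 1 − ρ).
The V-test computes V = n·ρ·cos(θ − μ) against μ = 0° (upstream) and refers
u = V·√(2/n) to the standard normal upper tail, with a Monte-Carlo null for
n < 5.  The Watson–Wheeler k-sample test maps pooled circular ranks
(mid-ranks for ties) to uniform scores γᵢ = 2π·rankᵢ/N and computes
W = 2·Σ_g (C_g² + S_g²)/n_g with 2(k−1) degrees of freedom.

Numerical choice: the chi-square p-value uses the rescaled statistic
W·(N−1)/N.  Under label permutation the exact mean of W is df·N/(N−1), so
the rescaling matches the chi-square mean; without it, p-values at
n = (12, 12) miss a full permutation reference by up to ≈0.03, with it by
under 0.02.  A vectorized permutation mode is available and is the default
when any group has n < 10.

## Spectral profile

Each per-bin series (10 Hz sampling) is decomposed by classical additive
moving-average seasonal decomposition (statsmodels) with a 1-s period
(10 bins): trend = centered moving average, periodicity = re-centered
per-phase means of the detrended series, noise = remainder.  The three
components reconstruct the observation exactly on interior bins, and the
periodic component has zero mean over every full period.

Power spectra are computed as one-sided boxcar periodograms of the
**noise-removed** (trend + periodic), mean-centered series, normalized so
that Σ density · Δf equals the series variance (Parseval).  Spectra are
deliberately not taken on the strictly 1-s-periodic component alone: that
component can only carry energy at exact multiples of 1 Hz, whereas the
behavioral modulations of interest live below 1 Hz (a 1-s moving average
attenuates a 0.21-Hz line by only ≈7 %, so sub-hertz structure survives in
the denoised series).  Dominant peaks are strict local maxima ranked by
density; the net shift between two groups is the difference of their summed
top-3 peak frequencies (negative = downshift) and densities.

Group-level series are across-fish means per bin: within-fish mean-centered
("relative") movement, velocity and acceleration; the across-fish circular
mean heading; and the across-fish resultant length per bin.

Cross-correlograms use per-lag Pearson correlation,
r(ℓ) = corr(linear[t], angular[t+ℓ]): positive lag means the angular change
occurs **after** the linear change, negative before.  Swapping the two
series exactly negates the lags.  The significance bound is the white-noise
±z₀.₉₇₅/√N band; correlograms are computed per fish on mean-centered
continuous series and averaged within groups.

## Synthetic swimmer

The generator emulates what the analysis assumes about a larva in the
flume, not hydrodynamics:

* **Burst-and-glide** — bursts arrive as a Poisson process (default rates
  0.8–2.6 s⁻¹ by preset); active speed after a burst decays exponentially
  (peak 25–28 mm s⁻¹, decay 5 s⁻¹). Below 2 % of peak speed the fish is
  gliding.
* **Flow response** — at flow onset the fish freezes (no new bursts, no
  residual glide) until a latency drawn from N(latency_mean, latency_sd)
  expires, then responds with an immediate burst and turn.
* **Heading control** — while responsive, each burst re-draws the heading
  from von Mises(0°, κ); otherwise the heading random-walks with a
  configurable step.  Heading changes are applied a planted number of bins
  after (positive) or before (negative) the accompanying burst, which makes
  the cross-correlogram's sign convention directly testable.
* **Drift** — while gliding during flow, the fish is advected downstream at
  the flow speed; while bursting it swims along its heading.  Bursts at
  rate ≈ 1 s⁻¹ roughly balance advection, so simulated fish hold station
  imperfectly, as real larvae do.
* **Grid quantization** — burst onsets and heading changes are snapped to
  the 100-ms analysis grid so planted lags and latencies are expressed
  exactly in bins; without snapping, a burst starting mid-bin puts most of
  its displacement into the following bin and every planted lag recovers
  one bin short.
* **Walls** — hitting a wall triggers a heading re-draw in the fish's
  current behavioral state; motion that keeps pushing into a wall slides
  along it.  A sticky rear wall that pins drifting fish against the
  downstream mesh is available as an option.
* **Pose model** — seven keypoints placed rigidly on the body axis
  (eye midpoint 0.8 mm ahead of the swim bladder, tail points 0.7 mm
  apart), tail points oscillating at 20 Hz during bursts, optional
  isotropic Gaussian keypoint noise and random dropouts.  Identical seeds
  give bit-identical tracks.

The presets (`control_like`, `cuso4_like`, `neomycin_like`) are declared
fixtures that reproduce the qualitative group signatures — controls with
tight upstream heading (κ = 10) and few long events; copper-like fish with
the longest response latency (2.0 s) and a large slow movement modulation;
neomycin-like fish with erratic headings (κ = 3.5), the highest event
counts, and a planted 0.21-Hz modulation of burst vigor.  They are not
estimates of real fish.

### What the generator does not emulate

No hydrodynamics (no vorticity cue, no boundary layer beyond an optional
lateral multiplier), no Z-axis movement, no body bending beyond a scripted
tail oscillation, no tracker-specific error structure (pose noise is i.i.d.
Gaussian; real pose estimators produce correlated, occlusion-driven
errors), and no inter-individual parameter variability within a preset.
Passing recovery tests therefore demonstrates that the pipeline measures
what the generative model plants — not that real fish satisfy the model.

## Estimator conventions used in validation

* Recovered latency uses the bin-center convention (event starts are known
  to bin resolution).  Recovery is median-unbiased; the mean carries a
  small positive tail because a fish whose response turn misses the ±45°
  band only classifies at a later burst.
* Recovered heading concentration pools per-bin headings over flow bins
  after the slowest plausible response (t ≥ 13 s) and excludes positions
  within 3 mm of the side/front walls and 6 mm of the rear wall, where
  wall interactions distort heading; it is compared to the von Mises
  Bessel ratio I₁(κ)/I₀(κ).
* Lag recovery cross-correlates relative per-bin movement against the
  absolute per-bin heading change.

## Problem sizes

Validation runs use 30-s trials at 60 fps (300 bins): 20 cohorts × 50 fish
for parameter recovery, 50 fish per preset for the group orderings, and a
40-fish neomycin-like cohort for spectral recovery, where the frequency
grid step is 1/29 Hz ≈ 0.034 Hz.  These sizes put Monte-Carlo error well
below the effects being checked while keeping the whole validation suite
in the tens of seconds.

## Known limitations

* The event rule is a deterministic re-expression of the original assay's
  operational definition; a learned classifier trained on annotated video
  could score ambiguous bins differently.
* Bin-level classification can admit a bin whose compliant fraction is
  below 100 ms when the remainder of the bin is benign enough to keep the
  bin-mean heading in band; conversely a compliant 90-ms bout straddling a
  bin boundary is (correctly) rejected.
* ROI geometry (5-mm front/back/side bands) is a declared convention; the
  original arena figure does not dimension its region boundaries.
* The chi-square Watson–Wheeler p-value remains an approximation; for
  small or badly unbalanced groups use the permutation mode.
* `external_dominant_frequency` expects a locally provided export of the
  original study's deposited pose tracks (a `manifest.csv` naming
  per-trial tables under `data/osf_export/`); the deposit is not
  redistributed with this package.
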