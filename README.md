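# rheokit

Rheotaxis profiling of larval zebrafish from markerless pose tracks.

Rheotaxis — orienting and swimming into an oncoming water flow — is a core
behavior of fishes, and in larval zebrafish it is shaped by the lateral
line, a mechanosensory system whose hair cells are routinely ablated with
ototoxic compounds (CuSO₄, neomycin) to study hair-cell damage.  `rheokit`
is for researchers who film single larvae in a small flume, track body
keypoints with a markerless pose estimator, and want a reproducible path
from those per-frame tracks to quantitative behavioral profiles:

* **rheotaxis event calls** — positive rheotaxis is scored when a fish
  holds a body angle within 0° ± 45° of upstream, beats its tail, and
  translates into the flow for at least 100 ms; tail movement and forward
  translation distinguish active swimming from passive downstream drift at
  a compliant angle;
* **circular statistics** — per-fish mean body angles, the group mean
  direction θ and mean resultant length ρ (angular variance 1 − ρ), the
  V-test of uniformity against a specified direction (μ = 0°, upstream),
  V = n·ρ·cos(θ − μ), and the Watson–Wheeler k-sample test on circular
  ranks, W = 2·Σ_g (C_g² + S_g²)/n_g with 2(k − 1) df;
* **spatial use** — arena occupancy histograms and five-region (front,
  back, left, right, middle) fractions, optionally restricted to the
  rheotaxis band;
* **spectral profiles** — classical additive decomposition of each
  kinematic series into trend + 1-s periodicity + noise, one-sided
  periodograms of the denoised series (Parseval-normalized), top-3
  dominant peaks, and between-group net shifts in summed peak frequency
  and density;
* **cross-correlograms** — r(ℓ) = corr(linear[t], angular[t + ℓ]) between
  relative linear and angular kinematics, where a positive lag means the
  angular change follows the linear change;
* **a synthetic burst-and-glide swimmer** — a seeded generator with von
  Mises heading control, stochastic response latency, passive downstream
  drift, planted periodic modulation and planted burst–turn lag, used to
  validate every stage by parameter recovery.

Trials follow the standard stimulus schedule (10 s no flow, 10 s initial
flow, 10 s final flow at 9.74 mm s⁻¹), and all series are quantized into
100-ms bins, the lowest common bin of 200 and 60 fps recordings.

## Worked example

Simulate a control-like larva, classify its rheotaxis events, and
summarize its heading:

```python
from rheokit import (preset_profiles, simulate_trial, bin_track,
                     linear_series, classify_events, summarize_events,
                     mean_resultant, v_test)

profile = preset_profiles()["control_like"]
trial = simulate_trial(profile, fps=60, seed=7, trial_id="demo",
                       treatment="control")
series = linear_series(bin_track(trial.track))
events = classify_events(series)
summary = summarize_events(events)
print(f"latency to first rheotaxis event: {summary.latency:.2f} s")
print(summary.per_epoch.round(2).to_string(index=False))

h = series.df.query("valid and bin_start >= 10").heading.dropna()
summ, vt = mean_resultant(h), v_test(h, mu=0.0)
print(f"heading during flow: theta = {summ.theta:.1f} deg, rho = {summ.rho:.3f}")
print(f"V-test toward upstream: V = {vt.statistic:.1f}, p = {vt.p:.2e}")
```

prints

```
latency to first rheotaxis event: 0.30 s
       epoch  n_events  mean_duration  total_distance
     no_flow         0            NaN            0.00
initial_flow         6           1.07           50.47
  final_flow         5           0.96           37.40
heading during flow: theta = 2.3 deg, rho = 0.946
V-test toward upstream: V = 189.1, p = 4.39e-80
```

The fish responded 0.30 s after flow onset, performed eleven rheotaxis
bouts of ≈1 s covering ≈88 mm, and held a tight upstream heading
(ρ = 0.946, mean angle 2.3° right of the flow axis); the V-test rejects a
uniform angle distribution in favor of concentration toward upstream.

## Command line

```sh
rheokit simulate -c config.yaml   # write a synthetic cohort + manifest
rheokit run -c config.yaml        # full analysis -> tidy CSV bundle
rheokit report out_dir            # digest of a completed run
```

`run` produces, per group and epoch: circular summaries and tests, event
summaries, responder curves, occupancy/ROI tables, decompositions, spectra
with dominant peaks and net shifts, and cross-correlograms — one tidy CSV
each, every row stamped with the config hash, plus a machine-readable
`run_log.json`.  A run is a pure function of (inputs, config, seed).

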