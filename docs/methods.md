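# Methods

This note documents the models, defaults and design choices behind
`tuftpipe`: what the synthetic data emulate, how the factorization and the
classifiers work, and what the recovery studies do and do not establish.

## Behavioral session model

A session is a sequence of trials separated by inter-trial intervals (ITIs).
Defaults describe a trained animal:

| parameter | default | meaning |
|---|---|---|
| `n_trials` | 150 | trials per session (protocol range 100–200) |
| `go_fraction` | 0.7 | probability a trial is Go (pole present) |
| `lever_hold_s` | 1.0 s | lever hold required to start a trial |
| `response_window_s` | 3.0 s | window for the lever-lift response |
| `reward_delays_ms` | {0, 250, 500} | per-Hit reward delay, drawn uniformly |
| `random_reward_prob` | 0.007 /s | per-ITI-second chance of an unearned reward |
| `timeout_s` | 9 s | false-alarm timeout |
| `iti_range_s` | (6, 12) s | uniform ITI duration |
| `hit_rate`, `false_alarm_rate` | 0.9, 0.15 | outcome probabilities |
| `frame_rate_hz` | 4 | imaging frame rate |

Timing structure per trial: pole onset at `press + 1 s`; first whisker
contact at `pole onset + N(0.37 s, 0.10 s)` (Go only); lever lift at
`pole onset + N(1.3 s, 0.2 s)` clipped into the response window; reward at
`lift + delay`. The contact transient is planted 580 ms after first contact,
so the short-latency population peak sits ≈950 ms after trial start — the
two printed latencies are inputs to the generator, not measured outcomes.
Reward delays are assigned uniformly and independently per Hit (the protocol
says only "randomly each trial").

`random_reward_prob` is calibrated so ~4.5% of ITIs contain a random reward,
inside the 2–5% protocol band and high enough that a 150-trial session
almost always contains the ≥3 random rewards the event-proportion test
needs (≈6–7 per session in expectation).

Licking: a consummatory bout starts 300–400 ms after each rewarded response
and ramps to ~5.5 licks/s by ~1 s; spontaneous lick and whisking bouts are
placed in ITIs. The whisker angle is an Ornstein-Uhlenbeck baseline at
100 Hz with planted whisking bouts (amplitude step plus 8-Hz oscillation,
0.5–2 s); 100 Hz comfortably resolves the 150-ms analysis windows.

The `lever_only` task variant renders the identical dendrite population with
all reward-driven amplitudes set to zero — the task-specificity control is a
generative option, not a claim.

## Dendrite classes and the imaging forward model

Each dendrite gets one label: `contact_only` (fires after contacts),
`reward_tracking` (contacts plus reward-locked transients at
`reward + 150 ms`, hence a unit latency-vs-delay slope), `random_reward_pretrial`
(responds to random rewards, baseline ITI rate 0.02 Hz, suppressed during
trials), `nonselective_timelocked` (fires at a fixed phase relative to pole
onset, drawn from [−3, 4] s so the population tiles pre-trial and trial
epochs), or `silent`. Default composition: 50 / 12 / 9 / 29% (the 9%
random-reward fraction is the planted population-level truth the
classification study tries to recover).

`trial_suppression` is the fraction of the ITI event rate removed during
trials (0 = none, 1 = silent within trials); default 0.8.

Heterogeneity: each dendrite draws a contact-latency offset (SD 0.1 s), a
reward-lag offset (SD 0.05 s) and a contact-reliability scale (U(0.7, 1.2)
on a base reliability of 0.75). Besides being realistic — dendrites differ
in contact tuning — this trial-by-trial and dendrite-by-dendrite variability
is what makes co-active dendrites statistically separable by the
factorization. Reward responses are uniformly reliable (0.9). Per-event
amplitudes jitter by 20%.

Calcium kinetics: a causal double exponential with 50-ms rise and 600-ms
decay (GCaMP6f-like; the indicator's kinetics are not part of the protocol,
so they are configurable). Sampling integrates the continuous kernel over
each frame bin; event impulses are split linearly between neighboring
frames, so sub-frame timing survives the 4-fps grid.

Imaging: footprints are blurred Bezier curves with optional branches,
40–70 px long (≥100 µm equivalents at 1 µm/px, capped at 0.65× the frame on
small frames); movie = footprints × traces + smooth background
(spatial pattern around 100 counts × slow 3% sinusoidal drift) +
Gaussian read noise (SD 2) + Poisson shot noise approximated as
intensity-scaled Gaussian. A unit-amplitude transient is ~100% ΔF/F at the
footprint peak, typical of tuft-wide dendritic calcium spikes; at several-
fold lower contrast the factorization cannot separate crossing co-active
dendrites, so the SNR is part of the stated study conditions.

What the generator does **not** emulate: sensory-driven trial-to-trial
amplitude modulation, neuropil contamination, slow photobleaching, motion
beyond integer rigid shifts, NMDA-type branch-local events, or correlated
(shared-input) noise across dendrites. Passing recovery tests therefore
shows the pipeline is correct under this forward model, not that it is
robust to every property of real movies.

## Sparse NMF segmentation

Model: `Y ≈ A C + b f` (pixels × frames), all factors nonnegative, objective
`½‖Y − AC − bf‖²_F + Σₖ λₖ‖A_k‖₁`. Choices:

- **Initialization**: greedy. Pick the pixel whose spatially smoothed,
  mean-subtracted trace explains the most residual variance; build the
  footprint seed from the correlation patch around it (threshold 0.3),
  restricted to the connected component containing the seed pixel so a
  co-active but spatially separate dendrite is not swept in; compute seed
  weights from the *unsmoothed* movie (the smoothed patch only shapes the
  mask); subtract the full rank-1 explanation and repeat K times. The seed
  RNG only breaks exact variance ties. Background initializes from the
  pixelwise temporal median and the normalized frame mean.
- **Updates**: HALS (exact coordinate minimization per column with clipping
  at zero), chosen over multiplicative updates for convergence speed. The
  recorded objective is non-increasing at every iteration by construction;
  this is asserted in tests.
- **Penalty scale**: `λₖ = sparsity_weight · σ̂ · ‖C⁰_k‖` with `σ̂` the
  robust per-pixel noise SD (median absolute temporal difference) and
  `C⁰_k` the initial trace — i.e. a pixel survives only if its weight
  exceeds roughly `sparsity_weight` noise standard errors. The penalty
  vector is frozen at initialization so the objective is a fixed function
  (exact monotonicity). Default `sparsity_weight = 1.0`, chosen by a grid
  (0.25–2) on 128-px synthetic movies with footprint recovery as the
  criterion.
- **Spatial support**: each footprint may only grow within a 6-px dilation
  of its initial support (CNMF-style constraint). This removes the
  cross-loading that co-activated distant dendrites otherwise produce.
- **Background rank 1**; K may over-specify truth by ~1.5× — components
  with <20 positive pixels are pruned and pairs with temporal correlation
  >0.85 *and* >10% shared support are merged (footprints summed, traces
  variance-weighted); the overlap requirement avoids merging distant but
  synchronized dendrites. Footprints are max-normalized afterwards (traces
  rescaled inversely), fixing the scale indeterminacy without changing
  `A C`.
- Non-convergence at `max_iter` (default 60, `rel_tol` 1e-4) sets a flag on
  the result instead of raising.

Ground-truth matching is a Hungarian assignment maximizing summed spatial
cosine similarity.

## Trace analysis

- **ΔF/F**: `F₀` is a rolling 10th percentile over 30 s — robust to the
  task's dense transients; the method tag is stored on the trace. `F₀ ≤ 0`
  is an error (offset correction required), and ΔF/F is invariant to
  multiplicative gain.
- **Event detection**: threshold at `median + 3·MAD` with the
  normal-consistent (1.4826-scaled) MAD, minimum duration 0.5 s (two frames
  at 4 fps), and suprathreshold runs separated by <0.5 s merged. The last
  two rules exist because at 4 fps a single-frame criterion admits isolated
  noise frames, and noise dips in a decay tail would otherwise re-trigger
  the detector; with them, a 0.2-Hz planted train at default SNR is
  detected with ≥0.9 recall and precision.
- **Peaks**: within half-open search windows — first peak [0, 2) s after
  trial start, second peak [0.2, 2) s after lever lift, matching the 2-s
  post-event convention. The window maximum must be an interior local
  maximum (monotone traces yield no peak) and must exceed the pre-trigger
  mean by 2 pre-trigger SDs — this prominence rule is the repo's explicit
  stand-in for the unstated "discernible second peak" criterion. Parabolic
  3-point interpolation refines the latency; it is on by default because
  the 250-ms frame period equals the smallest delay step, and without it
  slope recovery is quantized.
- **Whisking bouts**: per-window angle change = max − min over sliding
  150-ms windows; onsets where the change exceeds mean + 2 SD of the
  per-window change distribution (computed per session; optionally over an
  ITI mask), 1-s lockout enforced on every output.
- **Licking bouts**: gaps >1 s split bouts; bouts within 3 s of any reward
  are flagged non-isolated.
- **Registration**: optional integer rigid registration by phase
  cross-correlation against a running mean template, shifts clipped and
  applied circularly.
- Frame-time convention: frame `i` covers `[i/rate, (i+1)/rate)`; events map
  to frames by floor.

## Classification statistics

α = 0.05 throughout, no multiple-testing correction (none is applied in the
source analysis); all control-window sampling is seeded, so flags are
reproducible.

- **Two-proportion test**: pooled z statistic; one-sided tests p₁ > p₂. A
  pooled proportion of exactly 0 or 1 makes z undefined: the result is
  flagged degenerate with p = 1 (no evidence).
- **Reward tracking**: per-delay lever-lift-aligned triggered averages
  (≥3 trials per delay, else the condition is dropped); second-peak
  latency regressed on delay in seconds; flag = slope > 0 and p < α.
  With three delay conditions the regression has one residual degree of
  freedom, so the flag demands a near-perfect linear relation — the planted
  recovery (~75%) and the null calibration (type-I ≈ 0) both reflect that
  strictness.
- **Random-reward responsiveness**: p₁ = fraction of random rewards with an
  event onset within 2 s; p₂ = same over an equal number of control windows
  drawn uniformly (seeded) from ITI time ≥3 s from any reward, lick bout or
  trial boundary; one-sided test. Sessions with <3 random rewards cannot be
  tested (error), and a shortage of eligible control time is reported, not
  silently tolerated.
- **Activity preference**: event rate in [press − 3 s, press) versus
  [press, reward-or-trial-end); ties label "trial".
- **Predicted class**: reward-tracking flag → `reward_tracking`; else
  random-reward flag → `random_reward_pretrial`; else contact-responsive
  (event proportions after contacts vs pre-press controls) →
  `contact_only`; else `nonselective_timelocked`. Phase-locked dendrites
  whose preferred phase falls inside the contact window are genuinely
  indistinguishable from contact responders at the session level and bound
  the attainable nonselective recall (~0.7–0.8).

## Recovery studies (problem sizes)

The studies in `tuftpipe.studies` use these sizes, chosen to exercise the
stated conditions while completing in minutes on one core: latency — 10
sessions × 150 trials, 48-px movies (the frame average at 4 fps is the
analyzed object, so frame size is immaterial beyond SNR), default-SNR
population with a 35% reward-tracking contingent so the session-level second
peak is expressed; segmentation — one 256×256 movie, ~1,350 frames,
20 dendrites, K = 30; classification — 5 sessions × 44 dendrites
(trace-level rendering; rasterizing movies adds nothing to a classifier
test); null calibration — 200 contact-only replicates across 10 sessions.

## Known limitations

- The factorization assumes temporally decorrelated sources; perfectly
  synchronized overlapping dendrites are unidentifiable in principle, and
  two branches of one neuron are returned as one (or two) components
  without warning.
- The reward-tracking regression over three delay-condition means is
  conservative; per-trial latency regression would have more power but a
  different (unmodeled) error structure.
- Rigid registration is integer-valued and circular; it stands in for a
  full motion-correction stage, not a replacement on real data.
- The event-log schema adds a `trial_end` event kind beyond the core set so
  round-trips are lossless.
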