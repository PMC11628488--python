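# Methods

This note documents the models, procedures and numerical choices behind
`asmebci`: a pipeline for four-class auditory BCIs built on stream-segregated
oddball sequences (ASME paradigms), from stimulus generation through
synthetic EEG, ocular artifact removal, ERP statistics and shrinkage-LDA
decoding.

## Stimulus paradigms

A trial interleaves `N` oddball tone streams on a common onset grid with
overall SOA `t`, so each stream's within-stream SOA is `SOA_stm = N·t`.
The bundled configurations:

| paradigm      | N | SOA (s) | stimuli/trial | per-stream ratio | SOA_stm |
|---------------|---|---------|---------------|------------------|---------|
| `asme4stream` | 4 | 0.15    | 600           | S:D = 9:1        | 0.6 s   |
| `asme2stream` | 2 | 0.30    | 300           | S:D_L:D_H = 8:1:1| 0.6 s   |
| `oddball`     | 1 | 1.00    | 120 (default) | S:D = 5:1        | 1.0 s   |

Both ASME variants expose four selectable deviant classes (D1–D4): one
deviant per stream in the four-stream design, a low- and a high-pitched
deviant per stream in the two-stream design.  Attending one deviant makes
the within-stream target:nontarget ratio 1:9 in both designs.

Design choices the configuration alone does not fix:

* **Interleaving** is the fixed cyclic order 1, 2, …, N — the only order
  that keeps the within-stream SOA constant at `N·t`.
* **Deviant placement** is uniform over per-stream slot subsets subject to
  two constraints: no deviant in a stream's first two slots, and no two
  deviants of the same stream in adjacent within-stream slots (standard
  oddball practice).  Sampling uses the gap bijection, so placements are
  exactly uniform over the admissible subsets, and role counts follow the
  ratio exactly for every seed.
* **Tones** default to 0.1 s sine bursts with 5 ms raised-cosine ramps;
  tone frequencies are the published two-semitone standard/deviant pairs per
  stream.
* **Seeding**: every trial derives its seed from a master seed via
  `numpy.random.SeedSequence` over `(master, run, trial)`; all seeds stay
  below 2³¹.

## Synthetic sessions

`synthetic.simulate_session` produces 64 EEG + 2 EOG channels (the extended
10-20 montage named in `EEG_CHANNELS`) at 1000 Hz by default, in µV.  Per
event, each configured ERP component adds `kernel × topography`:

* **Kernel**: an asymmetric raised-cosine bump — zero before
  `onset_latency`, extremum `polarity · peak_amplitude` at `peak_latency`,
  zero again at `onset + width`.
* **Band-limiting**: the presets render kernels band-limited to 1–40 Hz (two
  zero-phase passes, peak renormalized).  Published ERP amplitudes are
  measured after identical filtering; a raw monophasic bump would lose
  roughly 30 % of its peak to the 1 Hz high-pass chain, so amplitudes are
  defined in the analysis band.  The residual attenuation of one further
  analysis pass is about 6 % and is the main known bias of amplitude
  recovery.
* **Topography**: Gaussian falloff over 3-D scalp positions from the
  standard 10-05 montage shipped with MNE, unit gain at the component's
  center channel.

Preset components (per paradigm, `snr="default"`):

| component | polarity | onset (s) | peak (s) | amplitude (µV)      | center |
|-----------|----------|-----------|----------|---------------------|--------|
| exogenous | −        | 0.05      | 0.10     | 1.0 (all stimuli)   | Cz     |
| N200      | −        | 0.15      | 0.22     | 2.0 / 2.5 (4s/2s)   | FCz    |
| P300      | +        | 0.30/0.24 | 0.40/0.36| 3.2 / 3.5 (4s/2s)   | CPz    |
| N700      | −        | 0.55      | 0.70     | 1.5 (4-stream only) | Fz     |

The two-stream preset carries the earlier P300 onset and slightly larger
P300/N200; the N700 appears only in the four-stream preset.  These values
reproduce the qualitative ordering the paradigm comparison is about and are
simulation parameters, not empirical claims.

**Noise**: spatially correlated 1/f (α = 1) background at 2.5 µV rms per
channel (random smooth Gaussian-gain mixing of 20 independent sources);
blinks (12/min, 0.3 s half-cosine, 200 µV in VEOG) couple front-to-back into
EEG (Fp\* 0.5, AF\* 0.3, F\* 0.15, else 0.01); saccades (6/min, 0.4 s
smoothed box, ±50 µV in HEOG) couple into lateral frontal channels with
hemisphere-dependent sign.  `snr="high"` doubles component amplitudes and
reduces the background to 1 µV; `snr="zero"` injects no components at all.
Real recordings differ in ways the generator does not model — volume
conduction, non-stationary rhythms, muscle and line noise, single-trial
latency jitter — so passing recovery tests demonstrates correctness of the
estimators, not expected field performance.

## Ocular artifact removal

Per run, the EEG is high-passed (zero-phase 2nd-order Butterworth, 1 Hz);
runs are concatenated; PCA reduces 64 channels to 15 components; FastICA
(logcosh, symmetric decorrelation, tol 1e-4, ≤1000 iterations, seeded)
unmixes them.  Each EOG channel is band-passed 1–10 Hz (zero-phase, for
alignment with the zero-phase EEG chain) and the source with the highest
|Pearson r| is zeroed — absolute value because a source's sign is arbitrary
under ICA.  Removal is the linear projection
`EEG ← EEG − (scores · Wᵀ_z · A ᵀ_z) · PCA_components`, which is exactly
idempotent and leaves the non-zeroed subspace untouched.  Fitting and
application are separate objects, so decoding folds fit the remover on
training runs only.

Numerical notes:

* Spatial filters are time-invariant, so PCA/ICA and the IC–EOG
  correlations are estimated on an evenly strided subset of at most 200 000
  samples when the input is longer (`max_fit_samples`); application always
  uses every sample.
* FastICA on predominantly Gaussian background may hit the iteration cap;
  the decomposition is still a valid spatial basis, so the default records
  the event (`converged_`, `n_iter_`) and continues.  Set
  `on_nonconvergence="raise"` to get a `ConvergenceError` carrying the
  iteration count.
* The "2nd-order" filter specification names the design order before
  zero-phase application; the realized magnitude roll-off is that of an
  effective 4th-order filter.

### Zero-phase filtering

All zero-phase Butterworth filtering is realized in the frequency domain as
multiplication by the squared magnitude response |H(f)|² of the 2nd-order
design, on signals zero-padded by 2 s per side.  This has exactly the
magnitude response of forward–backward IIR filtering, but none of its edge
transients, and is exactly symmetric under time reversal — a property the
pipeline's invariants rely on and that `filtfilt`-style recursion only
approximates away from the edges.

## ERP statistics

Epochs span −0.1 to 1.2 s around onset, half-open at the right edge (1300
samples at 1000 Hz; 325 at 250 Hz).  The chain is band-pass (1–40 Hz for ERP
analysis, 0.1–8 Hz for classification) → slice → zero-phase anti-aliased
decimation to 250 Hz → baseline correction (mean of [−0.1, 0) per
epoch/channel; switchable off).  Events whose window leaves the recording
are dropped and counted, never silently.

* **Signed-r²**: per channel/time, the point-biserial correlation `r`
  between amplitude and the binary target label, reported as `sign(r)·r²`;
  zero-variance points map to 0.
* **Peak amplitude** (1200 replicates): each draws 80 % of the target
  epochs without replacement, averages them, and takes the maximum over the
  configured channels × 0.2–0.5 s (the spatiotemporal peak); the estimate is
  the replicate mean.
* **Onset latency** (250 replicates): each draws 80 % of target and of
  standard epochs, averages the configured channels into one virtual channel
  per epoch, computes a one-sided Welch's t (target > standard) per time
  point, and records the first significant (p < 0.05) time inside
  0.2–0.5 s; replicates with none are discarded and counted in `n_failed`.
  The estimate is the mean of retained times; if every replicate fails the
  result is an undefined (NaN) latency carrying `n_failed`, not an
  exception.  Zero-variance time points take the t → ∞ limit (p = 0 when
  the target mean is larger, else 1).

The default channel tuple follows the printed instrument description
(`Fz, FCz, Cz, FPz, Pz`); the recorded 64-channel montage has no Fpz, so the
pipeline presets use `SIMULATED_P300_CHANNELS` with CPz in its place — the
anomaly is surfaced as two named constants rather than silently corrected.

## Decoding

Features are mean amplitudes in ten non-overlapping 0.1 s intervals over
0–1.0 s post-onset × 64 channels = 640 dimensions (channel-major).  The
binary classifier is LDA with the pooled within-class covariance shrunk as
`(1−γ)Σ̂ + γ(trΣ̂/d)I`, γ from the analytic Ledoit–Wolf estimator on the
class-centered data; `w = Σ_γ⁻¹(μ₊−μ₋)` and the bias puts `f = 0` at the
midpoint of the class means.  Binary performance is AUC (midrank
Mann–Whitney) under 4-fold chronological CV (contiguous blocks; folds
missing a class are skipped and reported).

The four-class simulation replays a six-run session through 3-fold
chronological CV (runs 1–2 / 3–4 / 5–6 train; the other four runs test; each
run is tested twice).  Per fold the EOG remover, features and LDA are fit on
the training runs only.  Per test trial, every deviant epoch is scored with
`f(x)`; the deviant class with the largest mean output is the selection
(ties — measure-zero with continuous scores — break toward the lowest class
index and are logged; a class with no epochs scores −∞ and is never
selected).  Both the 48-prediction fold-level accuracy (the headline) and
the 24-unique-trial mean are reported.

* **Significance**: the binomial threshold is the smallest `k/n` with
  `P(X > k) < α` at chance `1/N`; accuracies strictly above it are
  significant.  For n = 24, N = 4, α = 0.05 this gives 10/24 ≈ 0.42.
  The threshold decreases with more trials and with more classes (lower
  chance level).
* **ITR**: `R = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))` bits/trial with
  the 0·log 0 = 0 convention, `B = V·R` bits/min with the trial rate `V`
  passed explicitly (the default uses 60 s ÷ trial duration and ignores
  inter-trial overhead).

## Workload

NASA-TLX weighted workload: six 0–100 subscale ratings and fifteen pairwise
comparisons; `WWL = Σ tallyᵢ·scoreᵢ / 15`.  Scores are accepted on the
continuous 0–100 scale.

## Problem sizes

Full-scale sessions are 6 runs × 4 trials at 1000 Hz per paradigm.  The test
suite and the acceptance script run the same code on scaled sessions —
250 Hz and, for the chance-level sweeps, 60–120 stimuli per trial — chosen
so each sweep completes in minutes on one core; chance behavior and the
structural properties do not depend on trial length, and the
parameter-recovery sweeps keep the full 90 s trials (90 target epochs from
6 runs).  All randomness in tests and scripts flows from fixed or derived
seeds, and the simulator is bit-reproducible given a seed.

## Known limitations

* Amplitude recovery carries a deterministic ≈ −6 % bias from the final
  analysis-band pass over the band-limited kernels, plus a small positive
  max-over-noise bias; both are inside the ±0.5 µV recovery tolerance.
* The onset estimator's first-significant-time statistic is detection-power
  limited: recovered onsets sit later than the injected ones (significance
  needs the response to clear the noise), so it is validated on ordering
  and window containment, not absolute value.
* FastICA separates the blink/saccade sources well because they are
  strongly super-Gaussian; on sessions without artifacts the marked
  components are arbitrary (the procedure is unconditional by design).
* No volume conduction or realistic head model; topographies are scalp
  Gaussians.
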