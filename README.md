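# asmebci

Analysis toolkit for four-class auditory BCIs built on **ASME** paradigms —
Auditory Stream segregation Multiclass ERP.  Rapidly interleaved oddball
tone streams are perceived as separate auditory streams; attending the rare
deviant of one stream elicits ERPs (N200, P300, late N700), and the attended
deviant class is decoded from single-trial EEG.  The package is aimed at
auditory-BCI and ERP researchers who want the full offline pipeline —
stimulus sequences, ocular artifact removal, ERP statistics, decoding,
workload scoring — as reusable, tested building blocks, exercisable end to
end on a bundled synthetic EEG generator with known ground truth.

## What it implements

* **Paradigms** (`asmebci.paradigm`) — generators for the four-stream
  (SOA 0.15 s, 600 stimuli, 9:1) and two-stream (SOA 0.3 s, 300 stimuli,
  8:1:1) interleaved designs plus a plain oddball; both ASME designs keep
  the within-stream SOA at `N·t = 0.6 s` and expose four deviant classes.
  Target/nontarget labeling for an attended deviant, TSV serialization and
  WAV rendering included.
* **Synthetic sessions** (`asmebci.synthetic`) — 64 EEG + 2 EOG channels at
  1000 Hz with injected ERP components (kernel × scalp topography),
  spatially correlated 1/f noise, blinks and saccades; bit-reproducible and
  carrying its ground truth.
* **EOG removal** (`asmebci.preprocessing`) — zero-phase 1 Hz high-pass,
  run concatenation, PCA to 15 components, FastICA, and zeroing of the
  ICs most correlated with the (1–10 Hz band-passed) VEOG/HEOG.
  `EOGRemover` is a scikit-learn style transformer: fit on training runs,
  apply to held-out runs.
* **ERP statistics** (`asmebci.erp`) — epoching (−0.1 to 1.2 s, downsampled
  to 250 Hz), grand averages, signed-r² discriminability maps, and seeded
  bootstrap estimators of P300 peak amplitude (1200 replicates, 80 %
  resampling, spatiotemporal max in 0.2–0.5 s) and onset latency (250
  replicates, first one-sided Welch-significant time in 0.2–0.5 s).
* **Decoding** (`asmebci.decoding`) — 10-interval × 64-channel (640-dim)
  mean-amplitude features; `ShrinkageLDA` (Ledoit–Wolf shrinkage of the
  pooled covariance, `f(x) = wᵀx + b` with `f = 0` at the class-mean
  midpoint, scikit-learn estimator API); 4-fold chronological CV AUC; the
  3-fold (2 train / 4 test runs) four-class BCI simulation; the exact
  binomial significance threshold (`P_th = 0.42` at n = 24, N = 4,
  α = 0.05); and the ITR
  `R = log₂N + P log₂P + (1−P) log₂((1−P)/(N−1))`, `B = V·R`.
* **Workload** (`asmebci.workload`) — NASA-TLX weighted workload
  `WWL = Σ tallyᵢ·scoreᵢ / 15`.
* **CLI** (`asme`) — `paradigm`, `simulate`, `preprocess`, `erp`, `decode`,
  `tlx`, `replicate`, all seeded and idempotent.

See `docs/methods.md` for the model details, parameter tables and numerical
choices.

## Worked example

Simulate a two-stream session (six runs, one trial each, moderate SNR),
clean it, and estimate the P300:

```python
import numpy as np
from asmebci import simulate_session
from asmebci.preprocessing import (
    highpass_and_concatenate, fit_eog_remover, apply_eog_remover,
)
from asmebci.erp import make_epochs, estimate_peak_amplitude, estimate_onset_latency
from asmebci.decoding import significance_threshold, information_transfer_rate

runs, plans, cfg = simulate_session("asme2stream", n_runs=6, trials_per_run=1,
                                    snr="default", fs=250.0, seed=3)
cont = highpass_and_concatenate(runs)
remover = fit_eog_remover(cont, seed=0)
cleaned = apply_eog_remover(remover, cont)
print(f"zeroed ICs: {remover.zeroed_ics_} "
      f"(|r| = {np.abs(remover.correlations_).max(axis=1).round(3)})")

eps = make_epochs(cleaned, band=(1.0, 40.0), fs_out=250.0)
targets = eps.targets()
standards = eps.select(eps.labels["tag"].to_numpy() == "standard-in-target-stream")
amp = estimate_peak_amplitude(targets, seed=0)
lat = estimate_onset_latency(targets, standards, seed=0)
print(f"P300 peak amplitude: {amp.estimate:.2f} uV")
print(f"P300 onset latency : {lat.estimate:.3f} s")
print(f"P_th: {significance_threshold(24, 4, 0.05).value}")
itr = information_transfer_rate(0.86, 4, V=60.0 / 90.0)
print(f"ITR at P=0.86: R={itr.R:.3f} bits/trial, B={itr.B:.3f} bits/min")
```

Output:

```
zeroed ICs: [0, 14] (|r| = [0.992 0.851])
P300 peak amplitude: 3.20 uV
P300 onset latency : 0.299 s
P_th: 0.42
ITR at P=0.86: R=1.194 bits/trial, B=0.796 bits/min
```

Reading the numbers: two independent components were removed, one almost
perfectly correlated with the vertical EOG (blinks, |r| = 0.99) and one with
the horizontal EOG (saccades).  The bootstrap recovers the injected 3.5 µV
P300 up to the known ≈ 6 % filtering attenuation; the onset estimate lags
the injected 0.24 s onset because the first *significant* Welch time needs
the response to clear the noise floor (the estimator is validated on
ordering between paradigms, see `docs/methods.md`).  An accuracy of 0.86
over 24 trials clears the 0.42 binomial significance threshold and
corresponds to 1.19 bits per 90 s trial.

The same pipeline runs from the shell:

```bash
asme simulate --paradigm asme2stream --runs 6 --seed 1 --out session/
asme preprocess --in session/ --out cleaned/ --report ica.json
asme erp --in cleaned/ --out erp.json
asme decode --session session/ --out decode.json
asme replicate --seed 1 --fs 250 --n-stimuli 120 --snr high --out report.json
```

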