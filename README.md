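# tfdenoise

Time-frequency denoising of single-channel event-related EEG.

Event-related potentials (ERPs) — stimulus-locked deflections such as the
P300 — are buried in ongoing EEG, muscle activity and other noise at
single-trial level, and the usual remedy, averaging dozens of trials,
destroys exactly the trial-to-trial latency and amplitude dynamics many
studies are after. `tfdenoise` implements a single-trial, single-channel
denoiser that works on the trial's time-frequency image:

1. **STFT** — the trial x(t) becomes a complex time-frequency matrix
   X(t, f), treated as an image;
2. **BEMD** — bidimensional empirical mode decomposition splits the
   magnitude image into intrinsic mode functions BIMF₁…BIMF_N (highest to
   lowest spatial frequency) plus a residue, with
   X = Σᵢ BIMFᵢ + r_N exactly;
3. **NLM** — non-local means filters each sub-image:
   NL F(i) = Σⱼ w(i, j) F(j), with weights
   w(i, j) ∝ exp(−d(i, j)/h²) built from Gaussian-weighted patch distances
   d(i, j) = ‖N(i) − N(j)‖²_{2,a}, exploiting the self-similarity of the
   energy density across the image;
4. the filtered sub-images are recombined, the original phase is
   reattached, and the **inverse STFT** returns the denoised trial.

The package also ships the three standard single-channel baselines the
method is usually compared against — EEMD-ICA, EEMD-CCA and universal
soft-threshold wavelet shrinkage — a seeded synthetic ERP generator
(jittered N1/P3-like components in pink + alpha + EMG-band noise at a
controlled SNR), preprocessing utilities (band-pass, decimation, common
average reference, epoching), and a benchmarking harness that scores every
method by the Pearson correlation of each denoised trial with the
across-trial average reference.

Audience: EEG/ERP researchers and methods developers who need a
single-trial denoiser or a reproducible testbed for comparing one.

## Worked example

```python
import numpy as np
from tfdenoise import synthetic, pipeline, evaluate

sim = synthetic.generate(synthetic.SimConfig(seed=1))      # 56 trials, -5 dB
reference = synthetic.reference_from_trials(sim.trials)    # across-trial mean

trial = sim.trials[0]
denoised = pipeline.tf_denoise(trial)

r_raw = evaluate.pearson(trial, reference)
r_den = evaluate.pearson(denoised, reference)
ratio = pipeline.highfreq_suppression_ratio(trial, denoised, fs=250, f_cut=30)

print(f"corr(raw trial, reference)      = {r_raw:.3f}")
print(f"corr(denoised trial, reference) = {r_den:.3f}")
print(f">30 Hz power ratio (after/before) = {ratio:.3f}")
```

Output:

```
corr(raw trial, reference)      = 0.598
corr(denoised trial, reference) = 0.627
>30 Hz power ratio (after/before) = 0.766
```

The denoised trial tracks the reference waveform better than the raw trial
(correlation up from 0.598 to 0.627) and carries about a quarter less power
above 30 Hz — the band the 2–30 Hz ERP signal should not occupy.

The same operations are available from the shell:

```bash
tfdenoise simulate  --seed 1 --out trials.csv
tfdenoise denoise   --in trials.csv --method tf --out denoised.csv
tfdenoise benchmark --in trials.csv --methods tf,eemd-cca,wavelet \
                    --out per_trial.csv --report report.json
```

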