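# respemg

A toolkit for processing respiratory surface electromyography (sEMG):
cardiac-artifact removal, envelope extraction, breath-level parameter
extraction, and spectral fatigue indices — plus a synthetic-signal
generator with complete ground truth so every stage can be validated
end-to-end.

## What it does

| Module | Contents |
| --- | --- |
| `respemg.signal_core` | `Signal`/`Recording` data model, EDF + CSV I/O with JSON provenance sidecars, antialiased resampling, acquisition checks (fs ≥ 500/1000 Hz, clipping, flatline) |
| `respemg.synthgen` | Band-limited (25–250 Hz) amplitude-modulated EMG bursts (1–10 µV scale), Gaussian-PQRST ECG, baseline wander, mains, white noise, ventilator pressure with trigger/cycle delays and end-expiratory occlusions; returns ground truth (clean EMG, activation, R-peaks, breath landmarks, true conversion factor) |
| `respemg.denoise` | Zero-phase high-pass and mains notch, Pan-Tompkins R-peak detection, QRS gating (zeros/hold/linear/median fills), stationary-wavelet denoising (db2/db4, threshold 4.5·σ per level, approximation band dropped) |
| `respemg.envelope` | Moving RMS / ARV / rectified-median envelopes (centered 250 ms default), fixed-sample-entropy (fSampEn) envelope (m = 1, r = 0.25 × SD), noise-floor estimation and baseline correction (variance subtraction for RMS) |
| `respemg.features` | Breath segmentation (3σ threshold, 300 ms sustain), 70 %-of-peak offset rule, per-breath amplitude (max–min or p95–p5), normalization, EMG-time product, occlusion-derived neuromechanical efficiency and Pmus = k × envelope, ventilator timing (delay, phase angle) |
| `respemg.fatigue` | Welch PSD, mean/median frequency, H/L ratio (150–350 Hz over 20–46.7 Hz), spectral-moments ratio of order five (M(−1)/M(5)), per-breath trends |
| `respemg.pipelines` | Preset pipelines (`data_check`, `gating`, `wavelet`, `fsampen`, `custom`), full parameter provenance with bit-for-bit reproducible re-execution, cross-pipeline comparison |

## CLI

```sh
# generate a 60 s synthetic recording + ground truth
respemg simulate --out-dir out/sim --seed 1 --with-ventilator

# process it with a preset pipeline
respemg process --input out/sim/synthetic.csv --preset wavelet --out-dir out/proc

# per-breath feature table + summary
respemg features --input out/sim/synthetic.csv --preset wavelet --out-dir out/feat

# compare two pipelines on the same recording
respemg compare --input out/sim/synthetic.csv --preset gating --preset wavelet
```

`process` writes `envelope_<channel>.csv`, `features.csv` and
`provenance.json`; re-running a provenance document through
`respemg.pipelines.run_provenance` reproduces envelope samples
hash-identically.

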