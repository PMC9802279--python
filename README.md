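# matecalcium

Analysis pipeline for brain-wide calcium imaging of *C. elegans* male mating
behavior, bundled with a synthetic-recording generator so every stage can be
exercised and validated fully offline.

The package covers five analysis stages plus orchestration:

- **`matecalcium.synthetic`** — generates motif-structured mating ethograms
  (semi-Markov, exponential dwell times), neural activity coupled to
  behavioral motifs through a calcium-like difference-of-exponentials
  kernel, two-channel fluorescence emissions with a shared multiplicative
  motion artifact and shot-like noise, injected spurious-activation pulses,
  and rendered two-channel volumes (0.45 µm pixels, 1.75 µm slice spacing,
  10 volumes/s on a reduced desk-scale grid) — all with ground truth.
- **`matecalcium.extraction`** — mean-ROI channel signals over
  2.25 × 2.25 × 3.5 µm boxes centered on tracked nuclei, block-mean
  downsampling 10 → 5 samples/s, offset-subtracted green/red ratio, and
  Savitzky–Golay smoothing (order 1, window 13).
- **`matecalcium.alignment`** — event-triggered windows (−7 s … +13 s),
  pooled min–max-normalized response curves, per-instance lagged Pearson
  correlation against binarized behavior (lags ±5 samples = ±1 s) with lag
  selection by maximum absolute mean correlation and a one-sided one-sample
  t-test, peak-latency summaries, and rank-sum latency comparisons.
- **`matecalcium.ethogram` / `matecalcium.metrics`** — ethogram data model
  and validation, the eight mating-performance measures plus the mating
  success index (ejaculations per courtship minute), cohort success
  percentages (floored), and two-sided Wilcoxon rank-sum cohort
  comparisons.
- **`matecalcium.spurious`** — screening for pulses of vulva-circuit
  activation away from (guard-dilated) vulva contact on per-recording
  min–max-normalized traces, per-male classification, and per-genotype
  fractions.
- **`matecalcium.pipeline` / `matecalcium.cli`** — configuration, format
  readers/writers (ethogram/trace/track CSV, volume HDF5/TIFF, result
  JSON), and the end-to-end `run` orchestration with a manifest hash
  embedded in every output for exact reruns.

## Command line

All functionality is exposed through the `matecalcium` entry point:

```sh
matecalcium simulate-ethogram --seed 1 --out ethogram.csv
matecalcium simulate-traces --ethogram ethogram.csv --seed 1 --out raw.csv
matecalcium render-volumes --traces raw.csv --seed 1 --out volumes.h5 --tracks-out tracks.csv
matecalcium extract --volumes volumes.h5 --tracks tracks.csv \
    --roi 2.25 2.25 3.5 --sg-window 13 --sg-order 1 --downsample 2 --out activity.csv
matecalcium align     --traces activity.csv --ethogram ethogram.csv --neuron PCA --motif backward_slide --out curve.json
matecalcium correlate --traces activity.csv --ethogram ethogram.csv --neuron PCA --motif backward_slide --out corr.json
matecalcium latency   --traces activity.csv --ethogram ethogram.csv --neuron PVV --motif turn_success --out latency.json
matecalcium metrics --ethograms ethogram_dir/ --out metrics.csv
matecalcium compare --group-a a.csv --group-b b.csv --measure turning_success_rate --out cmp.json
matecalcium spurious --traces activity.csv --ethograms ethogram.csv --out spurious.json
matecalcium run --seed 1 --out results/
```

`matecalcium run` chains simulate → render → extract → align/correlate →
metrics → spurious screen and writes `manifest.json`, `metrics.csv`,
`correlations.json` and `spurious.json`; rerunning with the same config and
seed reproduces the text outputs byte for byte.

## Conventions

- Timestamps are seconds from recording start; intervals are half-open
  `[onset, offset)`; sample *i* at rate *r* covers `[i/r, (i+1)/r)`.
- Positive correlation lag means neural activity follows behavior.
- Measures with zero denominators are reported as undefined (`None`/empty),
  never as 0, and are excluded (with counts) from rank-sum tests.
- All generators are pure functions of (config, seed).
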