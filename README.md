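# rsfc

ROI-level resting-state functional-connectivity pipeline with a synthetic
cohort generator. The package implements, as tested and reusable code:

- **`rsfc.synthetic`** — cohorts of BOLD-like ROI recordings with planted
  correlation structure (three built-in profiles: `sighted_like`,
  `blind_like`, `infant_like`), linear drift, shared physiological
  nuisance, motion spikes, parcel-level signal dropout, and a
  ground-truth ledger for recovery tests. Includes a nearest-correlation
  (alternating-projections) PSD repair.
- **`rsfc.qc`** — DVARS, IQR-based motion-outlier flagging, best
  continuous-window selection, −3 SD signal-dropout detection, and
  group-specific exclusion rules.
- **`rsfc.preprocess`** — linear detrend, zero-phase Butterworth low-/
  band-pass filtering, nuisance principal-component extraction and
  regression (CompCor-style), frame censoring; all steps recorded in a
  provenance trail.
- **`rsfc.connectivity`** — Pearson FC matrices, seed–target block
  averages, within/between-hemisphere laterality, min–max profile
  normalization, group-matrix profile correlations, split-half noise
  ceilings.
- **`rsfc.stats`** — mixed between/within ANOVA interaction, paired t
  with Cohen's d, Bonferroni adjustment, the dependent-correlation z test
  for two correlations sharing a variable, one-way ANOVA with partial η².
- **`rsfc.pipeline` / `rsfc.cli`** — configuration-driven orchestration
  of QC → denoising → connectivity → group statistics with tidy CSV
  outputs.

## CLI

```bash
# write a synthetic cohort (TSV per subject + JSON sidecars + ledger)
rsfc simulate --config config.yaml --out data/ --seed 1

# QC stage only
rsfc qc --in data/ --out qc/

# full pipeline (reads a dataset directory, or simulates from the config)
rsfc run --config config.yaml --in data/ --out results/
rsfc run --config config.yaml --out results/ --seed 1   # in-memory cohort

# group statistics from an existing tidy block-FC table
rsfc stats --block-fc results/block_fc.csv --out stats.csv
```

Example `config.yaml`:

```yaml
simulation:
  groups:
    sighted: {n: 50, profile: sighted_like, n_frames: 300, tr_seconds: 2.0}
    blind:   {n: 30, profile: blind_like,   n_frames: 300, tr_seconds: 2.0}
    infant:  {n: 475, profile: infant_like, n_frames: 2300, tr_seconds: 0.392}
pipeline:
  compcor_k: 5
  qc: {iqr_factor: 1.5, window_length: 1600, max_outlier_fraction: 0.10,
       dropout_sd: 3.0}
  filters:
    sighted: {lowpass_hz: 0.08, highpass_seconds: 150}
    blind:   {lowpass_hz: 0.08, highpass_seconds: 150}
    infant:  {lowpass_hz: 0.08}
```

All thresholds default to the shipped profile above when omitted.

## Conventions worth knowing

- DVARS at the first frame is 0; outlier flagging is strict
  (`> Q75 + 1.5·IQR`, linear-interpolation quantiles); window ties break
  to the earliest start; the dropout rule is strict (`< μ − 3σ`, sample
  SD across parcels).
- Denoising order is detrend → nuisance regression → filter → censor
  (censoring last avoids filtering across gaps); a config flag flips the
  last two stages, visibly in the provenance.
- Block averages use raw mean r (Fisher-z behind a flag); matrix-profile
  correlations use the strict lower triangle; noise-ceiling splits are
  contiguous in time.

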