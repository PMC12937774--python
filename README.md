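# gvscreen

EEG-biomarker-driven screening of galvanic vestibular stimulation (GVS)
waveforms for Parkinson's disease, re-implemented as a tested, reusable
pipeline with a synthetic EEG cohort generator standing in for the
(non-deposited) human recordings.

The pipeline:

1. **Stimulus library** (`gvscreen.stimuli`) — a 304-stimulus GVS waveform
   library (DC, sinusoids 0.5–200 Hz, AM, chirp, chirp-AM, FM, PAC-modulated,
   multisine, binary patterns, one sham) grouped into 37 morphology
   categories, with deterministic waveform synthesis and JSON/CSV I/O.
2. **Synthetic cohort** (`gvscreen.simulate`) — seeded virtual subjects
   (5 HC + 5 PD by default) × 304 nine-second trials (2 s pre / 2 s stim /
   5 s post at 1000 Hz, 36-channel extended 10–20 montage).  PD-vs-HC
   contrasts are planted in beta power, beta bursts, beta–gamma PAC,
   waveform asymmetry, aperiodic slope and entropy; "effective" stimulus
   categories transiently pull PD generator parameters toward the healthy
   mean during the stimulation interval only.
3. **Biomarkers** (`gvscreen.features`) — 16 features per 2 s window:
   Tort-MI beta–gamma PAC, peak–trough asymmetry, rise–decay ratio,
   aperiodic exponent/offset, burst duration/amplitude/energy, beta and
   relative beta power, Petrosian FD, Hjorth mobility/complexity, spectral/
   approximate/sample entropy.  Windows: pre, stim, and four overlapping 2 s
   post windows (averaged); features averaged over 13 central electrodes.
4. **Composite model** (`gvscreen.model`) — leave-one-subject-out L1
   logistic regression on pre-stimulation features with an inner-CV 1SE
   rule; fold-averaged coefficients define a single scoring axis, a healthy
   reference score, and per-trial distances.
5. **SES ranking** (`gvscreen.ranking`) — 304×5 inverse-distance decision
   matrix, per-subject vector normalization, TOPSIS relative closeness
   (the Stimulus Evaluation Score) and global ranks.
6. **Group inference** (`gvscreen.stats`) — per-subject ranks, category
   median ranks, tie-corrected Kendall's W, one-tailed rank-sum tests with
   Benjamini–Hochberg FDR (q ≤ 0.1), Spearman stim/post-stim check, and
   per-channel paired-t −log10(q) maps.

## CLI

```bash
gvscreen run-all --out runs/demo --seed 0        # simulate -> report
gvscreen simulate --out session/ --seed 0        # EDF session + events CSVs
gvscreen extract  --session session/ --out features.csv
gvscreen train    --features features.csv --out model.json --accuracy acc.json
gvscreen score    --model model.json --features features.csv --out scores.csv
gvscreen rank     --scores scores.csv --out ses.csv
gvscreen stats    --features features.csv --library session/library.json --out stats/
```

Every tunable decision (band edges, burst rule, PAC bins, LASSO settings,
MCDA normalization, thresholds, cohort layout, seeds) lives in a YAML
`PipelineConfig`; pass it with `--config`.  All randomness flows from the
cohort master seed, and repeated runs are byte-identical.

Sessions are written as one EDF file per subject plus plain-text metadata
(`library.json`, `subjects.csv`, `truth.csv`, `<subject>_events.csv` with
0-based stimulus-onset sample indices).

## Notes

- ApEn/SampEn are computed on a copy decimated to 250 Hz by default
  (configurable via `BiomarkerConfig.entropy_fs`); this keeps the O(N²)
  estimators tractable at cohort scale.
- The synthetic cohort's effect sizes are calibrated so the LOSO classifier's
  pre-stimulation accuracy lands in the 80–90% range and the four planted
  categories (11, 20, 33, 36) are recoverable; they are not fitted to
  clinical data.
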