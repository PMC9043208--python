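# fqrs — automated fragmented-QRS detection and quantification

`fqrs` scores fragmentation of the QRS complex (fQRS) in short multi-lead
ECG strips. For each analyzed lead (the standard 12-lead set minus aVR) it
outputs a continuous fQRS score in [0, 1] plus its 0.5-threshold binary
call.

Pipeline per recording:

1. **Preprocessing** — zero-phase Butterworth band-pass (order-4 high-pass
   at 0.5 Hz, order-6 low-pass at 70 Hz) and per-lead z-normalization.
2. **Multi-lead QRS segmentation** — per-lead R-peak detection
   (Pan-Tompkins-family envelope detector), cross-lead consolidation so
   every lead carries the consensus beat count n_R (missed beats recovered
   by a refined 40 ms maximum search, surplus detections pruned toward the
   consensus positions), wavelet-based QRS onset/offset delineation
   (quadratic-spline dyadic transform, modulus-maxima search), cross-lead
   median reallocation of boundaries, template selection, beat alignment,
   and a correlation quality filter (q = 0.85) that removes irregular or
   ectopic heartbeats.
3. **Features** (10 per lead) — central frequencies and zero-crossing
   counts of variational-mode-decomposition modes 3-5 (K = 5), mean
   derivative / linear-fit slope / y-crossing of the phase-rectified signal
   averaging (PRSA) curve (40 ms window), and the QRS peak count.
4. **Classifier** — SVM (linear / polynomial / RBF kernels, seeded
   cross-validated hyperparameter search) with Platt scaling to a
   calibrated probability of the fragmented class.
5. **Evaluation** — sensitivity/specificity/PPV, ROC and PR AUC, Cohen's
   kappa with a 100-threshold sweep, and Pearson correlation against
   ordinal (0-5) observer-style labels.

A synthetic-data module generates multi-lead ECG with full ground truth
(R locations, QRS boundaries, per-lead fQRS labels, ectopic flags, sinus
vs. AF-like rhythm), so the entire pipeline is testable without clinical
data.

## CLI

```bash
# generate a synthetic cohort (WFDB records + manifest CSV)
fqrs simulate fixtures/ --n-recordings 50 --prevalence 0.3 --seed 1

# train on a synthetic cohort (or --features-csv <table>)
fqrs train model.json --n-recordings 100 --kernel linear --seed 1 \
    --report-out report.csv

# score recordings (11 rows per 12-lead recording)
fqrs score model.json fixtures/syn0000 fixtures/syn0001 --out scores.csv

# metric report for scored, labeled leads
fqrs evaluate scored_labeled.csv --out metrics.json
```

Inputs are WFDB records (`.hea`/`.dat`, format 16) or delimited text with
a lead-name header row (pass `--fs` for text). Config defaults
(q = 0.85, K = 5, threshold 0.5, band edges, ...) can be overridden via a
YAML file passed as `--config-file`. Exit codes: 0 ok, 1 data error,
2 config error.

## Layout

```
src/fqrs/
  io_preprocess.py   # recording I/O, band-pass, normalization, lead selection
  wfdb_io.py         # minimal WFDB format-16 reader/writer
  segmentation.py    # R-peak detection + consolidation, delineation, quality filter
  features.py        # VMD, PRSA, peak count, per-lead feature vector
  classifier.py      # SVM + Platt scaling, splits, class balancing, persistence
  evaluation.py      # Sens/Spec/PPV, ROC/PR AUC, kappa sweep, ordinal correlation
  synthetic.py       # synthetic ECG generator with ground truth
  pipeline.py        # end-to-end glue
  cli.py             # typer CLI: simulate / train / score / evaluate
```
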