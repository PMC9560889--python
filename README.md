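# wptgc

Time-frequency Granger causality for paired physiological time series
(e.g. one EEG and one EMG channel). The pipeline:

1. **Preprocessing** (`wptgc.io_preprocess`) — common average reference,
   zero-phase 1–60 Hz Butterworth bandpass, anti-aliased resampling to
   250 Hz, segmentation into 7 s trials (3 s preparation + 4 s execution),
   baseline correction, trial averaging, per-channel z-scoring.
2. **Band extraction** (`wptgc.wpt`) — a seven-level Coiflet wavelet
   packet transform with periodized boundaries (exactly orthogonal, so the
   summed terminal-band reconstruction matches the input to ~1e-30 MSE).
   Terminal nodes are mapped from natural filter-tree order to ascending
   frequency by the inverse Gray-code permutation; `extract_band`
   reconstructs the ~0.98 Hz band containing a requested center frequency.
3. **Nonlinear models** (`wptgc.narx`) — polynomial (linear + quadratic)
   NAR/NARX models; structure detection by forward-regression orthogonal
   least squares (FROLS) with the error-reduction ratio, Gram–Schmidt
   orthogonalization and triangular back-substitution, with an optional
   (default) least-squares refit of the selected terms.
4. **Causality** (`wptgc.causality`) — directed GC as the log ratio of
   restricted/full one-step residual variances (the full model nests the
   restricted term set so the ratio is monotone), sliding-window
   time-varying GC, frequency × time GC maps, canonical band/period
   summaries, surrogate significance thresholds, and gated group
   statistics (Shapiro–Wilk + Levene → one-way ANOVA, else
   Kruskal–Wallis).
5. **Ground truth** (`wptgc.synthetic`) — seeded generators for coupled
   polynomial difference-equation pairs (constant / step / ramp coupling
   profiles) and narrowband oscillatory pairs, plus a registry of frozen
   fixtures (`null_pair`, `linear_unidirectional`,
   `quadratic_unidirectional`, `bidirectional`, `step_coupling`,
   `banded_20hz`).

## CLI

All commands are subcommands of `wptgc` (tabular I/O is CSV, reports and
manifests are JSON):

```sh
wptgc simulate --fixture linear_unidirectional --n 10000 --seed 7 x.csv y.csv truth.json
wptgc preprocess --fs 2500 --onsets 10000,30000 raw.csv segments/
wptgc decompose --wavelet coif5 --levels 7 --fs 250 --bands 1:50 in.csv bands/
wptgc gc --p 5 --q 5 --nmax 10 y.csv x.csv
wptgc tfmap --window 1.0 --step 0.1 --freqs 1:50 --fs 250 eeg.csv emg.csv out/
wptgc bands --bands delta:0.5-4,theta:4-8,alpha:9-12,beta:13-35,gamma:35-50 \
            --periods preparation:0-3,execution:3-7 out/map_x_to_y.csv summary.csv
wptgc stats groups.csv --group-column group --value-column gc
wptgc run --config cfg.yaml eeg.csv emg.csv out/
```

`wptgc run` executes the whole chain and writes both directed TF maps,
the band/period summary and a manifest (config, versions, input/output
checksums) that makes runs byte-reproducible.

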