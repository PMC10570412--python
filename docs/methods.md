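# Methods

Conventions, parameter choices and numerical details behind `epistage`. The
README gives the pipeline overview; this document records the decisions a
user needs to interpret or change results.

## Surrogate EEG generator

Each channel is generated independently as

```
x(t) = white Gaussian noise (SD noise_sd)
     + 1/f-shaped pink noise (SD pink_sd)
     + Poisson-timed sinusoidal bursts (carrier burst_freq, amplitude burst_amp)
```

Stage defaults (`default_stage_params`):

| stage   | noise_sd (µV) | pink_sd | burst_rate (1/s) | burst_amp (µV) | regularity |
|---------|---------------|---------|------------------|----------------|------------|
| normal  | 50            | 15      | 0 (no bursts)    | 0              | 0.0        |
| acute   | 50            | 15      | 8                | 400            | 0.9        |
| chronic | 50            | 15      | 2                | 100            | 0.2        |

The burst carrier (330 Hz by default) lies inside the fast-ripple analysis
band so stage information survives subband filtering. Each burst lasts
`regularity / burst_rate` seconds, so `regularity` equals the expected duty
cycle when bursts do not overlap: the acute stage is almost continuously
occupied by strong rhythmic discharge, the chronic stage sparsely by weak
discharge. These defaults were chosen *a priori* so that mean sample entropy
of the filtered signal orders normal > chronic > acute — regular
high-amplitude oscillation is highly predictable (low entropy); sparse weak
bursts reduce entropy only slightly.

**Limitations.** Channels are statistically independent given the stage —
there is no volume conduction, no inter-channel coupling, no spikes/sharp
waves, no artifacts, and no nonstationarity beyond burst timing. The
generator supports a qualitative study of complexity-based staging, not a
biophysical simulation. `run_per_subject` adds multiplicative log-normal
jitter to the stage parameters per synthetic subject to emulate
inter-subject heterogeneity.

Seeding: every random quantity derives from one integer seed via
`np.random.default_rng([seed, key])`; derived seeds are bounded below 2^31.

## Preprocessing

- Epochs: non-overlapping windows of `epoch_seconds` (default 1 s); a
  trailing remainder is dropped. `segment_equal(rec, 20)` provides the
  20-equal-part split used in protocol arithmetic.
- Band extraction uses Haar DWT subband reconstruction: detail level *j*
  covers the dyadic band [fs/2^(j+1), fs/2^j], and every level whose band
  *strictly overlaps* the requested band is kept (approximation and all
  other details are zeroed before `waverec`). At fs = 1000 Hz the
  250–500 Hz fast-ripple band is exactly the level-1 detail; the level-1
  Haar detail reconstruction removes each consecutive sample pair's mean.
  Odd-length inputs are edge-padded and trimmed after reconstruction.

## Complexity measures

All five operate on one channel of one epoch; tolerances `r` are
`r_frac × SD(channel)` with `r_frac = 0.2`, embedding `m = 2` unless noted.

- **ApEn**: Φ^m − Φ^(m+1) with self-matches included, Chebyshev distance,
  natural log.
- **SampEn**: −ln(A/B) with both A and B counted over the first N−m
  templates, i ≠ j (self-matches excluded). B = 0 raises
  `UndefinedResultError`; A = 0 yields +inf. In batch feature extraction
  both cases are replaced by `sampen_cap` (default 10.0) with a
  `RuntimeWarning`, so feature matrices stay finite.
- **PE**: ordinal patterns of order 3, delay 1; ties ranked by earlier
  index (stable argsort); Shannon entropy normalized by ln(3!).
- **FuzzEn**: mean-subtracted templates, exponential membership
  exp(−(d/r)^n) with n = 2.
- **KC**: binarize strictly above the channel median, LZ76 phrase count
  c(n) by the Kaspar–Schuster scan, normalized to c(n)·log2(n)/n.

A constant channel (SD = 0) returns 0 for the four entropies by convention.
Hot loops (ApEn, SampEn, FuzzEn, LZ76) are numba-compiled;
`epistage.oracles` contains deliberately naive pure-Python
transcriptions of the definitions used as independent test references. To
make PE comparisons exact, both implementations accumulate −p·log p over
patterns in lexicographic order with `math.log`.

### Protocol note on epoch length for statistics

The template entropies are O(N²) in epoch length; 30-second epochs
(N = 30,000) are computationally impractical. The statistical layer
(`stage_separation_report`, the acceptance checks) therefore builds its
160-value stage groups from twenty 1-second epochs × 8 channels, preserving
the group-size arithmetic of the 20-equal-epoch protocol at tractable cost.

## Graph dataset and model

- Topology is a fixed complete graph K8 (edges 1, no self-loops): stage
  information enters only through node features.
- Split 50–20–30, stratified per class, shuffled deterministically from the
  run seed. Feature standardization uses training-set statistics only;
  zero-variance columns keep their values (SD replaced by 1, with warning).
- Laplacian: L̃ = 2·L_norm/λ_max − I with L_norm = D̂^(−1/2)(D−A)D̂^(−1/2);
  isolated nodes use degree 1 in the normalization; λ_max falls back to the
  theoretical bound 2 when L_norm is identically zero. For K8 the spectrum
  of L̃ is exactly {−1, 1}.
- Architecture: ChebConv(1→10, K=3) → max-pool (nodes 8→4 as fixed pairs,
  features 5→3) → ReLU → ChebConv(10→20, K=3, Laplacian of the coarsened
  complete graph K4) → max-pool (4→2, 3→1) → ReLU → flatten (40) → FC 40→15
  → ReLU → dropout 0.5 → FC 15→3 → softmax. Pooling windows are
  left-aligned equal blocks; the last absorbs the remainder.
- Training: mini-batch SGD, lr 0.001, momentum 0.5, batch 6, mean
  cross-entropy; dropout is inverted (scaled at train time). The returned
  model carries the weights of the epoch with the best validation accuracy.
  The default is 50 training epochs; short 3-epoch schedules are supported
  through `TrainConfig` but generally underfit at this learning rate.
  Training is bit-reproducible for a fixed seed (initialization, batch
  order and dropout masks all derive from it).
- Gradients are analytic (manual backpropagation through every layer) and
  are checked against central finite differences in the test suite
  (relative error < 1e-5).

## Statistics

- One-way ANOVA from explicit between/within sums of squares;
  p = F-survival function at (k−1, N−k). All-identical groups return
  (F, p) = (0, 1); zero within-group variance with nonzero between-group
  variance raises.
- Tukey–Kramer: q = |mean_i − mean_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)),
  p from the studentized range distribution at (k, N−k). Differences are
  signed first-minus-second in stage order (normal, acute, chronic).
- PCA on the correlation matrix (columns standardized with ddof=1),
  eigendecomposition via `np.linalg.eigh`; each component's sign is fixed so
  its largest-magnitude loading is positive.
- General per-channel features: mean, population variance, max, min, and
  moment skewness m3/m2^(3/2) (0 for constant channels, with warning).

## I/O conventions

- Data are µV, arrays are channels × samples, 8 channels by default in the
  canonical montage order.
- CSV: header of channel names, one row per sample; sampling rate must be
  supplied by the caller (`fs_override`).
- EDF: 16-bit, 1-second data records, physical range ±5000 µV (quantization
  step ≈ 0.153 µV); stage and subject are stored in the EDF patient /
  recording identification header fields and recovered on read (reading
  uses MNE).
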