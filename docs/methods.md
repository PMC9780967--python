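# Methods

## Scope and data model

`wotrack` re-implements, at desk scale, a wearable tracker for the
Levodopa wearing-off phenomenon: per-step classification of OFF
(pre-administration) versus ON (post-administration) walking from
bilateral leg sEMG, with an optional EEG movement-related-potential
branch. The clinical recordings behind the published population
statistics are not deposited, so the package substitutes a synthetic
session generator calibrated to those statistics; every downstream stage
is then validated against the generator's hidden ground truth. Passing
tests therefore demonstrate internal correctness and statistical
calibration of the pipeline on a realistic signal model — they do not
certify performance on real patients.

## Synthetic walking sessions

Each leg is a renewal process of strides anchored at the Lateral
Gastrocnemius (LG) onset, i.e. foot strike. Per stride the generator
draws, independently per condition:

* stride time ~ N(mean, sd), quantized to the 2 ms grid (clipped at
  700 ms; with the default statistics the clip probability is ~1e-7);
* per-muscle duty cycles ~ N, clipped to [2, 95] %;
* LG–TA and RF–BF co-contraction times ~ N, capped per stride at the
  realized contraction minimum of the pair.

**Condition statistics (defaults).** Means follow the published
population table; SDs follow the running-text description (the only
place SDs appear). Pre: stride 1081.09 ± 72.01 ms, co-con LG-TA
113.74 ± 32.12 ms, co-con RF-BF 232.51 ± 50.04 ms, DC LG/TA/RF/BF
24.78 ± 3.70 / 63.48 ± 5.44 / 56.29 ± 5.49 / 23.31 ± 2.42 %. Post:
stride 1044.64 ± 34.49 ms, co-cons 106.16 ± 29.19 and 228.02 ± 17.00 ms,
DC means 24.34 / 63.49 / 57.49 / 23.54 % (post DC SDs are published
nowhere and reuse the pre values). The source lists TA ≈ 63 % / RF ≈ 56 %
in its table but the swapped values in its text; the table convention is
the default and `default_params(..., dc_convention="text")` selects the
other reading.

**Co-contraction cap compensation.** The RF-BF co-contraction mean
(232.5 ms) lies within one SD of the BF contraction-time mean (~252 ms),
so naively capping draws at the per-stride minimum would bias the
realized mean by ≈ −16 ms. The generator therefore shifts the draw mean
by the root of `E[min(N(m + delta, s), cap)] = m` under a normal
approximation of the tighter cap. Realized *means* then match the
configured ones (verified within 4·sd/√n in the tests); the realized SD
in capped regimes falls somewhat below the configured value, which is the
price of honouring both the marginal mean and the hard physical
constraint `co-contraction ≤ min(contraction times)`.

**Activation template.** Where in the stride each muscle fires is not
published; the template is physiologically motivated and fixed: LG fires
at foot strike for its duty cycle; TA spans late stance/swing and
continues through the next foot strike, overlapping LG's onset by exactly
the drawn LG-TA co-contraction; RF fires from foot strike through
stance; BF overlaps the end of the RF burst by the drawn RF-BF
co-contraction. Quantized overlaps are exact by construction, which gives
the stride-feature stage an exactness oracle (noise-free triggers must
reproduce the truth table bit for bit).

**sEMG model.** Channel = white baseline noise (RMS 30 counts) + Gaussian
carrier band-passed 20–200 Hz, amplitude-modulated by a trapezoidal
envelope of the activation mask with 20 ms linear ramps centred on the
mask edges; default SNR 20 dB (burst RMS over baseline RMS); samples
rounded to integers in the 16-bit range. A 1 s quiet lead-in precedes the
first stride (the detector's baseline seed assumes a relaxed start).

**EEG model.** 1/f background (~20 uV RMS) plus one burst per band (BP
8 uV, mu 5 uV, beta 3 uV nominal, 20 % amplitude spread) per channel,
Hann-windowed 300 ms tones centred 150–450 ms before every LG onset.
Burst draws come from a random stream keyed by (seed, leg, stride index)
and *not* by condition: with matched EEG seeds the pre and post
ground-truth band features are identical, which realizes the cortical
null exactly at the feature level. Note the absolute dB re 1 uV scale of
signal-extracted features (~15–30 dBu) is far below the published
feature table (~40–63 dBu, which plausibly includes an acquisition
gain); only relative comparisons and the null matter here, and the
feature-table layer draws band features directly at the published dB
values. Background segments are generated per session, so two conditions'
raw EEG signals differ; the exact pairwise null holds for the
ground-truth/feature-table layer, while pipeline-extracted features
differ by onset-detection jitter and are only null *in distribution*.

**Between-subject variation.** A per-subject multiplicative effect on
every feature mean (3 % SD, truncated to [0.7, 1.3]), drawn once per
subject and shared by both conditions — a subject keeps their gait scale
across sessions, so paired contrasts are unaffected while cross-subject
generalization (train/test splits) is made realistically harder.

## Trigger generation

Stages: (1) mean-square envelope over a 50 ms window centred on the
sample (24 ms lookahead; the deployed analogue would incur it as
latency); (2) double-threshold state machine — ON above
`mu_b + 3 sigma_b`, OFF below `mu_b + 1.5 sigma_b`, with baseline
statistics over a sliding 2 s pool restricted to OFF samples, seeded by
the first 500 ms (documented limitation: a session must start relaxed);
(3) 30 ms debounce (gap-closing then short-burst removal); (4) burst
validation — bursts whose plateau power is below 4x baseline are
rejected as hysteresis chatter (genuine bursts at the supported
10–30 dB SNR sit at ≥ 10x); (5) edge relocalization.

Stage 5 exists because raw threshold crossings of a windowed envelope
are structurally biased: onsets trip early in the window fill and offsets
only after it drains, by up to ~50 ms at the low OFF threshold. Each
coarse edge is therefore refitted by least squares against the model
`E[env²](t) = n₀² + A²·smooth(ramp²((t − tau)/rho))` with the ramp centre
tau (±12 samples) and duration rho ∈ {12, 20, 32} ms free, minimizing
*relative* squared error (inverse-model weighting). The weighting
matters: the envelope noise is multiplicative chi-square, and both
unweighted and log-scale fits showed measurable sample-level bias on
single-burst probes, while the relative-error fit is mean-unbiased to
~0.3 samples. Plateau power is pooled across a channel's bursts (trimmed
mean of per-burst estimates) when a burst is within a factor 2 of the
pool, since short-core per-burst estimates are noisy and that noise
propagates into a symmetric outward edge bias; heterogeneous bursts keep
their own estimate. A second fit pass recentred on the first estimate
removes the first-passage bias of the crossing-based search centre.
Residual bias after all stages: ~+0.5 samples (+1 ms) on contraction
durations at 20 dB SNR, i.e. ≈ 0.1 % duty cycle, within the 3-SE
recovery tolerance at 2000 strides. All thresholds are relative to
data-derived statistics, so the trigger is invariant under positive
rescaling of the input.

## Stride features

Strides are half-open intervals between consecutive LG trigger onsets of
one leg; incomplete boundary cycles are dropped, as are
trajectory-curving steps flagged by the generator. Contraction times are
per-stride totals over possibly multiple bursts (a config question left
open by the source; totals keep `contraction + relaxation = stride time`
exact). A burst straddling a stride boundary contributes its in-stride
samples to each stride. Left and right legs are pooled as independent
observations, ordered chronologically, with the leg kept as metadata.

## MRP features

A 256-sample (~512 ms) FIFO per EEG channel; at each LG onset the
snapshot is analysed by STFT — default frame 128, hop 64, Hann window —
and the per-band feature is `20·log10(max |X| / 1 uV)` over frames and
in-band bins, floored at −120 dBu. Magnitudes are coherent-gain
normalized (2/sum(window)) so an on-bin unit sinusoid reads its
amplitude, making the 1 uV reference physical. Band edges are inclusive;
with coarse frames a band may contain no bin centre (the 9–11 Hz mu band
at 128-point resolution), in which case the bin nearest the band midpoint
is used. Whether "maximum spectral content" means magnitude or power is
unstated in the source; magnitude is the default and power is a config
switch (it changes nothing after the square root in dB). A single-frame
256-point rectangular mode exists for oracle testing against a direct
DFT.

## Statistical selection

Two-sided paired Student's t-tests per feature at alpha = 0.05, no
multiple-testing correction by default (matching the per-feature reading
of the source analysis; Bonferroni is a flag). The default pairing
matches the i-th valid stride of a subject's pre session to the i-th of
its post session, truncated to the shorter; subject-level-mean pairing is
the alternative. Degenerate cases are explicit: all-zero differences give
t = 0, p = 1; zero-variance nonzero differences report p = 0 with a flag.
Note that with these population statistics the TA duty cycle is a true
near-null (means 63.48 vs 63.49 %), so its p-value is approximately
uniform; any single simulation shows p > 0.05 about 95 % of the time,
which is the expected behaviour, not an instability of the test.

## Classifiers

The four shallow models use scikit-learn behind the module surface
(CART with Gini and a 129-split cap expressed as 130 leaf nodes, QDA with
1e-6 regularization, linear-kernel SVC, KNN with k = 21/city-block/equal
weights); scale-sensitive ones are z-scored with training-set statistics.
The four dense networks run on an in-package engine: batch-norm input
layer (eps = 1e-3, running statistics by exponential moving average),
dense hidden layers (He init), sigmoid output, binary cross-entropy,
Nadam (DNN1–3) or RMSProp (DNN4), batch size 32, up to 200 epochs with
early stopping (patience 20) on a held-out fold of a stratified 4-fold
split. None of the training hyperparameters beyond the optimizer choice
are published; all are config-exposed. Scores are probability-like in
[0, 1] for the positive class (pre-Levodopa/OFF); the SVM decision
function is mapped through a logistic, which is monotone and therefore
ROC-neutral. The published layer listing for the third network is
internally inconsistent; it is implemented as two hidden layers of 32
(Tanh, then ReLU), making its parameter count equal to the second
network's even though the published flash footprints differ — matching
vendor-toolchain memory numbers is out of scope.

Complexity accounting convention: dense in→out layer = in·out MACC plus
out bias accumulates; batch-norm = 2 ops per input (folded scale/shift);
activations counted separately as non-MACC ops; ROM = 4 bytes per
parameter (float32); RAM = 4 bytes per slot of the widest consecutive
activation-buffer pair plus input and output. The capacity ordering
DNN1 > DNN2 ≥ DNN3 > DNN4 matches the published flash ordering.

## Evaluation

Confusion counts with positive = pre-Levodopa; accuracy, recall,
precision, F1 and specificity in percent, rounded half-up to 2 decimals
(the tables' convention); ROC by threshold sweep with tied scores swept
together, AUC by trapezoid, and the operating point minimizing the
Euclidean distance to {FPR, TPR} = {0, 1}. Undefined ratios (empty
denominators) surface as NaN rather than silently as 0.

## Problem sizes and reproducibility

The default cohort mirrors the study bookkeeping: 3 training + 2 test
subjects (disjoint by construction, validated), 2 sessions each, 8 runs x
150 steps (75 strides per leg) = 1200 steps per session, hence 3600
steps per condition for training and 2400 for testing. The full
signal-level pipeline at this scale runs in ~10 s per classifier on one
CPU. Parameter-recovery checks use a single 2000-stride session; the
selection pattern is checked over 20 replicates of 3600 feature pairs
drawn at the statistics layer (signal synthesis adds nothing to a test of
the t-test layer and would dominate its runtime). Every stage derives its
random stream from a master seed plus a stage key (FNV-hashed labels into
a SeedSequence), so reruns are bit-identical; EEG stream keys omit the
condition to realize the cortical null.

## Known limitations

* The generator draws strides i.i.d.; real gait has serial correlation
  (drift, fatigue), which would widen paired-test variances.
* Left and right legs are independent renewal processes with a half-
  stride initial offset; true bilateral phase coupling is not modelled.
* EMG bursts have stationary amplitude within a session; the trigger
  stage's pooled-plateau default leans on this (per-burst fallback
  engages beyond a factor-2 spread).
* The EEG branch's absolute dB scale is not matched to the published
  feature magnitudes (see above); cortical results here are null checks,
  not amplitude reproductions.
* Classification accuracy on synthetic cohorts (~74 % for the deployed
  network) is not a claim about the published patient-level accuracy
  (~84 %), which depends on undeposited recordings.
* Baseline seeding assumes the first 500 ms of a run are relaxed; a run
  starting mid-gait would corrupt the adaptive threshold until the
  baseline pool turns over.
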