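# wotrack

Tracking the **wearing-off (WO) phenomenon** in Parkinson's disease from
wearable neuromuscular recordings.

Patients on long-term Levodopa fluctuate between an **ON** phase (drug
benefit, session recorded *post* administration) and an **OFF** phase
(symptom reappearance, recorded *pre* administration). `wotrack`
implements a desk-scale version of a wearable WO tracker: from bilateral
lower-limb surface EMG (8 channels: left/right Lateral Gastrocnemius,
Tibialis Anterior, Biceps Femoris, Rectus Femoris) and 7-channel EEG
(T3, C3, Cz, C4, T4, P3, P4), all sampled at 500 Hz, it discriminates
OFF from ON *per walking step*.

Because clinical recordings of this kind are not publicly deposited, the
package ships a calibrated synthetic-session generator whose per-stride
statistics reproduce the published pre/post-Levodopa populations, and the
whole pipeline is validated against that generator's ground truth.

## The pipeline

1. **Trigger generation** — each sEMG channel is reduced to a 1-bit
   trigger (1 = contracted). A mean-square envelope (50 ms window) feeds a
   double-threshold state machine with an adaptive baseline
   (`ON: env > mu_b + 3 sigma_b`, `OFF: env < mu_b + 1.5 sigma_b`,
   baseline tracked over the last 2 s of relaxed samples), debounced at
   30 ms, then each burst edge is relocalized by a least-squares fit of a
   ramp-edge power model so that averaged durations are unbiased.
2. **Muscular indexes** — strides run between successive LG onsets (foot
   strike). Per stride and leg: stride time, per-muscle
   contraction/relaxation times and duty cycles
   `DC = contraction / stride time x 100`, and the co-contraction times of
   the antagonist pairs LG–TA and RF–BF. All durations sit on the 2 ms
   sample grid.
3. **MRP features** (optional EEG branch) — a 256-sample FIFO per EEG
   channel is analysed by STFT at each LG onset; per channel the maximum
   spectral magnitude in the Bereitschaftspotential (2–5 Hz), mu (9–11 Hz)
   and beta (12–30 Hz) bands is reported in dB re 1 uV.
4. **Feature selection** — paired t-tests (alpha = 0.05) between the pre
   and post populations of every feature. Muscular features separate the
   conditions; cortical ones do not, so the deployed branch is EMG-only.
5. **Classification** — eight reference configurations: decision tree
   (Gini, ≤129 splits), quadratic discriminant, linear SVM, KNN (k = 21,
   city-block), and four small dense networks (batch-norm input, 1–3
   hidden layers of 32 units, sigmoid output) with an in-package
   forward/backward engine (Nadam/RMSProp, binary cross-entropy) and
   MACC/ROM/RAM complexity accounting.
6. **Evaluation** — confusion matrix with positive class = pre-Levodopa
   (OFF), accuracy/recall/precision/F1/specificity in percent, ROC, AUC,
   and the operating point closest to {FPR, TPR} = {0, 1}.

## Worked example

```sh
python examples/train_and_evaluate.py
```

simulates the full study layout — three training subjects and two
held-out test subjects, two sessions each (pre/post), 8 runs x 150 steps
per session — then trains the single-hidden-layer network (DNN4) and
evaluates it on the unseen subjects:

```
dataset: {'train': {'pre': 3600, 'post': 3600}, 'test': {'pre': 2400, 'post': 2400}}

held-out test performance (positive class = pre-Levodopa / OFF):
  accuracy     74.52 %
  recall       70.58 %   (OFF strides caught)
  precision    76.62 %   (OFF calls that are right)
  F1           73.48 %
  specificity  78.46 %
  AUC         0.825

deployment cost: 317 parameters, 303 MACC/inference, 1268 B ROM, 188 B RAM
```

Accuracy well above chance on subjects never seen in training shows the
muscular indexes carry a generalizable ON/OFF signature; the absolute
level reflects the synthetic cohort, not any clinical dataset.
`examples/simulate_and_detect.py` (signal-level parameter recovery) and
`examples/feature_selection.py` (the muscular-vs-cortical selection
pattern) walk through the earlier stages the same way.

The same stages are scriptable from a shell:

```sh
wotrack simulate --condition pre --n-strides 75 --seed 1 --out run0
wotrack binarize --in run0 --out run0/triggers.csv
wotrack features --session run0 --triggers run0/triggers.csv --out run0/features.csv
wotrack pipeline --seed 1 --models dnn4 --out results/
```

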