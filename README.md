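# corticlass

EEG depression-classification pipeline operating in cortical source space:

1. **synthetic** — lead-field generation and labeled multi-subject EEG
   simulation with controlled class imbalance and per-subject domain shift
   (label convention: 0 = depressed, 1 = healthy control).
2. **preprocessing** — 50 Hz notch, 4–80 Hz band-pass, anti-aliased
   decimation, amplitude artifact flagging, per-channel z-scoring, and
   non-overlapping 2-s epoching (at most 150 epochs per subject).
3. **inverse** — Tikhonov minimum-norm estimation
   `J = K^T (K K^T + alpha I)^(-1) Phi` with sLORETA standardization
   (division by the model-implied source standard deviation) and ROI
   averaging over a 68-label bilateral Desikan–Killiany parcellation.
4. **features** — per band (theta 4–8, alpha 8–13, beta 13–30, gamma
   30–80 Hz): clustering coefficient and local efficiency on the binarized
   phase-locking-value graph, absolute peak, skewness, Welch band power and
   relative power, sample entropy, and fuzzy entropy — a `[N x 32]` feature
   matrix per epoch.
5. **model** — a 4-layer multi-head self-attention feature enhancer
   (residual + ReLU, shape-preserving), Pearson-threshold adjacency
   (`phi = 0.3`) with symmetric `D^(-1/2)(A+I)D^(-1/2)` normalization,
   2-layer graph convolution, mean-pool classifier head, and a domain
   discriminator behind a gradient-reversal layer. Implemented on a small
   numpy reverse-mode autodiff engine (no GPU framework required).
6. **training** — focal loss with class-balancing weights, adversarial
   domain cross-entropy through the gradient-reversal layer, center loss
   with EMA class centers, joint objective
   `L = L_focal + gamma_c * L_center - lambda * L_adv`, Adam, subject-wise
   stratified splits, early stopping, and the S1–S8 ablation grid
   (CFE / FA / FADA toggles).

Everything runs on synthetic data; no external recordings are needed.

## CLI

```sh
corticlass simulate   --config cfg.yaml --out data/
corticlass preprocess --in data/ --out epochs/ --notch 50 --band 4 80 --rate 250
corticlass train      --config cfg.yaml --data data/ --out run/
corticlass ablate     --config cfg.yaml --data data/ --out ablation.csv
```

`cfg.yaml` sections: `synthetic` (subject counts, channels, sources, ROIs,
rate, duration, noise/effect/shift scales, seed), `preprocess`, and `train`
(batch size 16, learning rate 5e-5, 70 epochs, patience 15, dropout 0.3,
Adam, 4 attention heads, hidden dimension 512 by default; tests use smaller
settings). Training writes `history.jsonl` (per-epoch loss components and
validation accuracy), `checkpoint.npz`, `metrics.csv`, and `confusion.csv`.

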