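# somnoseq

Multi-class sleep staging from wearable-grade inputs: per-epoch activity
counts plus two coarse cardiac channels — heart-rate mean (HRM) and
heart-rate standard deviation (HRSD) over 30-s epochs. These are the
signals a consumer wrist wearable can deliver passively, unlike the EEG
or continuous ECG that most automated staging methods assume. The package
targets three-class (wake / NREM / REM) and four-class (wake / light /
deep / REM) staging, where the four-class problem is severely imbalanced:
deep (N3, slow-wave) sleep typically covers well under 10% of a night's
epochs, yet its duration is the clinically interesting quantity.

## Model

Nights are processed as overlapping windows of L = 12 consecutive 30-s
epochs (stride 1). Each window of C standardized channels passes through
three length-preserving 1-D convolutions (kernel 9, padding 4, stride 1,
leaky ReLU) into an LSTM encoder; an LSTM decoder with multiplicative
attention over the encoder states emits a softmax stage distribution
h_θ^k(x) for every epoch of the window. Because of the stride-1 overlap,
every interior epoch is predicted 12 times; the night-level label is the
mode of those votes.

Training minimizes one of two weighted cross-entropies over M window
epochs. Inverse-frequency (IF) weighting handles mild imbalance:

    J_IF = -(1/M) Σ_m Σ_k w^k y_m^k log h_θ^k(x_m),      w^k ∝ 1/f_k

Real-world (RW) weighting additionally charges for false positives,
which is what stops the minority deep-sleep class being over-predicted:

    J_RW = -(1/M) Σ_m [ Σ_k w_fn^k y_m^k log h_θ^k(x_m)
                        + Σ_k Σ_{l≠k} w_fp^{kl} y_m^k log(1 − h_θ^l(x_m)) ]

with w_fn^k = 1/f_k and w_fp^{kl} = sqrt((1/f_k)(1/f_l)) off the
diagonal (zero diagonal). Optimization uses Adam, learning rate 0.00015,
batch size 50, validation-based snapshot selection; transfer learning
fine-tunes all parameters at 0.00001. The network and its gradients are
implemented in NumPy via a small reverse-mode autodiff core
(`somnoseq.autograd`), verified against finite differences.

The package also implements the surrounding pipeline: R-point trains to
per-epoch HRM/HRSD with artifact correction (intervals < 0.33 s replaced
by the midpoint with their predecessor; intervals > 1.33 s split into
round(T/T_mean) equal chunks) and per-epoch 2-SD outlier rejection; 60-s
activity upsampling; z-axis accelerometry to counts; cross-correlation
channel alignment; clinical sleep metrics (efficiency, onset latency by
the three-consecutive-epoch rule, fragmentation, sleep transition index,
per-stage times/fractions); and a Markov-chain night simulator with
stage-conditional emissions so everything is testable without cohort
access.

## Worked example

`examples/simulate_and_stage.py` simulates 12 labeled three-class nights
with well-separated stage emissions, trains a reduced model (hidden 16,
10 optimization epochs) and stages the two held-out nights:

```
train loss: 0.791 -> 0.314 over 10 optimization epochs

column-normalized confusion (%, columns = true stage):
             W    NREM     REM
pred    W    95.6    14.3     1.9
pred NREM     2.2    84.1     5.8
pred  REM     2.2     1.6    92.3

overall accuracy   0.894
macro sensitivity  0.907
weighted F1        0.894
macro MCC          0.836
```

Each confusion column sums to 100%; the diagonal is per-stage
sensitivity (chance level would be 33.33% for three classes). Macro
sensitivity averages the diagonal; weighted F1 and the one-vs-rest
macro MCC summarize precision/recall balance under imbalance. Other
examples cover the R-peak correction rules
(`rpeak_preprocessing.py` — correction roughly halves the HRM error on a
night with 2% detection artifacts), the clinical-metric summary of a
night (`clinical_summary.py`) and the IF/RW weight constructions
(`loss_weighting.py`).

A thin CLI wraps the same library end to end:

```sh
somnoseq simulate --subjects 6 --epochs 960 --scheme three --seed 1 --out data/
somnoseq train --config run.yaml
somnoseq predict --checkpoint run/model.npz --table data/epochs.csv \
    --scheme three --out pred.txt
somnoseq evaluate --pred pred.txt --truth truth.txt --scheme three --out metrics.json
```

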