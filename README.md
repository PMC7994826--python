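# tftslstm

Classification of univariate physiological time series (ECG rhythms, gait
force signals, and similar) by **time–frequency / time–space feature
sequences** fed to a **bidirectional LSTM**.

Long recurrent networks train poorly and slowly on raw physiological
records thousands of samples long. This package instead splits each record
of length L into M = ⌈L/128⌉ segments and reduces every segment to four
complementary scalars:

| feature | domain | definition |
|---|---|---|
| IF | time–frequency | spectral centroid Σ f_j P_j / Σ P_j of the Kaiser-windowed periodogram P_j = \|Σ_k w_k x_k e^{−i2πjk/N}\|²/(WN), f ∈ [0, fs/2] |
| SE | time–frequency | Shannon entropy −Σ p_j log₂ p_j of the normalized spectrum p_j = P_j/ΣP_j |
| E_FRI | time–space | Shannon entropy of the 256-level gray histogram of the fuzzy recurrence plot |
| E_FR | time–space | De Luca–Termini entropy Σ_ij[−μ log₂ μ − (1−μ) log₂(1−μ)] of the fuzzy recurrence plot |

The fuzzy recurrence plot (FRP) is built by time-delay embedding
(d = 1, φ = 1 by default), fuzzy c-means clustering (c = 3) of the
phase-space vectors, and the max–min composition
R(i,j) = max_q min(μ_iq, μ_jq) with unit diagonal — a grayscale
generalization of the binary recurrence plot.

The resulting M × 4 sequence (for a 1280-sample record: 10 × 4 instead of
1280 × 1) is standardized and classified by a bi-LSTM (hidden size 100,
Adam, lr 0.01, gradient-norm clipping at 1, ≤ 80 epochs) under grouped,
stratified tenfold cross-validation with fold-local class balancing. The
library also prepares data the same way end to end: modal-length
equalization, cyclic minority-class repetition, per-split standardization.

## Worked example

```python
import tftslstm as tl

# two-class synthetic dataset: noisy sinusoids vs Lorenz chaos, z-scored
bench = tl.run_synthetic_benchmark(seed=1)
print(bench.summary())
```

```
Synthetic benchmark: 200 records of length 1280

TF-TS feature sequences:
10-fold cross-validation
==============================================================================
           ACC             SEN             SPE             PRE              F1
 1.0000±0.0000   1.0000±0.0000   1.0000±0.0000   1.0000±0.0000   1.0000±0.0000
training time: 0.05 min total, 0.072 s/epoch

Raw-signal sequences (same network, same epoch budget):
10-fold cross-validation
==============================================================================
           ACC             SEN             SPE             PRE              F1
 0.7700±0.1457   0.7600±0.2366   0.7800±0.3155   0.8439±0.1855   0.7570±0.1759
epoch-time ratio (raw / features): 133.9x
```

Reading this: each column is an evaluation metric (accuracy, sensitivity,
specificity, precision, F1) reported as mean ± sd over the ten folds. The
feature pipeline classifies the chaotic class perfectly, while the same
network given the raw 1280-step signals under the same 4-epoch budget
reaches 77 % accuracy and needs two orders of magnitude more wall time per
epoch — the compression is what makes the recurrent classifier practical.

The same experiment from the shell:

```bash
tftslstm simulate --out data --seed 1 --n-per-class 20
tftslstm extract  --manifest data/manifest.csv --out features.csv
tftslstm cv       --manifest data/manifest.csv --out report --seed 1
tftslstm frp-image --manifest data/manifest.csv --record-id chaotic-0000 --out frp.png
```

`cv` writes `folds.csv` (source-record fold map), `features.csv`,
`metrics.csv` (per-fold + mean/sd) and `report.txt`. Real data come in
through the same manifest layout (one CSV per record, one sample per row)
or, for PhysioNet-style downloads, `tftslstm.io.read_wfdb_record`.

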