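# affectpath

Joint prediction of **where a user will check in next and how they will
feel there**, from geotagged social-media posts whose images carry
per-image (valence, intensity) emotion readings.

Emotion has strong spatio-temporal structure: people express different
emotional states in different places, and the sequence of
(place, emotion) visits is predictable. `affectpath` implements the
full modelling chain for researchers in affective computing and urban
behaviour analysis:

1. **Stay areas** — density-peak clustering discretises unevenly dense
   check-in points into `n` stay areas `C_i` (Gaussian-kernel density
   `ρ`, separation `δ` to the nearest denser point, centers by largest
   `γ = ρ·δ`, labels propagated downhill, low-density noise filtered).
2. **Emotional quadrants** — a post's readings are summed,
   `dimension = Σ_i (x_i, y_i)`, and classified into a quadrant `E_i`
   of the Russell valence/arousal circumplex (I: +/+, II: −/+,
   III: −/−, IV: +/−; axis ties count as "low").
3. **Emotional interaction graph** — each user's chronological walk
   over vertices `V_i = (C_i, E_i)` contributes directed edges with
   time-decayed weights `g(Δt) = σ(T_max / (α·Δt))`, accumulated over
   all users (`T_max` = that user's largest inter-post gap, `α = 10`).
4. **Graph embedding** — LINE-style first+second-order embedding
   minimises the out-degree-weighted KL divergence between empirical
   and model transition distributions, giving each vertex a vector
   `u_i`; a user's history becomes the trajectory matrix
   `F_k = [u_1 … u_{m−1}]`.
5. **Predictor** — sinusoidal positional encoding, multi-head scaled
   dot-product attention `softmax(QKᵀ/√d_k)V` and a BiLSTM read the
   encoded sequence in parallel; their final states feed a shared
   trunk with two softmax heads (next area, next quadrant), trained
   with summed cross-entropies `L = −(1/N) Σ_i Σ_c y_ic log p_ic`.

A seeded synthetic world generator (first-order Markov chain over
(area, quadrant) states with known stationary law and Bayes-optimal
accuracy) provides ground truth for end-to-end validation; see
`docs/methods.md` for the model details and design choices.

The sequence model runs on a small numpy reverse-mode autodiff engine
(`affectpath.autodiff`), verified against finite differences — no deep
learning framework is required.

## Worked example

```python
from affectpath import run_pipeline

config = {
    "simulate": {"n_areas": 20, "n_users": 200},     # synthetic world
    "cluster":  {"n_areas": 20, "bandwidth": 500},
    "embed":    {"dim": 64, "n_samples": 200_000},
    "train":    {"epochs": 15, "max_seq_len": 10, "max_history": 10,
                 "fc_hidden": 256, "dropout": 0.3},
}
metrics = run_pipeline(config, "runs/demo", seed=1)
print(open("runs/demo/summary.txt").read())
```

prints

```
Next-visit model (attention + BiLSTM)
==============================================
samples (train/val)          4723/1212
stay-area classes            20
d_model / heads / lstm       64/4/64
trainable parameters         138264
epochs trained               15
final training loss          1.6413
----------------------------------------------
joint accuracy               0.7888
area accuracy                0.7970
quadrant accuracy            0.8564
area macro P/R/F1            0.7987/0.7789/0.7854
quadrant macro P/R/F1        0.8578/0.7954/0.8211
```

The generating chain's stickiness is 0.8, so no predictor can exceed
80% next-vertex accuracy; the held-out joint accuracy of 0.789 means
the model has essentially recovered the transition structure (the gap
to the ceiling is 0.011). The run directory also holds every
intermediate artifact: `areas.geojson`, `edges.tsv`, `emb.tsv`,
`metrics.json` (with per-quadrant and per-sequence-length accuracy),
`history.csv` and a timed log.

The same stages are available from the shell:

```bash
affectpath simulate --config world.yaml --seed 7 --out data/
affectpath cluster  --input data/checkins.csv --n-areas 100 \
                    --out areas.geojson --assignments assign.tsv
affectpath emotions --input data/checkins.csv --out labeled.tsv
affectpath graph    --input data/checkins.csv --assignments assign.tsv \
                    --labeled labeled.tsv --alpha 10 --out edges.tsv
affectpath embed    --edges edges.tsv --dim 64 --order both \
                    --samples 100000 --seed 7 --out emb.tsv
affectpath run      --config pipeline.yaml --seed 7 --out runs/demo
```

Real data enters through `read_checkins` (CSV with configurable column
names; ISO-8601 or `Fri Jan 01 05:09:23 +0800 2021`-style timestamps).

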