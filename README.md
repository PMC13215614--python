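# gxenet

Attention-based graph neural networks with LSTM weather encoding for
genotype-by-environment (G×E) maize yield prediction, plus the full data
preparation and evaluation protocol and a synthetic G×E data generator so
every stage is testable without any external dataset.

## What it does

- **`gxenet.synthetic`** — generates G2F-shaped synthetic datasets: a
  `{-1,0,+1}` SNP matrix with missingness, planted near-constant and
  near-duplicate marker columns, latent population structure, daily weather
  series of variable season length (with recorded heat-wave events), and
  replicated plot yields with additive genotype, additive environment,
  multiplicative interaction and noise components. Ground truth is emitted
  alongside so every simulated yield can be recomputed exactly.
- **`gxenet.genotype`** — SNP-matrix compression: per-column probabilistic
  imputation, a 95%-modal low-variance filter, windowed similarity pruning
  (one representative per ≥95%-identical group within disjoint windows of
  width `L`), and PCA fitted on training hybrids only (components up to a
  target explained-variance fraction, default 90%).
- **`gxenet.weather`** — a single-layer unidirectional LSTM that folds each
  environment's z-scored daily `k × 5` weather matrix (PAR, max/min
  temperature, precipitation, direct-normal irradiance) into a fixed-length
  embedding `z_env` (default m = 21), plus a validation sweep over the
  candidate grid `{6, 9, ..., 50}`.
- **`gxenet.graphs`** — per-sample block graphs over n genotype-component
  nodes and m environment-feature nodes: architecture A is the fully
  connected bipartite graph (both directions); B and C add directed
  intra-set top-k similarity edges (`s(u, v) = 1 / (1 + |x_u − x_v|)`,
  default k = 10).
- **`gxenet.nn`** — multi-head scaled dot-product attention message passing
  over the in-neighborhoods, residual + layer norm per round, K rounds with
  tied parameters (default K = 30, d = 128, 8 heads), then either mean‖max
  pooling over genotype nodes (A/B) or a learnable supernode query attending
  separately over genotype and environment nodes (C); a 2d → 128 → 64 → 1
  MLP head maps the readout to yield.
- **`gxenet.train`** — forward-time splitting (development years strictly
  before the test year; 80/20 train/validation grouped by (hybrid,
  environment) pair), the combined loss `λ·MSE + (1−λ)·MAE` with λ = 0.8,
  AdamW (lr 3e-4, weight decay 1e-4) with early stopping on validation RMSE,
  and diagnostics: RMSE/PCC/R², per-environment reports with the
  PCC ~ genotype-count slope, and a weather-feature PCA map of environments.

Training runs on a small built-in numpy autograd engine
(`gxenet._autodiff`), so there is no deep-learning framework dependency;
everything is CPU-only and fully deterministic under a fixed seed.

## CLI

```bash
gxenet simulate --seed 1 --out-dir data/            # synthetic dataset
gxenet prep-geno --genotypes data/genotypes.tsv \
    --phenotypes data/phenotypes.tsv --out emb.tsv  # impute/filter/prune/PCA
gxenet sweep-m --weather data/weather.tsv \
    --phenotypes data/phenotypes.tsv --out sweep.tsv
gxenet split --phenotypes data/phenotypes.tsv --test-year 2021 --out split.tsv
gxenet train --arch C --genotypes data/genotypes.tsv \
    --weather data/weather.tsv --phenotypes data/phenotypes.tsv \
    --out-prefix runs/model                          # checkpoint + metrics
gxenet predict --checkpoint runs/model ... --out preds.tsv
gxenet evaluate --predictions eval.tsv
gxenet report-env --predictions eval.tsv --out env_report.tsv
```

`gxenet train` accepts a YAML config mirroring the training defaults
(batch size 32, 100 epochs, K = 30, k = 10, d = 128, 8 heads, lr 3e-4,
weight decay 1e-4, λ = 0.8).

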