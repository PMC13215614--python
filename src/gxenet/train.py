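"""Forward-time splitting, combined loss, optimization loop, diagnostics.

Training minimizes ``lambda * MSE + (1 - lambda) * MAE`` with AdamW,
early-stops on validation RMSE and restores the best-epoch weights.
Splits honor the forward-time protocol: the test year is strictly later
than every development year, and the 80/20 train/validation partition
never places the same (hybrid, environment) pair on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from ._autodiff import AdamW, Tensor, concat
from .genotype import GenotypeEmbedding
from .nn import GxEModel
from .weather import (EnvironmentSeries, NormalizationStats, fit_normalization,
                      pad_series)

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec", "TrainConfig", "Metrics", "GxEDataset", "TrainedPredictor",
    "forward_time_split", "train_val_partition", "make_split",
    "combined_loss", "evaluate", "train_model",
    "per_environment_report", "environment_pca_map",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitSpec:
    train_keys: set                # {(hybrid_id, env_id)}
    val_keys: set
    test_keys: set
    key_year: dict                 # (hybrid_id, env_id) -> year

    def validate(self) -> None:
        if self.train_keys & self.val_keys or self.train_keys & self.test_keys \
                or self.val_keys & self.test_keys:
            raise ValueError("split key sets overlap")
        dev_years = {self.key_year[k] for k in self.train_keys | self.val_keys}
        test_years = {self.key_year[k] for k in self.test_keys}
        if dev_years and test_years and min(test_years) <= max(dev_years):
            raise ValueError("test years must be strictly after development years")


def forward_time_split(phenotypes: pd.DataFrame, test_year) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All records at ``test_year`` become the test set; earlier records form
    the development pool.  Records after the test year are an error."""
    years = phenotypes["year"]
    if not (years == test_year).any():
        raise ValueError(f"test year {test_year} not present in phenotype table")
    if (years > test_year).any():
        raise ValueError("records after the test year make the protocol ambiguous")
    test = phenotypes[years == test_year].copy()
    pool = phenotypes[years < test_year].copy()
    return pool, test


def train_val_partition(
    pool: pd.DataFrame, frac: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group records by (hybrid, env) pair and assign whole groups to
    train or validation; group-count proportions within one group of frac."""
    keys = list(pool.groupby(["hybrid_id", "env_id"], sort=True).groups)
    if len(keys) < 2:
        raise ValueError("need at least 2 distinct (hybrid, env) pairs to partition")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    n_train = int(round(frac * len(keys)))
    n_train = min(max(n_train, 1), len(keys) - 1)
    train_keys = {keys[i] for i in order[:n_train]}
    pair = list(zip(pool["hybrid_id"], pool["env_id"]))
    in_train = np.array([p in train_keys for p in pair])
    return pool[in_train].copy(), pool[~in_train].copy()


def make_split(phenotypes: pd.DataFrame, test_year, frac: float = 0.8,
               seed: int = 0) -> SplitSpec:
    pool, test = forward_time_split(phenotypes, test_year)
    train, val = train_val_partition(pool, frac=frac, seed=seed)
    as_keys = lambda df: set(zip(df["hybrid_id"], df["env_id"]))
    key_year = dict(zip(zip(phenotypes["hybrid_id"], phenotypes["env_id"]),
                        phenotypes["year"]))
    spec = SplitSpec(train_keys=as_keys(train), val_keys=as_keys(val),
                     test_keys=as_keys(test), key_year=key_year)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# loss and metrics
# ---------------------------------------------------------------------------

def combined_loss(pred: np.ndarray, truth: np.ndarray, lam: float = 0.8) -> float:
    """lambda * MSE + (1 - lambda) * MAE."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be nonempty and equal-length")
    if not 0 <= lam <= 1:
        raise ValueError("lambda must be in [0, 1]")
    err = pred - truth
    return float(lam * np.mean(err**2) + (1 - lam) * np.mean(np.abs(err)))


def _combined_loss_t(pred: Tensor, truth: np.ndarray, lam: float) -> Tensor:
    err = pred - Tensor(truth)
    return lam * (err**2).mean() + (1 - lam) * err.abs().mean()


@dataclass
class Metrics:
    rmse: float
    pcc: float
    r2: float
    n: int


def evaluate(preds: np.ndarray, truths: np.ndarray) -> Metrics:
    """RMSE, Pearson correlation and R^2 = 1 - SSE/SST."""
    preds = np.asarray(preds, dtype=np.float64)
    truths = np.asarray(truths, dtype=np.float64)
    if preds.shape != truths.shape or preds.size < 2:
        raise ValueError("need >= 2 aligned predictions")
    if np.std(truths) < 1e-12:
        raise ValueError("constant truths: PCC undefined")
    rmse = float(np.sqrt(np.mean((preds - truths) ** 2)))
    pcc = float(pearsonr(preds, truths).statistic)
    sst = float(np.sum((truths - truths.mean()) ** 2))
    r2 = float(1.0 - np.sum((preds - truths) ** 2) / sst)
    return Metrics(rmse=rmse, pcc=pcc, r2=r2, n=int(preds.size))


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class GxEDataset:
    """Everything the trainer consumes: per-hybrid PC scores, per-environment
    weather series, and the phenotype table."""

    embedding: GenotypeEmbedding
    env_series: dict               # env_id -> EnvironmentSeries
    phenotypes: pd.DataFrame

    def __post_init__(self):
        self._hybrid_row = {h: i for i, h in enumerate(self.embedding.hybrid_ids)}
        missing_h = set(self.phenotypes["hybrid_id"]) - set(self._hybrid_row)
        missing_e = set(self.phenotypes["env_id"]) - set(self.env_series)
        if missing_h or missing_e:
            raise ValueError(f"phenotypes reference unknown hybrids {sorted(missing_h)[:5]}"
                             f" / environments {sorted(missing_e)[:5]}")

    @property
    def n_components(self) -> int:
        return self.embedding.scores.shape[1]

    def scores_for(self, hybrid_ids) -> np.ndarray:
        rows = [self._hybrid_row[h] for h in hybrid_ids]
        return self.embedding.scores[rows]

    def records_for(self, keys: set) -> pd.DataFrame:
        pair = list(zip(self.phenotypes["hybrid_id"], self.phenotypes["env_id"]))
        sel = np.array([p in keys for p in pair])
        return self.phenotypes[sel].copy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 100
    K: int = 30                    # message-passing rounds
    k: int = 10                    # intra-set out-degree (B/C)
    d: int = 128                   # hidden dim
    n_heads: int = 8
    m: int = 21                    # environment embedding dim
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    lam: float = 0.8
    patience: int = 10
    seed: int = 0
    head_dims: tuple = (128, 64)
    clip_norm: float = 5.0
    average_replicates: bool = False

    def __post_init__(self):
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must be in [0, 1]")
        for name in ("batch_size", "epochs", "K", "d", "n_heads", "m", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedPredictor:
    """A trained model bundled with the preprocessing state it was fit with."""

    model: GxEModel
    stats: NormalizationStats
    pc_scale: np.ndarray           # per-component divisor applied to PC scores

    def encode_envs(self, series: list[EnvironmentSeries]) -> np.ndarray:
        padded, lengths = pad_series(series, self.stats)
        return self.model.lstm.encode_batch(padded, lengths).data

    def predict(self, dataset: GxEDataset, records: pd.DataFrame,
                batch_size: int = 512) -> np.ndarray:
        env_ids = sorted(records["env_id"].unique())
        z = self.encode_envs([dataset.env_series[e] for e in env_ids])
        z_by_env = dict(zip(env_ids, z))
        pc = dataset.scores_for(records["hybrid_id"]) / self.pc_scale
        ze = np.stack([z_by_env[e] for e in records["env_id"]])
        values = np.concatenate([pc, ze], axis=1)
        preds = []
        for lo in range(0, values.shape[0], batch_size):
            chunk = values[lo:lo + batch_size]
            masks = self.model.build_masks(chunk)
            preds.append(self.model.forward_values(Tensor(chunk), masks).data)
        return np.concatenate(preds)


def _clip_gradients(params: list[Tensor], max_norm: float) -> None:
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train_model(
    arch: str,
    data: GxEDataset,
    split: SplitSpec,
    cfg: TrainConfig,
) -> tuple[TrainedPredictor, pd.DataFrame]:
    """Mini-batch AdamW on the combined loss with early stopping on
    validation RMSE; returns the best-epoch predictor and the per-epoch
    history (train loss, validation RMSE/PCC)."""
    split.validate()
    train_rec = data.records_for(split.train_keys)
    val_rec = data.records_for(split.val_keys)
    if train_rec.empty or val_rec.empty:
        raise ValueError("train and validation sets must be nonempty")
    if cfg.average_replicates:
        train_rec = (train_rec.groupby(["hybrid_id", "env_id", "year"], as_index=False)
                     ["yield_mg_ha"].mean())

    train_envs = sorted(train_rec["env_id"].unique())
    stats = fit_normalization([data.env_series[e] for e in train_envs])

    train_hybrids = sorted(train_rec["hybrid_id"].unique())
    pc_train = data.scores_for(train_hybrids)
    pc_scale = np.maximum(pc_train.std(axis=0), 1e-8)

    model = GxEModel(arch, n_geno=data.n_components, n_env=cfg.m, d=cfg.d,
                     n_heads=cfg.n_heads, K=cfg.K, k_intra=cfg.k,
                     head_dims=tuple(cfg.head_dims), lstm_m=cfg.m, seed=cfg.seed)
    model.out_bias.data[:] = float(train_rec["yield_mg_ha"].mean())
    predictor = TrainedPredictor(model=model, stats=stats, pc_scale=pc_scale)
    opt = AdamW(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)

    # pre-normalized weather tensors, padded once
    all_envs = sorted(set(train_rec["env_id"]) | set(val_rec["env_id"]))
    padded, lengths = pad_series([data.env_series[e] for e in all_envs], stats)
    env_row = {e: i for i, e in enumerate(all_envs)}

    pc_all = {h: data.scores_for([h])[0] / pc_scale
              for h in set(train_rec["hybrid_id"]) | set(val_rec["hybrid_id"])}

    t_hyb = train_rec["hybrid_id"].to_numpy()
    t_env = train_rec["env_id"].to_numpy()
    t_y = train_rec["yield_mg_ha"].to_numpy()
    val_y = val_rec["yield_mg_ha"].to_numpy()

    rng = np.random.default_rng(cfg.seed)
    history = []
    best_rmse = np.inf
    best_state = model.state()
    best_epoch = 0
    stale = 0
    n_train = len(t_y)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for lo in range(0, n_train, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            envs_b = sorted(set(t_env[idx]))
            rows = np.array([env_row[e] for e in envs_b])
            z = model.lstm.encode_batch(padded[rows], lengths[rows])   # (E, m)
            pos = {e: i for i, e in enumerate(envs_b)}
            z_rec = z[np.array([pos[e] for e in t_env[idx]])]          # (B, m)
            pc = np.stack([pc_all[h] for h in t_hyb[idx]])             # (B, n)
            values = concat([Tensor(pc), z_rec], axis=1)
            masks = model.build_masks(values.data)
            pred = model.forward_values(values, masks)
            loss = _combined_loss_t(pred, t_y[idx], cfg.lam)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            if cfg.clip_norm:
                _clip_gradients(opt.params, cfg.clip_norm)
            opt.step()
            epoch_losses.append(loss.item())

        val_pred = predictor.predict(data, val_rec)
        val_m = evaluate(val_pred, val_y)
        history.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                        "val_rmse": val_m.rmse, "val_pcc": val_m.pcc})
        if val_m.rmse < best_rmse - 1e-9:
            best_rmse = val_m.rmse
            best_state = model.state()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    model.load_state(best_state)
    return predictor, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def per_environment_report(preds: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-environment metrics and the slope of PCC ~ genotype count.

    ``preds`` needs columns env_id, hybrid_id, y_true, y_pred.  Environments
    with constant truths (or < 2 records) are skipped with a warning.
    """
    rows = []
    for env_id, grp in preds.groupby("env_id", sort=True):
        if len(grp) < 2 or np.std(grp["y_true"]) < 1e-12:
            logger.warning("environment %s skipped (constant or singleton truths)", env_id)
            continue
        m = evaluate(grp["y_pred"].to_numpy(), grp["y_true"].to_numpy())
        rows.append({"env_id": env_id, "n_genotypes": grp["hybrid_id"].nunique(),
                     "pcc": m.pcc, "rmse": m.rmse})
    table = pd.DataFrame(rows)
    slope = float("nan")
    if len(table) >= 2 and table["n_genotypes"].nunique() > 1:
        slope = float(np.polyfit(table["n_genotypes"], table["pcc"], 1)[0])
    elif len(table) >= 2:
        slope = 0.0
    return table, slope


def _season_aggregates(series: list[EnvironmentSeries]) -> np.ndarray:
    """Per-environment per-variable season mean, min and max."""
    return np.array([
        np.concatenate([s.values.mean(axis=0), s.values.min(axis=0), s.values.max(axis=0)])
        for s in series
    ])


def environment_pca_map(series: list[EnvironmentSeries], pcc_by_env: dict) -> pd.DataFrame:
    """Project environments onto the first two PCs of aggregated weather
    features, annotated with each environment's mean PCC."""
    if len(series) < 3:
        raise ValueError("need at least 3 environments for the PCA map")
    agg = _season_aggregates(series)
    centered = agg - agg.mean(axis=0)
    if np.allclose(centered, 0):
        coords = np.zeros((len(series), 2))
    else:
        coords = PCA(n_components=2).fit_transform(agg)
    return pd.DataFrame({
        "env_id": [s.env_id for s in series],
        "pc1": coords[:, 0],
        "pc2": coords[:, 1],
        "pcc": [pcc_by_env.get(s.env_id, np.nan) for s in series],
    })
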