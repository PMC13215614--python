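"""Season-long weather encoding with a single-layer unidirectional LSTM.

Each environment's daily records (k days x 5 variables) are z-scored
with training statistics and folded through the LSTM from zero initial
states; the final hidden state is the environment embedding ``z_env``.
An embedding-dimension sweep trains an environment-only yield head per
candidate m and reports validation Pearson correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from ._autodiff import AdamW, Tensor, concat

logger = logging.getLogger(__name__)

WEATHER_VARIABLES = [
    "par_total",          # all-sky surface PAR total
    "tmax_2m",            # maximum temperature at 2 m
    "tmin_2m",            # minimum temperature at 2 m
    "precip_corrected",   # corrected precipitation
    "swdni",              # shortwave direct-normal irradiance
]
N_VARIABLES = len(WEATHER_VARIABLES)

#: candidate embedding dimensions for the validation sweep
DEFAULT_M_CANDIDATES = [6, 9, 12, 15, 18, 21, 24, 27, 30, 35, 40, 45, 50]

#: embedding dimension used downstream by default
DEFAULT_M = 21

__all__ = [
    "WEATHER_VARIABLES", "DEFAULT_M", "DEFAULT_M_CANDIDATES",
    "EnvironmentSeries", "LSTMParams", "EnvironmentEmbedding", "NormalizationStats",
    "fit_normalization", "lstm_step", "encode_season", "init_lstm_params",
    "LSTMEncoder", "pad_series", "sweep_embedding_dim",
]


@dataclass
class EnvironmentSeries:
    """One environment's ordered daily weather records."""

    env_id: str
    dates: list
    values: np.ndarray             # (k, 5)
    heatwave_days: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != N_VARIABLES:
            raise ValueError(f"expected (k, {N_VARIABLES}) values")
        if self.values.shape[0] < 1 or len(self.dates) != self.values.shape[0]:
            raise ValueError("dates and values must align, k >= 1")
        stamps = pd.to_datetime(pd.Series(self.dates))
        if not stamps.is_monotonic_increasing or stamps.duplicated().any():
            raise ValueError("dates must be strictly increasing")

    @property
    def n_days(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizationStats:
    mean: np.ndarray               # (5,)
    std: np.ndarray                # (5,), floored at 1e-8

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std


@dataclass
class LSTMParams:
    """Gate parameters: W_* input (m x 5), U_* recurrent (m x m), b_* bias (m,)."""

    W_i: np.ndarray; U_i: np.ndarray; b_i: np.ndarray
    W_f: np.ndarray; U_f: np.ndarray; b_f: np.ndarray
    W_o: np.ndarray; U_o: np.ndarray; b_o: np.ndarray
    W_c: np.ndarray; U_c: np.ndarray; b_c: np.ndarray
    m: int

    def __post_init__(self):
        for g in "ifoc":
            W, U, b = getattr(self, f"W_{g}"), getattr(self, f"U_{g}"), getattr(self, f"b_{g}")
            if W.shape != (self.m, N_VARIABLES) or U.shape != (self.m, self.m) or b.shape != (self.m,):
                raise ValueError(f"inconsistent shapes for gate {g}")
            if not (np.isfinite(W).all() and np.isfinite(U).all() and np.isfinite(b).all()):
                raise ValueError(f"non-finite parameters in gate {g}")


@dataclass
class EnvironmentEmbedding:
    env_id: str
    z_env: np.ndarray

    def __post_init__(self):
        self.z_env = np.asarray(self.z_env, dtype=np.float64)
        if not np.isfinite(self.z_env).all():
            raise ValueError("embedding must be finite")


def fit_normalization(train_series: list[EnvironmentSeries]) -> NormalizationStats:
    """Per-variable mean/std pooled over all training days (std floored at 1e-8)."""
    if not train_series:
        raise ValueError("need at least one training series")
    pooled = np.vstack([s.values for s in train_series])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 total days to fit normalization")
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    if (std < 1e-8).any():
        constant = [WEATHER_VARIABLES[i] for i in np.flatnonzero(std < 1e-8)]
        logger.warning("constant weather variable(s) %s: std floored at 1e-8", constant)
        warnings.warn(f"constant weather variable(s) {constant}; std floored", stacklevel=2)
        std = np.maximum(std, 1e-8)
    return NormalizationStats(mean=mean, std=std)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def lstm_step(
    p: LSTMParams, x_t: np.ndarray, s_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One recurrence: input/forget/output gates, candidate cell, state update."""
    x_t = np.asarray(x_t, dtype=np.float64)
    s_prev = np.asarray(s_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x_t.shape != (N_VARIABLES,) or s_prev.shape != (p.m,) or c_prev.shape != (p.m,):
        raise ValueError("lstm_step input shape mismatch")
    i = _sigmoid(p.W_i @ x_t + p.U_i @ s_prev + p.b_i)
    f = _sigmoid(p.W_f @ x_t + p.U_f @ s_prev + p.b_f)
    o = _sigmoid(p.W_o @ x_t + p.U_o @ s_prev + p.b_o)
    c_tilde = np.tanh(p.W_c @ x_t + p.U_c @ s_prev + p.b_c)
    c_t = f * c_prev + i * c_tilde
    s_t = o * np.tanh(c_t)
    return s_t, c_t


def encode_season(
    p: LSTMParams, series: EnvironmentSeries, stats: NormalizationStats
) -> EnvironmentEmbedding:
    """Normalize, fold lstm_step over days from zero states, return final hidden state."""
    if series.n_days == 0:
        raise ValueError("empty series")
    X = stats.apply(series.values)
    s = np.zeros(p.m)
    c = np.zeros(p.m)
    for t in range(X.shape[0]):
        s, c = lstm_step(p, X[t], s, c)
    return EnvironmentEmbedding(env_id=series.env_id, z_env=s)


def init_lstm_params(m: int, seed: int, scale: float = 0.2) -> LSTMParams:
    rng = np.random.default_rng(seed)
    kw = {}
    for g in "ifoc":
        kw[f"W_{g}"] = rng.normal(0, scale, size=(m, N_VARIABLES))
        kw[f"U_{g}"] = rng.normal(0, scale / np.sqrt(m), size=(m, m))
        kw[f"b_{g}"] = np.zeros(m)
    return LSTMParams(m=m, **kw)


class LSTMEncoder:
    """Differentiable, batched counterpart of :func:`encode_season`.

    Holds the gate parameters as autograd tensors; ``encode_batch`` runs
    the recurrence over a padded batch of normalized sequences with a
    per-day validity mask so variable season lengths need no padding
    semantics beyond "frozen state after the last real day".
    """

    def __init__(self, params: LSTMParams):
        self.m = params.m
        self._t = {
            name: Tensor(getattr(params, name).copy(), requires_grad=True)
            for name in ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f",
                         "W_o", "U_o", "b_o", "W_c", "U_c", "b_c")
        }

    @classmethod
    def init(cls, m: int, seed: int) -> "LSTMEncoder":
        return cls(init_lstm_params(m, seed))

    def parameters(self) -> list[Tensor]:
        return list(self._t.values())

    def to_params(self) -> LSTMParams:
        return LSTMParams(m=self.m, **{k: v.data.copy() for k, v in self._t.items()})

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self._t[k].data = v.copy()

    def state(self) -> dict:
        return {k: v.data.copy() for k, v in self._t.items()}

    def encode_batch(self, padded: np.ndarray, lengths: np.ndarray) -> Tensor:
        """padded: (E, k_max, 5) already normalized; returns (E, m) final states."""
        E, k_max, _ = padded.shape
        p = self._t
        s = Tensor(np.zeros((E, self.m)))
        c = Tensor(np.zeros((E, self.m)))
        for t in range(k_max):
            x = Tensor(padded[:, t, :])
            i = (x @ p["W_i"].T + s @ p["U_i"].T + p["b_i"]).sigmoid()
            f = (x @ p["W_f"].T + s @ p["U_f"].T + p["b_f"]).sigmoid()
            o = (x @ p["W_o"].T + s @ p["U_o"].T + p["b_o"]).sigmoid()
            c_tilde = (x @ p["W_c"].T + s @ p["U_c"].T + p["b_c"]).tanh()
            c_new = f * c + i * c_tilde
            s_new = o * c_new.tanh()
            alive = Tensor((lengths > t).astype(np.float64)[:, None])
            s = alive * s_new + (1.0 - alive) * s
            c = alive * c_new + (1.0 - alive) * c
        return s


def pad_series(
    series: list[EnvironmentSeries], stats: NormalizationStats
) -> tuple[np.ndarray, np.ndarray]:
    """Stack normalized series into (E, k_max, 5) with zero padding + lengths."""
    lengths = np.array([s.n_days for s in series], dtype=int)
    k_max = int(lengths.max())
    padded = np.zeros((len(series), k_max, N_VARIABLES))
    for i, s in enumerate(series):
        padded[i, : s.n_days] = stats.apply(s.values)
    return padded, lengths


# ---------------------------------------------------------------------------
# embedding-dimension sweep (environment-only predictor)
# ---------------------------------------------------------------------------

def _train_env_only(
    m: int,
    series: dict,
    train_records: pd.DataFrame,
    val_records: pd.DataFrame,
    cfg: dict,
) -> float:
    """Train z_env -> MLP -> yield; return validation PCC."""
    seed = int(cfg.get("seed", 0))
    epochs = int(cfg.get("epochs", 40))
    lr = float(cfg.get("lr", 1e-2))
    hidden = int(cfg.get("hidden", 16))
    lam = float(cfg.get("lambda_", 0.8))

    train_envs = sorted(train_records["env_id"].unique())
    stats = fit_normalization([series[e] for e in train_envs])
    enc = LSTMEncoder.init(m, seed)
    rng = np.random.default_rng(seed + 1)
    W1 = Tensor(rng.normal(0, 1 / np.sqrt(m), size=(m, hidden)), requires_grad=True)
    b1 = Tensor(np.zeros(hidden), requires_grad=True)
    W2 = Tensor(rng.normal(0, 1 / np.sqrt(hidden), size=(hidden, 1)), requires_grad=True)
    b2 = Tensor(np.zeros(1), requires_grad=True)

    y_mean = float(train_records["yield_mg_ha"].mean())
    opt = AdamW(enc.parameters() + [W1, b1, W2, b2], lr=lr, weight_decay=1e-4)

    def forward(env_list: list[str]) -> Tensor:
        padded, lengths = pad_series([series[e] for e in env_list], stats)
        z = enc.encode_batch(padded, lengths)            # (E, m)
        h = (z @ W1 + b1).relu()
        pred = (h @ W2 + b2)[:, 0] + y_mean
        return pred

    def records_pred(records: pd.DataFrame, pred_by_env: dict) -> np.ndarray:
        return np.array([pred_by_env[e] for e in records["env_id"]])

    y_train_by_env = train_records.groupby("env_id")["yield_mg_ha"].mean()
    env_list = list(y_train_by_env.index)
    y_t = Tensor(y_train_by_env.to_numpy())
    for _ in range(epochs):
        pred = forward(env_list)
        err = pred - y_t
        loss = lam * (err**2).mean() + (1 - lam) * err.abs().mean()
        opt.zero_grad()
        loss.backward()
        opt.step()

    pred_env = dict(zip(env_list, forward(env_list).data))
    val_envs = sorted(set(val_records["env_id"]) - set(pred_env))
    if val_envs:
        padded, lengths = pad_series([series[e] for e in val_envs], stats)
        z = enc.encode_batch(padded, lengths)
        h = (z @ W1 + b1).relu()
        extra = (h @ W2 + b2).data[:, 0] + y_mean
        pred_env.update(dict(zip(val_envs, extra)))
    val_pred = records_pred(val_records, pred_env)
    val_true = val_records["yield_mg_ha"].to_numpy()
    if np.std(val_true) < 1e-12:
        raise ValueError("validation yields are constant; PCC undefined")
    return float(pearsonr(val_pred, val_true).statistic)


def sweep_embedding_dim(
    candidates: list[int] | None,
    train_data: tuple[pd.DataFrame, dict],
    val_data: tuple[pd.DataFrame, dict],
    trainer_config: dict | None = None,
) -> tuple[pd.DataFrame, int]:
    """Validation sweep over embedding dimensions.

    ``train_data``/``val_data`` are ``(records, series)`` pairs where
    ``records`` has columns env_id / yield_mg_ha and ``series`` maps
    env_id -> :class:`EnvironmentSeries`.  Returns the per-m table and
    the argmax m (ties -> smallest m).
    """
    if candidates is None:
        candidates = list(DEFAULT_M_CANDIDATES)
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    cfg = dict(trainer_config or {})
    train_records, train_series = train_data
    val_records, val_series = val_data
    series = {**train_series, **val_series}
    rows = []
    for m in candidates:
        pcc = _train_env_only(int(m), series, train_records, val_records, cfg)
        rows.append({"m": int(m), "val_pcc": pcc})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["val_pcc"].idxmax(), "m"])
    # ties -> smallest m
    top = table[np.isclose(table["val_pcc"], table["val_pcc"].max())]
    best = int(top["m"].min())
    return table, best
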