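"""Synthetic genotype / weather / yield data with known ground truth.

Emulates the shape of a multi-environment maize trial dataset: a
{-1,0,+1} SNP matrix with missingness, planted near-constant and
near-duplicate marker columns (targets for the filtering stages), daily
weather series of variable season length, and replicated plot yields
built from additive genotype, additive environment, multiplicative
interaction and noise components.  Every draw is derived
deterministically from ``SimConfig.seed`` so datasets regenerate
bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .weather import EnvironmentSeries, WEATHER_VARIABLES

__all__ = ["SimConfig", "GroundTruth", "simulate_genotypes", "simulate_weather",
           "simulate_yields", "simulate_dataset", "write_dataset"]


def _rng(seed: int, tag: str, index: int = 0) -> np.random.Generator:
    """Deterministic substream for one entity, independent of call order."""
    return np.random.default_rng([seed, zlib.crc32(tag.encode()), index])


@dataclass
class SimConfig:
    n_hybrids: int = 200
    n_snps: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    n_constant_cols: int = 0
    n_duplicate_pairs: int = 0
    n_envs: int = 20
    season_length_range: tuple[int, int] = (100, 140)
    n_latent_env: int = 2
    effect_variances: dict = field(default_factory=lambda: {
        "additive_g": 1.0, "additive_e": 1.0, "interaction": 0.5, "noise": 0.25})
    replicates_per_pair: int = 1
    years: tuple = (2019, 2020, 2021)
    seed: int = 0
    prune_window: int = 100       # planted duplicate pairs land inside one window
    causal_fraction: float = 0.1  # fraction of SNP columns driving the genetic score
    pairs_per_env: int | None = None  # hybrids sampled per environment (None = all eligible)
    heatwave_fraction: float = 0.5
    test_hybrid_fraction: float = 0.2
    test_env_fraction: float = 0.25
    n_latent_g: int = 4           # population-structure factors
    structure_sd: float = 0.12    # sd of the per-SNP allele-frequency shift

    def validate(self) -> None:
        if self.n_hybrids < 0 or self.n_snps < 0 or self.n_envs < 0:
            raise ValueError("counts must be >= 0")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.season_length_range[0] < 2 or self.season_length_range[0] > self.season_length_range[1]:
            raise ValueError("season lengths must be >= 2 and ordered")
        if any(v < 0 for v in self.effect_variances.values()):
            raise ValueError("effect variances must be >= 0")
        if self.n_constant_cols + 2 * self.n_duplicate_pairs > self.n_snps:
            raise ValueError("planted constant + duplicate columns exceed n_snps")
        if self.replicates_per_pair < 1:
            raise ValueError("replicates_per_pair must be >= 1")
        if len(self.years) < 1:
            raise ValueError("at least one year required")


@dataclass
class GroundTruth:
    """Everything needed to recompute every simulated yield exactly."""

    mu: float
    genetic_score: dict            # hybrid_id -> g_h
    env_score: dict                # env_id -> e_env
    gamma: float
    noise_seed: int
    causal_snp_ids: list
    causal_weights: list
    heatwave_days: dict            # env_id -> list of day indices (may be empty)
    env_year: dict                 # env_id -> year
    hybrid_year_pool: dict         # hybrid_id -> "dev" | "test"

    def expected_yield(self, hybrid_id: str, env_id: str) -> float:
        g = self.genetic_score[hybrid_id]
        e = self.env_score[env_id]
        return self.mu + g + e + self.gamma * g * e


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _modal_fraction(col: np.ndarray) -> float:
    vals = col[~np.isnan(col)]
    if vals.size == 0:
        return 1.0
    _, counts = np.unique(vals, return_counts=True)
    return counts.max() / vals.size


def _complete_genotypes(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """The true (no missingness) SNP matrix plus the latent structure factors
    (hybrids x q) and per-SNP loadings (snps x q).  Shared by genotype and
    yield sims."""
    n, p = cfg.n_hybrids, cfg.n_snps
    X = np.empty((n, p), dtype=np.float64)

    n_const = cfg.n_constant_cols
    dup_pairs = cfg.n_duplicate_pairs

    # positions: constants first, then duplicate pairs at adjacent indices that
    # never straddle a prune-window boundary, then free HW columns.
    const_idx = list(range(n_const))
    dup_idx: list[tuple[int, int]] = []
    pos = n_const
    W = max(cfg.prune_window, 2)
    for _ in range(dup_pairs):
        if pos % W == W - 1:  # pair would straddle the window edge
            pos += 1
        dup_idx.append((pos, pos + 1))
        pos += 2
    if dup_idx and dup_idx[-1][1] >= p:
        raise ValueError("not enough columns to place duplicate pairs")
    planted = set(const_idx) | {i for pair in dup_idx for i in pair}

    # population structure: latent factors shift per-hybrid allele frequencies,
    # so a linear function of causal SNPs survives PCA compression (as LD does
    # in real marker panels); marginal frequencies stay Hardy-Weinberg at the
    # drawn MAF in expectation.
    rng_u = _rng(cfg.seed, "structure")
    q = max(cfg.n_latent_g, 1)
    U = rng_u.standard_normal((n, q)) if cfg.structure_sd > 0 else np.zeros((n, q))

    rng_hw = _rng(cfg.seed, "hw-columns")
    lo, hi = cfg.maf_range
    V = np.zeros((p, q))
    for j in range(p):
        if j in planted:
            continue
        # resample until the column is not accidentally >= 95%-modal
        for _ in range(50):
            maf = rng_hw.uniform(lo, hi)
            v_j = rng_hw.standard_normal(q) * (cfg.structure_sd / np.sqrt(q))
            p_h = np.clip(maf + U @ v_j, 0.01, 0.99)
            col = rng_hw.binomial(2, p_h).astype(np.float64) - 1.0
            if n < 3 or _modal_fraction(col) < 0.95:
                break
        X[:, j] = col
        V[j] = v_j

    rng_c = _rng(cfg.seed, "constant-columns")
    for j in const_idx:
        X[:, j] = rng_c.choice([-1.0, 0.0, 1.0])

    rng_d = _rng(cfg.seed, "duplicate-pairs")
    for a, b in dup_idx:
        maf = rng_d.uniform(max(lo, 0.2), hi)  # keep pair columns well away from constancy
        probs = [(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2]
        col = rng_d.choice([-1.0, 0.0, 1.0], size=n, p=probs)
        X[:, a] = col
        dup = col.copy()
        # flip ~2% of entries: comfortably >= 95% identical but not exact
        n_flip = int(np.floor(0.02 * n))
        if n_flip > 0:
            flip = rng_d.choice(n, size=n_flip, replace=False)
            dup[flip] = np.where(dup[flip] == 1.0, -1.0, dup[flip] + 1.0)
        X[:, b] = dup
    return X, U, V


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a hybrids x SNPs matrix over {-1,0,+1} with planted filter targets."""
    cfg.validate()
    X = _complete_genotypes(cfg)[0].copy()
    if cfg.missing_rate > 0:
        rng_m = _rng(cfg.seed, "missing-mask")
        mask = rng_m.random(X.shape) < cfg.missing_rate
        X[mask] = np.nan
    hybrid_ids = [f"H{i:05d}" for i in range(cfg.n_hybrids)]
    snp_ids = [f"S{j:06d}" for j in range(cfg.n_snps)]
    return GenotypeMatrix(hybrid_ids=hybrid_ids, snp_ids=snp_ids, values=X)


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

_BASE = {  # (offset, seasonal amplitude, daily noise sd) per variable
    "par_total": (9.0, 3.0, 0.8),
    "tmax_2m": (24.0, 6.0, 2.0),
    "tmin_2m": (12.0, 5.0, 2.0),
    "precip_corrected": (3.0, 1.5, 1.2),
    "swdni": (18.0, 5.0, 1.5),
}


def simulate_weather(cfg: SimConfig) -> list[EnvironmentSeries]:
    cfg.validate()
    out = []
    for e in range(cfg.n_envs):
        rng = _rng(cfg.seed, "weather", e)
        k = int(rng.integers(cfg.season_length_range[0], cfg.season_length_range[1] + 1))
        t = np.arange(k)
        phase = rng.uniform(0, 2 * np.pi)
        cols = []
        for name in WEATHER_VARIABLES:
            off, amp, sd = _BASE[name]
            level = off + rng.normal(0, 0.15 * off)
            curve = level + amp * np.sin(np.pi * t / max(k - 1, 1) + 0.1 * phase)
            curve = curve + rng.normal(0, sd, size=k)
            if name == "precip_corrected":
                curve = np.clip(curve, 0.0, None)
            cols.append(curve)
        values = np.column_stack(cols)
        dates = pd.date_range("2000-04-01", periods=k, freq="D")
        out.append(EnvironmentSeries(env_id=f"E{e:04d}", dates=list(dates), values=values))
    # heat waves on a deterministic subset of environments
    rng_hw = _rng(cfg.seed, "heatwaves")
    n_hw = int(round(cfg.heatwave_fraction * cfg.n_envs))
    hw_envs = sorted(rng_hw.choice(cfg.n_envs, size=n_hw, replace=False)) if n_hw else []
    for e in hw_envs:
        series = out[e]
        k = series.values.shape[0]
        length = int(rng_hw.integers(4, 9))
        start = int(rng_hw.integers(0, max(k - length, 1)))
        days = list(range(start, min(start + length, k)))
        shift = rng_hw.uniform(5.0, 9.0)
        series.values[days, 1] += shift  # tmax
        series.values[days, 2] += shift * 0.7  # tmin
        series.heatwave_days = days
    return out


# ---------------------------------------------------------------------------
# yields
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray, target_var: float) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return x / sd * np.sqrt(target_var)


def simulate_yields(
    G: GenotypeMatrix,
    envs: list[EnvironmentSeries],
    cfg: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Sample (hybrid, environment, replicate) plot records.

    yield = mu + g_h + e_env + gamma * g_h * e_env + eps, with the last
    year's hybrids and environments disjoint from earlier years.
    """
    cfg.validate()
    if len(G.hybrid_ids) == 0 or len(envs) == 0:
        raise ValueError("empty genotype or environment set")

    var = cfg.effect_variances
    X_true, U, V = _complete_genotypes(cfg)

    # genetic score: linear in a causal subset of the TRUE marker matrix.
    # Causal weights follow the structure loadings (plus an independent part)
    # so the polygenic score is coherent across structured markers -- the
    # analogue of LD making a marker panel's top PCs informative.
    rng_g = _rng(cfg.seed, "genetic-effects")
    n_causal = max(1, int(round(cfg.causal_fraction * cfg.n_snps)))
    causal = sorted(rng_g.choice(cfg.n_snps, size=n_causal, replace=False))
    beta = rng_g.normal(0, 1, size=V.shape[1])
    aligned = V[causal] @ beta
    scale = np.abs(aligned).mean() if np.abs(aligned).mean() > 0 else 1.0
    weights = aligned + 0.15 * scale * rng_g.normal(0, 1, size=n_causal)
    g_raw = X_true[:, causal] @ weights
    g = _standardize(g_raw, var.get("additive_g", 0.0))

    # environment score: season aggregates plus a heat-wave penalty
    agg = []
    for s in envs:
        v = s.values
        agg.append([v[:, i].mean() for i in range(5)] + [v[:, 1].max(), v[:, 3].sum()])
    agg = np.asarray(agg)
    rng_e = _rng(cfg.seed, "env-effects")
    w_e = rng_e.normal(0, 1, size=agg.shape[1])
    e_raw = (agg - agg.mean(axis=0)) / np.maximum(agg.std(axis=0), 1e-9) @ w_e
    hw_len = np.array([len(s.heatwave_days or []) for s in envs], dtype=float)
    e_raw = e_raw - 0.3 * hw_len  # short events matter beyond the aggregates
    e = _standardize(e_raw, var.get("additive_e", 0.0))

    inter_var = var.get("interaction", 0.0)
    gamma = 0.0
    if inter_var > 0:
        ge_sd = np.std(np.outer(g, e))
        gamma = float(np.sqrt(inter_var) / max(ge_sd, 1e-12))

    # year assignment: the last year's hybrids and environments are disjoint
    rng_y = _rng(cfg.seed, "years")
    n_h, n_e = len(G.hybrid_ids), len(envs)
    years = list(cfg.years)
    last = years[-1]
    n_test_h = int(round(cfg.test_hybrid_fraction * n_h)) if len(years) > 1 else 0
    n_test_e = max(1, int(round(cfg.test_env_fraction * n_e))) if len(years) > 1 else 0
    h_perm = rng_y.permutation(n_h)
    test_h = set(h_perm[:n_test_h])
    e_perm = rng_y.permutation(n_e)
    test_e = set(e_perm[:n_test_e]) if len(years) > 1 else set()
    env_year = {}
    dev_years = years[:-1] if len(years) > 1 else years
    for idx in range(n_e):
        if idx in test_e:
            env_year[envs[idx].env_id] = last
        else:
            env_year[envs[idx].env_id] = dev_years[int(rng_y.integers(len(dev_years)))]

    mu = 9.5
    noise_seed = int(_rng(cfg.seed, "noise-seed").integers(2**31 - 1))
    rng_n = np.random.default_rng(noise_seed)
    noise_sd = np.sqrt(var.get("noise", 0.0))

    rng_p = _rng(cfg.seed, "pairs")
    records = []
    for idx, s in enumerate(envs):
        year = env_year[s.env_id]
        eligible = [h for h in range(n_h) if (h in test_h) == (year == last)]
        if cfg.pairs_per_env is not None and cfg.pairs_per_env < len(eligible):
            eligible = sorted(rng_p.choice(eligible, size=cfg.pairs_per_env, replace=False))
        for h in eligible:
            base = mu + g[h] + e[idx] + gamma * g[h] * e[idx]
            for _ in range(cfg.replicates_per_pair):
                eps = rng_n.normal(0, noise_sd) if noise_sd > 0 else 0.0
                records.append((s.env_id, G.hybrid_ids[h], year, base + eps))

    table = pd.DataFrame(records, columns=["env_id", "hybrid_id", "year", "yield_mg_ha"])
    truth = GroundTruth(
        mu=mu,
        genetic_score={G.hybrid_ids[h]: float(g[h]) for h in range(n_h)},
        env_score={envs[i].env_id: float(e[i]) for i in range(n_e)},
        gamma=gamma,
        noise_seed=noise_seed,
        causal_snp_ids=[G.snp_ids[j] for j in causal],
        causal_weights=[float(w) for w in weights],
        heatwave_days={s.env_id: list(s.heatwave_days or []) for s in envs},
        env_year=env_year,
        hybrid_year_pool={G.hybrid_ids[h]: ("test" if h in test_h else "dev")
                          for h in range(n_h)},
    )
    return table, truth


def simulate_dataset(cfg: SimConfig):
    """Convenience: genotypes + weather + phenotypes + ground truth."""
    G = simulate_genotypes(cfg)
    envs = simulate_weather(cfg)
    pheno, truth = simulate_yields(G, envs, cfg)
    return G, envs, pheno, truth


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(out_dir, G: GenotypeMatrix, envs: list[EnvironmentSeries],
                  pheno: pd.DataFrame, truth: GroundTruth) -> None:
    """Emit the three delimited-text inputs plus a ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geno = pd.DataFrame(G.values, index=G.hybrid_ids, columns=G.snp_ids)
    geno.index.name = "hybrid_id"
    geno.to_csv(out / "genotypes.tsv", sep="\t", na_rep="NA", float_format="%.0f")

    rows = []
    for s in envs:
        for d, v in zip(s.dates, s.values):
            rows.append([s.env_id, pd.Timestamp(d).date().isoformat(), *v])
    pd.DataFrame(rows, columns=["env_id", "date", *WEATHER_VARIABLES]).to_csv(
        out / "weather.tsv", sep="\t", index=False)

    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=1)
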