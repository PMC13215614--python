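"""SNP-matrix compression: imputation, filters, PCA embedding.

The pipeline order is fixed: probabilistic imputation -> low-variance
filter -> windowed similarity pruning -> PCA fitted on training hybrids
only.  Each stage's output columns are a subset of its input's.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "GenotypeMatrix", "FilterReport", "PCAModel", "GenotypeEmbedding",
    "impute_probabilistic", "filter_low_variance", "prune_windowed_similarity",
    "fit_pca", "project_genotypes", "run_pipeline",
]

_ALLELES = np.array([-1.0, 0.0, 1.0])


@dataclass
class GenotypeMatrix:
    """Hybrids x SNPs over {-1, 0, +1}; missing entries are NaN."""

    hybrid_ids: list
    snp_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.hybrid_ids), len(self.snp_ids)):
            raise ValueError("matrix shape does not match id lists")
        if len(set(self.hybrid_ids)) != len(self.hybrid_ids):
            raise ValueError("hybrid ids must be unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("snp ids must be unique")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, _ALLELES).all():
            raise ValueError("genotype values must be in {-1, 0, +1} or missing")

    @property
    def n_hybrids(self) -> int:
        return len(self.hybrid_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_columns(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            hybrid_ids=list(self.hybrid_ids),
            snp_ids=[self.snp_ids[j] for j in keep],
            values=self.values[:, keep],
        )

    def subset_rows(self, hybrid_ids: list) -> "GenotypeMatrix":
        index = {h: i for i, h in enumerate(self.hybrid_ids)}
        rows = [index[h] for h in hybrid_ids]
        return GenotypeMatrix(hybrid_ids=list(hybrid_ids),
                              snp_ids=list(self.snp_ids),
                              values=self.values[rows])


@dataclass
class FilterReport:
    stage: str                       # "low_variance" | "window_prune"
    removed_snp_ids: list
    kept_count: int
    parameters: dict = field(default_factory=dict)


@dataclass
class PCAModel:
    center: np.ndarray               # per-SNP mean
    components: np.ndarray           # (n_components, n_snps), rows orthonormal
    explained_variance_ratio: np.ndarray
    n_components: int
    snp_ids: list

    def __post_init__(self):
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("PCA loadings are not orthonormal")
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained variance ratios must be nonincreasing and sum <= 1")


@dataclass
class GenotypeEmbedding:
    hybrid_ids: list
    scores: np.ndarray               # hybrids x n_components


# ---------------------------------------------------------------------------

def impute_probabilistic(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Replace each missing entry with a draw from its column's empirical
    {-1,0,+1} distribution.  Non-missing entries are untouched; draws use a
    per-column substream keyed on (seed, snp_id) so results do not depend
    on column order."""
    X = G.values.copy()
    for j, snp_id in enumerate(G.snp_ids):
        col = X[:, j]
        missing = np.isnan(col)
        if not missing.any():
            continue
        observed = col[~missing]
        if observed.size == 0:
            raise ValueError(f"column {snp_id!r} is entirely missing; cannot impute")
        freqs = np.array([(observed == a).mean() for a in _ALLELES])
        rng = np.random.default_rng([seed, zlib.crc32(str(snp_id).encode())])
        col[missing] = rng.choice(_ALLELES, size=missing.sum(), p=freqs)
    return GenotypeMatrix(list(G.hybrid_ids), list(G.snp_ids), X)


def _modal_fractions(X: np.ndarray) -> np.ndarray:
    counts = np.stack([(X == a).sum(axis=0) for a in _ALLELES])
    return counts.max(axis=0) / X.shape[0]


def filter_low_variance(
    G: GenotypeMatrix, modal_threshold: float = 0.95
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop columns whose most frequent value covers >= modal_threshold of rows."""
    if G.n_snps == 0 or G.n_hybrids == 0:
        raise ValueError("empty genotype matrix")
    if G.has_missing():
        raise ValueError("low-variance filter requires an imputed (complete) matrix")
    modal = _modal_fractions(G.values)
    keep = np.flatnonzero(modal < modal_threshold)
    removed = [G.snp_ids[j] for j in np.flatnonzero(modal >= modal_threshold)]
    report = FilterReport(
        stage="low_variance",
        removed_snp_ids=removed,
        kept_count=int(keep.size),
        parameters={"modal_threshold": modal_threshold},
    )
    return G.subset_columns(keep), report


def prune_windowed_similarity(
    G: GenotypeMatrix, window_L: int, identity_threshold: float = 0.95
) -> tuple[GenotypeMatrix, FilterReport]:
    """Within consecutive non-overlapping windows of window_L columns, keep
    one representative (lowest index) of every >= identity_threshold-identical
    group; greedy left-to-right."""
    if window_L < 1:
        raise ValueError("window_L must be >= 1")
    if G.has_missing():
        raise ValueError("window pruning requires an imputed (complete) matrix")
    X = G.values
    n = X.shape[0]
    keep: list[int] = []
    for start in range(0, G.n_snps, window_L):
        window_kept: list[int] = []
        for j in range(start, min(start + window_L, G.n_snps)):
            redundant = any(
                (X[:, j] == X[:, r]).mean() >= identity_threshold for r in window_kept
            )
            if not redundant:
                window_kept.append(j)
        keep.extend(window_kept)
    keep_arr = np.asarray(keep, dtype=int)
    removed = [G.snp_ids[j] for j in range(G.n_snps) if j not in set(keep)]
    report = FilterReport(
        stage="window_prune",
        removed_snp_ids=removed,
        kept_count=int(keep_arr.size),
        parameters={"window_L": window_L, "identity_threshold": identity_threshold},
    )
    return G.subset_columns(keep_arr), report


def fit_pca(
    G_train: GenotypeMatrix,
    variance_target: float = 0.90,
    max_components: int | None = None,
) -> PCAModel:
    """Principal components on the (centered, unscaled) training matrix.

    Keeps the smallest component count reaching ``variance_target``
    cumulative explained variance, capped at ``max_components``.
    """
    if not (0 < variance_target <= 1):
        raise ValueError("variance_target must be in (0, 1]")
    if G_train.has_missing():
        raise ValueError("PCA requires an imputed (complete) matrix")
    if G_train.n_hybrids < 2:
        raise ValueError("PCA needs at least 2 rows")
    limit = min(G_train.n_hybrids - 1, G_train.n_snps)
    if max_components is not None:
        limit = min(limit, max_components)
    pca = PCA(n_components=min(G_train.n_hybrids - 1, G_train.n_snps), svd_solver="full")
    pca.fit(G_train.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_components = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_components = min(n_components, limit)
    return PCAModel(
        center=pca.mean_.copy(),
        components=pca.components_[:n_components].copy(),
        explained_variance_ratio=pca.explained_variance_ratio_[:n_components].copy(),
        n_components=n_components,
        snp_ids=list(G_train.snp_ids),
    )


def project_genotypes(model: PCAModel, G: GenotypeMatrix) -> GenotypeEmbedding:
    """scores = (values - center) @ components.T; column set must match the fit."""
    if list(G.snp_ids) != list(model.snp_ids):
        diff = set(G.snp_ids).symmetric_difference(model.snp_ids)
        raise ValueError(f"SNP id mismatch with fitted model: {sorted(diff)[:10]}"
                         f"{' ...' if len(diff) > 10 else ''}")
    if G.has_missing():
        raise ValueError("projection requires an imputed (complete) matrix")
    scores = (G.values - model.center) @ model.components.T
    return GenotypeEmbedding(hybrid_ids=list(G.hybrid_ids), scores=scores)


def run_pipeline(
    G: GenotypeMatrix,
    train_hybrids: list,
    seed: int,
    window_L: int = 100,
    modal_threshold: float = 0.95,
    identity_threshold: float = 0.95,
    variance_target: float = 0.90,
    max_components: int | None = None,
):
    """impute -> low-variance -> window-prune -> PCA (train rows only) -> project all.

    Returns (embedding, model, [reports]).
    """
    imputed = impute_probabilistic(G, seed=seed)
    filtered, rep1 = filter_low_variance(imputed, modal_threshold=modal_threshold)
    pruned, rep2 = prune_windowed_similarity(filtered, window_L=window_L,
                                             identity_threshold=identity_threshold)
    model = fit_pca(pruned.subset_rows(train_hybrids),
                    variance_target=variance_target, max_components=max_components)
    embedding = project_genotypes(model, pruned)
    return embedding, model, [rep1, rep2]
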