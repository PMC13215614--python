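"""Delimited-text readers/writers for the three input tables, plus an
optional VCF genotype reader and a model checkpoint container."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix
from .weather import WEATHER_VARIABLES, EnvironmentSeries

__all__ = ["read_genotypes", "read_weather", "read_phenotypes",
           "read_vcf_genotypes", "save_checkpoint", "load_checkpoint"]


def read_genotypes(path) -> GenotypeMatrix:
    """hybrids x SNPs table: first column hybrid_id, NA for missing."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, na_values=["NA"])
    return GenotypeMatrix(
        hybrid_ids=[str(h) for h in df.index],
        snp_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=np.float64),
    )


def read_weather(path) -> list[EnvironmentSeries]:
    """Long table (env_id, date, variable columns); extra columns are ignored."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [v for v in WEATHER_VARIABLES if v not in df.columns]
    if missing:
        raise ValueError(f"weather table is missing variable columns {missing}")
    out = []
    for env_id, grp in df.groupby("env_id", sort=True):
        grp = grp.sort_values("date")
        out.append(EnvironmentSeries(
            env_id=str(env_id),
            dates=list(pd.to_datetime(grp["date"])),
            values=grp[WEATHER_VARIABLES].to_numpy(dtype=np.float64),
        ))
    return out


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"env_id", "hybrid_id", "year", "yield_mg_ha"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table is missing columns {sorted(missing)}")
    df["year"] = df["year"].astype(int)
    return df


def read_vcf_genotypes(path) -> GenotypeMatrix:
    """Diploid biallelic VCF -> {-1, 0, +1} dosage (heterozygote = 0).

    Multiallelic or non-diploid records are skipped; missing GT -> NaN.
    """
    sample_ids: list[str] = []
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                continue  # biallelic SNPs only
            fmt = fields[8].split(":")
            gt_idx = fmt.index("GT")
            calls = np.full(len(sample_ids), np.nan)
            ok = True
            for i, sample in enumerate(fields[9:]):
                gt = sample.split(":")[gt_idx].replace("|", "/")
                if gt in (".", "./."):
                    continue
                alleles = gt.split("/")
                if len(alleles) != 2:
                    ok = False
                    break
                dose = sum(int(a) for a in alleles)
                calls[i] = dose - 1  # 0/0 -> -1, 0/1 -> 0, 1/1 -> +1
            if ok:
                snp_ids.append(vid if vid != "." else f"{chrom}:{pos}")
                rows.append(calls)
    values = np.column_stack(rows) if rows else np.empty((len(sample_ids), 0))
    return GenotypeMatrix(hybrid_ids=list(sample_ids), snp_ids=snp_ids, values=values)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, predictor, config: dict | None = None) -> None:
    """Self-describing container: npz of arrays + JSON metadata sidecar."""
    from .train import TrainedPredictor  # noqa: F401  (type documented here)

    model = predictor.model
    arrays = {f"param_{i}": a for i, a in enumerate(model.state())}
    arrays["pc_scale"] = predictor.pc_scale
    arrays["norm_mean"] = predictor.stats.mean
    arrays["norm_std"] = predictor.stats.std
    meta = {
        "arch": model.arch, "d": model.d, "n_heads": model.n_heads,
        "K": model.K, "k_intra": model.k_intra,
        "n_geno": model.n_geno, "n_env": model.n_env,
        "head_dims": [W.data.shape[1] for W, _ in model.mlp[:-1]],
        "lstm_m": model.lstm.m if model.lstm is not None else None,
        "config": config or {},
    }
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path):
    from .nn import GxEModel
    from .train import TrainedPredictor
    from .weather import NormalizationStats

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    arrays = np.load(path.with_suffix(".npz"))
    model = GxEModel(meta["arch"], meta["n_geno"], meta["n_env"], d=meta["d"],
                     n_heads=meta["n_heads"], K=meta["K"], k_intra=meta["k_intra"],
                     head_dims=tuple(meta["head_dims"]), lstm_m=meta["lstm_m"])
    n_params = len(model.parameters())
    model.load_state([arrays[f"param_{i}"] for i in range(n_params)])
    stats = NormalizationStats(mean=arrays["norm_mean"], std=arrays["norm_std"])
    return TrainedPredictor(model=model, stats=stats, pc_scale=arrays["pc_scale"]), meta
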