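"""Interchange formats and run configuration.

Tables are tab-separated UTF-8 with a mandatory header row; floats are
written with 10 significant digits.  Supported formats:

* survival CSV: ``patient_id,time,event,stratum`` (time on the integer grid);
* covariate TSV: ``sample_id`` plus one column per covariate;
* phenotype TSV: ``sample_id`` and ``phenotype``;
* genotype dosage matrix, either plain TSV (``sample_id`` + one column per
  variant) or a PLINK-.raw-style dialect (``FID IID PAT MAT SEX PHENOTYPE``
  then variant columns, whitespace-separated);
* association TSV: ``VARIANT_ID BETA SE STAT P NEG_LOG10_P FLAG``;
* per-stratum Kaplan-Meier curve TSV: ``t S n_at_risk d c``;
* transcript JSON-lines; run configuration YAML.

Missing genotype cells (``NA``) are mean-imputed per variant by default
(with a count available to the caller); the ``fail`` policy raises and
names the offending cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .gwas_exact import AssocStats, GwasDataset
from .survival import KMCurve, SurvivalRecord

__all__ = [
    "RunConfig",
    "load_config",
    "read_survival",
    "write_survival",
    "read_covariates",
    "write_covariates",
    "read_phenotype",
    "write_phenotype",
    "read_genotypes",
    "write_genotypes",
    "read_gwas_dataset",
    "write_gwas_dataset",
    "write_assoc",
    "read_assoc",
    "write_km_curve",
]

FLOAT_FMT = "%.10g"


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

_SCHEMA = {
    "seed": int,
    "pipeline": str,  # km | gwas_exact | gwas_fast | meta | compare
    "crypto": {"num_slots": int, "depth_budget": int, "precision_bits": int,
               "mode": str, "noise_seed": int},
    "topology": {"fanout": int},
    "dp": {"count": int, "split": list},
    "dp_noise": {"mechanism": str, "epsilon": float, "delta": float, "sensitivity": float},
    "cheb": {"degree": int, "interval": list},
    "gj": {"validation_mode": bool, "newton_steps": int},
    "fgd": {"learning_rate": float, "iterations": int, "refresh_every": int},
    "fast": {"batch_slots": int},
    "km": {"T": int, "strata": list, "checkpoints": list},
    "gwas": {"df_mode": str, "reference": str, "maf_min": float},
    "io": {
        "survival": str, "covariates": str, "phenotype": str, "genotypes": str,
        "genotype_dialect": str, "out_dir": str, "transcript": str,
    },
}


def _validate_block(block, schema, path=""):
    if not isinstance(block, dict):
        raise ConfigurationError(f"config section {path or '<root>'} must be a mapping")
    for key, val in block.items():
        if key not in schema:
            raise ConfigurationError(f"unknown config key {path + key!r}")
        want = schema[key]
        if isinstance(want, dict):
            _validate_block(val, want, path + key + ".")
        elif want is float:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                raise ConfigurationError(f"config key {path + key!r} must be a number")
        elif want is int:
            if not isinstance(val, int) or isinstance(val, bool):
                raise ConfigurationError(f"config key {path + key!r} must be an integer")
        elif not isinstance(val, want):
            raise ConfigurationError(f"config key {path + key!r} must be of type {want.__name__}")


@dataclass
class RunConfig:
    """Validated run configuration (unknown keys are rejected)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        _validate_block(self.raw, _SCHEMA)

    def get(self, dotted: str, default=None):
        node = self.raw
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                return default
            node = node[part]
        return node


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(raw=raw)


# --------------------------------------------------------------------------
# Survival records
# --------------------------------------------------------------------------


def write_survival(records, path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(len(records))],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "stratum": [r.stratum for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_survival(path) -> list:
    df = pd.read_csv(path)
    required = {"patient_id", "time", "event", "stratum"}
    if not required.issubset(df.columns):
        raise ValidationError(f"survival CSV must have columns {sorted(required)}")
    return [
        SurvivalRecord(time=int(t), event=bool(e), stratum=str(s))
        for t, e, s in zip(df["time"], df["event"], df["stratum"])
    ]


# --------------------------------------------------------------------------
# GWAS tables
# --------------------------------------------------------------------------


def write_covariates(X, path, sample_ids=None) -> None:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sample_ids = sample_ids or [f"s{i}" for i in range(X.shape[0])]
    df = pd.DataFrame(X, columns=[f"cov{j}" for j in range(X.shape[1])])
    df.insert(0, "sample_id", sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_covariates(path):
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError("covariate TSV must have a sample_id column")
    ids = df["sample_id"].astype(str).tolist()
    return df.drop(columns="sample_id").to_numpy(dtype=float), ids


def write_phenotype(y, path, sample_ids=None) -> None:
    y = np.asarray(y, dtype=float).ravel()
    sample_ids = sample_ids or [f"s{i}" for i in range(len(y))]
    pd.DataFrame({"sample_id": sample_ids, "phenotype": y}).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_phenotype(path):
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "phenotype"}.issubset(df.columns):
        raise ValidationError("phenotype TSV must have sample_id and phenotype columns")
    return df["phenotype"].to_numpy(dtype=float), df["sample_id"].astype(str).tolist()


def write_genotypes(G, path, variant_ids=None, sample_ids=None, dialect: str = "tsv") -> None:
    G = np.atleast_2d(np.asarray(G, dtype=float))
    p, v = G.shape
    variant_ids = variant_ids or [f"v{i}" for i in range(v)]
    sample_ids = sample_ids or [f"s{i}" for i in range(p)]
    df = pd.DataFrame(G, columns=variant_ids)
    if dialect == "tsv":
        df.insert(0, "sample_id", sample_ids)
        df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
    elif dialect == "plink_raw":
        for col, val in [("PHENOTYPE", -9), ("SEX", 0), ("MAT", 0), ("PAT", 0)]:
            df.insert(0, col, val)
        df.insert(0, "IID", sample_ids)
        df.insert(0, "FID", sample_ids)
        df.to_csv(path, sep=" ", index=False, float_format=FLOAT_FMT)
    else:
        raise ConfigurationError(f"unknown genotype dialect {dialect!r}")


def read_genotypes(path, dialect: str = "tsv", na_policy: str = "mean_impute"):
    """Read a dosage matrix; returns (G, variant_ids, sample_ids, n_imputed).

    Dosages must lie in [0, 2] (or be NA).  ``na_policy``:
    ``mean_impute`` replaces NA with the variant mean; ``fail`` raises and
    names the first offending cell.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        if "sample_id" not in df.columns:
            raise ValidationError("genotype TSV must have a sample_id column")
        sample_ids = df["sample_id"].astype(str).tolist()
        body = df.drop(columns="sample_id")
    elif dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+")
        meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        missing = [m for m in meta if m not in df.columns]
        if missing:
            raise ValidationError(f"plink_raw file lacks columns {missing}")
        sample_ids = df["IID"].astype(str).tolist()
        body = df.drop(columns=meta)
    else:
        raise ConfigurationError(f"unknown genotype dialect {dialect!r}")

    variant_ids = list(body.columns)
    try:
        G = body.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric dosage in {path}: {exc}") from exc

    n_imputed = 0
    if np.isnan(G).any():
        if na_policy == "fail":
            r, ccol = np.argwhere(np.isnan(G))[0]
            raise ValidationError(
                f"missing dosage at sample {sample_ids[r]!r}, variant {variant_ids[ccol]!r}"
            )
        if na_policy != "mean_impute":
            raise ConfigurationError(f"unknown NA policy {na_policy!r}")
        for j in range(G.shape[1]):
            col = G[:, j]
            nas = np.isnan(col)
            if nas.any():
                fill = np.nanmean(col) if not nas.all() else 0.0
                col[nas] = fill
                n_imputed += int(nas.sum())
    finite = G[np.isfinite(G)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValidationError("dosages must lie in [0, 2]")
    return G, variant_ids, sample_ids, n_imputed


def write_gwas_dataset(ds: GwasDataset, prefix, dialect: str = "tsv") -> dict:
    """Write the three tables of a dataset; returns their paths."""
    sample_ids = [f"s{i}" for i in range(ds.p)]
    paths = {
        "covariates": f"{prefix}.cov.tsv",
        "phenotype": f"{prefix}.pheno.tsv",
        "genotypes": f"{prefix}.geno.tsv" if dialect == "tsv" else f"{prefix}.raw",
    }
    write_covariates(ds.X, paths["covariates"], sample_ids)
    write_phenotype(ds.y, paths["phenotype"], sample_ids)
    write_genotypes(ds.G, paths["genotypes"], ds.variant_ids, sample_ids, dialect)
    return paths


def read_gwas_dataset(covariates, phenotype, genotypes, dialect: str = "tsv",
                      na_policy: str = "mean_impute") -> GwasDataset:
    X, ids_x = read_covariates(covariates)
    y, ids_y = read_phenotype(phenotype)
    G, variant_ids, ids_g, _ = read_genotypes(genotypes, dialect, na_policy)
    if not (ids_x == ids_y == ids_g):
        raise ValidationError("sample order differs across covariate/phenotype/genotype tables")
    return GwasDataset(X=X, y=y, G=G, variant_ids=variant_ids)


# --------------------------------------------------------------------------
# Results
# --------------------------------------------------------------------------


def write_assoc(res: AssocStats, path) -> None:
    res.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_assoc(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_km_curve(curve: KMCurve, path) -> None:
    curve.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
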