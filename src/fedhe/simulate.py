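"""Synthetic cohorts emulating the statistical structure of the target studies.

Two generators:

* ``gen_survival`` — stratified right-censored survival cohorts on an
  integer time grid (months).  Event and censoring times are geometric
  (the discrete-time analogue of exponential waiting times), with
  administrative censoring at the grid maximum — matching a cohort whose
  follow-up is rounded to months and stratified by a biomarker such as
  tumor mutational burden.

* ``gen_gwas`` — multi-site quantitative-trait GWAS cohorts: genotype
  dosages drawn Binomial(2, maf) per variant under Hardy-Weinberg
  equilibrium (independent variants, no LD), standard-normal covariates
  standing in for ancestry components, and a linear phenotype with a
  configurable set of planted causal variants plus Gaussian noise.

``split_dps`` partitions any of these datasets across k sites
deterministically, so federated results can be compared with the pooled
computation row-for-row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError
from .gwas_exact import GwasDataset
from .survival import SurvivalRecord

__all__ = [
    "SurvivalSimConfig",
    "GwasSimConfig",
    "gen_survival",
    "gen_gwas",
    "split_dps",
    "split_gwas",
]


@dataclass
class SurvivalSimConfig:
    """Stratified discrete-time survival cohort settings.

    ``groups`` maps a stratum label to ``(n, event_hazard)``: per-grid-unit
    event probability.  ``censor_prob`` is the per-unit withdrawal
    probability shared by all strata; anyone still under observation at
    ``T`` is administratively censored there.
    """

    groups: list = field(default_factory=lambda: [("low", 500, 0.030),
                                                  ("mid", 550, 0.018),
                                                  ("high", 550, 0.010)])
    censor_prob: float = 0.02
    T: int = 200
    seed: int = 0

    def __post_init__(self):
        for label, n, hz in self.groups:
            if not 0.0 <= hz <= 1.0:
                raise ConfigurationError(f"hazard for {label!r} outside [0, 1]")
            if n < 1:
                raise ConfigurationError(f"group {label!r} must have n >= 1")
        if not 0.0 <= self.censor_prob < 1.0:
            raise ConfigurationError("censor_prob must lie in [0, 1)")


def gen_survival(cfg: SurvivalSimConfig):
    """Draw a stratified right-censored cohort; returns (records, truth).

    Per patient, an event time E ~ Geometric(hazard) and a censoring time
    C ~ Geometric(censor_prob) compete on the grid (both capped at T, with
    C = T meaning administrative censoring).  The observed record is
    ``(min(E, C), event = E <= C)`` — at a tie the event is observed.
    """
    rng = np.random.default_rng(cfg.seed)
    records = []
    truth = {"groups": {}, "seed": cfg.seed, "T": cfg.T}
    for label, n, hz in cfg.groups:
        if hz > 0:
            ev = rng.geometric(hz, size=n) - 1  # support {0, 1, ...}
        else:
            ev = np.full(n, np.iinfo(np.int64).max)
        if cfg.censor_prob > 0:
            cs = rng.geometric(cfg.censor_prob, size=n) - 1
        else:
            cs = np.full(n, np.iinfo(np.int64).max)
        cs = np.minimum(cs, cfg.T)  # administrative censoring at T
        time = np.minimum(ev, cs)
        event = ev <= cs
        for t, e in zip(time, event):
            records.append(SurvivalRecord(time=int(min(t, cfg.T)), event=bool(e), stratum=label))
        truth["groups"][label] = {"n": n, "hazard": hz}
    return records, truth


@dataclass
class GwasSimConfig:
    """Multi-site GWAS cohort settings (Hardy-Weinberg genotypes, linear trait)."""

    p: int = 800
    f: int = 12
    v: int = 256
    maf_range: tuple = (0.05, 0.5)
    n_causal: int = 10
    effect_sd: float = 0.25
    covariate_effect_scale: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.n_causal > self.v:
            raise ConfigurationError("n_causal cannot exceed the number of variants")
        if min(self.p, self.v) < 1 or self.f < 0:
            raise ConfigurationError("dimensions must be positive")


def gen_gwas(cfg: GwasSimConfig):
    """Draw a GWAS dataset; returns (GwasDataset, truth).

    ``y = X beta_cov + sum_causal g beta_g + eps`` with
    ``eps ~ N(0, noise_sd^2)``; genotypes ``g ~ Binomial(2, maf)`` with
    per-variant maf uniform over ``maf_range``; covariates standard normal.
    ``truth`` records the causal indices and their effects.
    """
    rng = np.random.default_rng(cfg.seed)
    X = rng.standard_normal((cfg.p, cfg.f))
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.v)
    G = rng.binomial(2, maf, size=(cfg.p, cfg.v)).astype(float)
    beta_cov = rng.normal(0.0, cfg.covariate_effect_scale, size=cfg.f)
    causal = np.sort(rng.choice(cfg.v, size=cfg.n_causal, replace=False)) if cfg.n_causal else np.array([], dtype=int)
    beta_g = rng.normal(0.0, cfg.effect_sd, size=cfg.n_causal)
    y = X @ beta_cov + rng.normal(0.0, cfg.noise_sd, size=cfg.p)
    if cfg.n_causal:
        y = y + G[:, causal] @ beta_g
    ds = GwasDataset(X=X, y=y, G=G, variant_ids=[f"rs{i:06d}" for i in range(cfg.v)])
    truth = {
        "causal_indices": causal.tolist(),
        "causal_betas": beta_g.tolist(),
        "beta_cov": beta_cov.tolist(),
        "maf": maf.tolist(),
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
    }
    return ds, truth


def _partition_sizes(n: int, k: int, proportions=None) -> list:
    if proportions is None:
        base, rem = divmod(n, k)
        return [base + (1 if i < rem else 0) for i in range(k)]
    proportions = list(proportions)
    if len(proportions) != k:
        raise ConfigurationError("proportions length must equal the site count")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigurationError("proportions must sum to 1")
    sizes = [int(np.floor(q * n)) for q in proportions]
    i = 0
    while sum(sizes) < n:
        sizes[i % k] += 1
        i += 1
    return sizes


def split_dps(items, k: int, proportions=None, seed: int = 0) -> list:
    """Disjoint row partition of a record list across k sites."""
    items = list(items)
    if k < 1:
        raise ConfigurationError("site count must be >= 1")
    sizes = _partition_sizes(len(items), k, proportions)
    if any(s == 0 for s in sizes):
        raise ValidationError("a site would receive no samples; reduce k or adjust proportions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    out, pos = [], 0
    for s in sizes:
        out.append([items[i] for i in order[pos : pos + s]])
        pos += s
    return out


def split_gwas(ds: GwasDataset, k: int, proportions=None, seed: int = 0) -> list:
    """Disjoint sample partition of a GwasDataset across k sites."""
    if k < 1:
        raise ConfigurationError("site count must be >= 1")
    sizes = _partition_sizes(ds.p, k, proportions)
    if any(s == 0 for s in sizes):
        raise ValidationError("a site would receive no samples; reduce k or adjust proportions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ds.p)
    out, pos = [], 0
    for s in sizes:
        idx = np.sort(order[pos : pos + s])
        out.append(
            GwasDataset(X=ds.X[idx], y=ds.y[idx], G=ds.G[idx], variant_ids=list(ds.variant_ids))
        )
        pos += s
    return out
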