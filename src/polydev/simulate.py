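"""Simulation under the additive polygenic model.

This module is the calibration engine for the deviation classifiers and the
generator of fully synthetic study cohorts. Under the additive model,
per-variant dosages are binomial draws of two trials at the variant's allele
frequency (Hardy-Weinberg proportions, no linkage disequilibrium), the score
is the beta-weighted dosage sum, and the phenotype is

    pheno = sqrt(r2) * ps_z + sqrt(1 - r2) * eps,    eps ~ N(0, 1)

so the score explains a fraction ``target_r2`` of phenotypic variance in
expectation. A ``genotype_level=False`` fast path draws the standardized
score directly from N(0, 1), which is exact for the downstream bivariate
distribution and is what makes 10,000-replicate rank nulls cheap.

Synthetic study cohorts add planted deviators: individuals whose phenotype
receives a +/- shift (in phenotype-SD units) before standardisation. These
stand in for rare large-effect variant carriers and strong environmental
exposures — causes of deviation the classifiers are meant to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import DosageMatrix, build_pairs, standardize
from .errors import ConfigError

__all__ = [
    "SimConfig",
    "SimCohort",
    "RankNullStore",
    "PlantSpec",
    "simulate_null_cohort",
    "simulate_rank_null",
    "generate_synthetic_study",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cohort (and of rank-null replicates).

    ``maf`` is either an explicit per-variant frequency vector or a
    ``(low, high)`` uniform draw range within (0, 0.5]; ``beta`` an explicit
    effect vector or ``None`` for standard-normal draws. ``target_r2`` is
    the fraction of phenotypic variance the score explains. ``B`` is the
    number of replicates used when building rank nulls.
    """

    n: int
    m: int = 500
    target_r2: float = 0.316
    seed: int = 0
    B: int = 10_000
    maf: object = (0.01, 0.5)
    beta: Optional[np.ndarray] = None
    genotype_level: bool = True

    def __post_init__(self):
        if self.n < 2:
            raise ConfigError(f"n must be >= 2, got {self.n}")
        if self.m < 1:
            raise ConfigError(f"m must be >= 1, got {self.m}")
        if not (0.0 < self.target_r2 < 1.0):
            raise ConfigError(f"target_r2 must be in (0, 1), got {self.target_r2}")
        if self.B < 1:
            raise ConfigError(f"B must be >= 1, got {self.B}")
        maf = self.maf
        # YAML round-trips tuples as lists; a 2-element list is a draw range
        # unless the cohort really has m=2 explicit frequencies
        if isinstance(maf, list) and len(maf) == 2 and self.m != 2:
            maf = tuple(maf)
            object.__setattr__(self, "maf", maf)
        if isinstance(maf, tuple) and len(maf) == 2:
            lo, hi = maf
            if not (0.0 < lo <= hi <= 0.5):
                raise ConfigError(f"maf draw range must satisfy 0 < lo <= hi <= 0.5, got {maf}")
        else:
            arr = np.asarray(maf, dtype=float)
            if arr.shape != (self.m,):
                raise ConfigError(f"explicit maf vector must have length m={self.m}")
            if ((arr <= 0) | (arr > 0.5)).any():
                raise ConfigError("explicit maf values must lie in (0, 0.5]")
        if self.beta is not None and np.asarray(self.beta).shape != (self.m,):
            raise ConfigError(f"explicit beta vector must have length m={self.m}")


@dataclass(frozen=True)
class SimCohort:
    """One simulated cohort: dosages (when genotype-level), standardized
    (score, phenotype) pairs, and the realized variance explained."""

    pairs: pd.DataFrame
    realized_r2: float
    dosages: Optional[DosageMatrix] = None
    sex: Optional[np.ndarray] = None


@dataclass
class RankNullStore:
    """Null phenotype distributions per score rank.

    ``values[b, k]`` is replicate *b*'s standardized phenotype at ascending
    score rank *k*. Per-rank medians are the reference centres for the
    rank-matched empirical p-values.
    """

    n: int
    B: int
    values: np.ndarray
    _medians: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def medians(self) -> np.ndarray:
        if self._medians is None:
            self._medians = np.median(self.values, axis=0)
        return self._medians


@dataclass(frozen=True)
class PlantSpec:
    """Deviators planted into a synthetic study.

    ``shift_sd`` is the additive phenotype shift in phenotype-SD units,
    applied before final standardisation. ``skew`` applies a monotone
    exponential transform (LDL-C-like right skew) before adjustment.
    ``sexed`` optionally gives (r2_male, r2_female) for a two-group
    structure with group-specific variance explained.
    """

    n_low: int = 0
    n_high: int = 0
    shift_sd: float = 4.0
    skew: bool = False
    skew_lambda: float = 0.5
    sexed: Optional[tuple] = None

    def __post_init__(self):
        if self.n_low < 0 or self.n_high < 0:
            raise ConfigError("planted counts must be non-negative")
        if (self.n_low or self.n_high) and self.shift_sd <= 0:
            raise ConfigError(f"shift_sd must be > 0, got {self.shift_sd}")
        if self.sexed is not None:
            r2m, r2f = self.sexed
            if not (0 < r2m < 1 and 0 < r2f < 1):
                raise ConfigError("sexed variance-explained values must be in (0, 1)")


def _draw_maf(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.maf, tuple) and len(config.maf) == 2:
        lo, hi = config.maf
        return rng.uniform(lo, hi, size=config.m)
    return np.asarray(config.maf, dtype=float)


def _draw_score(config: SimConfig, rng: np.random.Generator):
    """Standardized score plus (optionally) the genotype matrix behind it."""
    if not config.genotype_level:
        return standardize(rng.standard_normal(config.n)), None
    maf = _draw_maf(config, rng)
    beta = (
        rng.standard_normal(config.m)
        if config.beta is None
        else np.asarray(config.beta, dtype=float)
    )
    dosage = rng.binomial(2, maf, size=(config.n, config.m)).astype(float)
    raw = dosage @ beta
    iids = _ids(config.n)
    dosages = DosageMatrix(
        individual_ids=iids,
        variant_ids=np.array([f"var{j + 1}" for j in range(config.m)], dtype=object),
        dosage=dosage,
    )
    return standardize(raw), dosages


def _ids(n: int) -> np.ndarray:
    width = len(str(n))
    return np.array([f"sim{str(i + 1).zfill(width)}" for i in range(n)], dtype=object)


def _phenotype(ps_z: np.ndarray, r2, rng: np.random.Generator) -> np.ndarray:
    """Unstandardized phenotype with score-explained variance r2 (scalar or
    per-individual vector)."""
    eps = rng.standard_normal(len(ps_z))
    return np.sqrt(r2) * ps_z + np.sqrt(1.0 - np.asarray(r2)) * eps


def _realized_r2(ps_z: np.ndarray, pheno_z: np.ndarray) -> float:
    return float(np.corrcoef(ps_z, pheno_z)[0, 1] ** 2)


def simulate_null_cohort(config: SimConfig) -> SimCohort:
    """One cohort under the additive polygenic model, no deviators.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ps_z, dosages = _draw_score(config, rng)
    pheno = _phenotype(ps_z, config.target_r2, rng)
    pheno_z = standardize(pheno)
    pairs = build_pairs(_ids(config.n), ps_z, pheno_z)
    return SimCohort(pairs=pairs, realized_r2=_realized_r2(ps_z, pheno_z), dosages=dosages)


def _rank_by_score(score: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ascending ranks of score, ties broken by a seeded random permutation.

    Returns ``ranks`` with ``ranks[i]`` the 0-based rank of individual i.
    """
    order = np.lexsort((rng.random(len(score)), score))
    ranks = np.empty(len(score), dtype=np.int64)
    ranks[order] = np.arange(len(score))
    return ranks


def simulate_rank_null(
    config: SimConfig, *, mem_cap_bytes: int = 2 << 30, store_path=None
) -> RankNullStore:
    """B replicate cohorts, each storing phenotypes ordered by score rank.

    Memory is ``B * n * 4`` bytes (float32). Above ``mem_cap_bytes`` the
    matrix is not held in RAM; pass ``store_path`` to back it with an
    on-disk memmap instead.
    """
    est = config.B * config.n * 4
    if est > mem_cap_bytes and store_path is None:
        raise ConfigError(
            f"rank-null store needs ~{est / 2**30:.1f} GiB for B={config.B}, "
            f"n={config.n}; pass store_path= for a disk-backed memmap, or "
            "reduce B / raise mem_cap_bytes"
        )
    rng = np.random.default_rng(config.seed)
    if store_path is not None:
        values = np.lib.format.open_memmap(
            store_path, mode="w+", dtype=np.float32, shape=(config.B, config.n)
        )
    else:
        values = np.empty((config.B, config.n), dtype=np.float32)
    for b in range(config.B):
        ps_z, _ = _draw_score(config, rng)
        pheno_z = standardize(_phenotype(ps_z, config.target_r2, rng))
        ranks = _rank_by_score(ps_z, rng)
        row = np.empty(config.n)
        row[ranks] = pheno_z
        values[b] = row
    return RankNullStore(n=config.n, B=config.B, values=values)


def generate_synthetic_study(
    config: SimConfig, plant: PlantSpec
) -> tuple[SimCohort, pd.DataFrame]:
    """Null cohort plus planted deviators, with truth labels.

    With ``n_low = n_high = 0`` and no skew/sex structure the cohort is
    identical to :func:`simulate_null_cohort` at the same seed.
    """
    if plant.n_low + plant.n_high > config.n:
        raise ConfigError(
            f"cannot plant {plant.n_low + plant.n_high} deviators in a cohort of {config.n}"
        )
    rng = np.random.default_rng(config.seed)
    ps_z, dosages = _draw_score(config, rng)
    sex = None
    if plant.sexed is not None:
        # eps drawn inside _phenotype keeps the base stream identical to the
        # unsexed path only when sexed is None; with sex structure the draw
        # order necessarily differs.
        r2m, r2f = plant.sexed
        sex = np.where(rng.random(config.n) < 0.5, "male", "female")
        r2 = np.where(sex == "male", r2m, r2f)
        pheno = _phenotype(ps_z, r2, rng)
    else:
        pheno = _phenotype(ps_z, config.target_r2, rng)

    truth = np.full(config.n, "null", dtype=object)
    n_plant = plant.n_low + plant.n_high
    if n_plant:
        idx = rng.choice(config.n, size=n_plant, replace=False)
        low, high = idx[: plant.n_low], idx[plant.n_low :]
        pheno[low] -= plant.shift_sd
        pheno[high] += plant.shift_sd
        truth[low] = "planted_low"
        truth[high] = "planted_high"
    if plant.skew:
        pheno = np.exp(plant.skew_lambda * pheno)
    pheno_z = standardize(pheno)
    iids = _ids(config.n)
    pairs = build_pairs(iids, ps_z, pheno_z)
    labels = pd.DataFrame({"individual_id": iids, "truth": truth})
    cohort = SimCohort(
        pairs=pairs, realized_r2=_realized_r2(ps_z, pheno_z), dosages=dosages, sex=sex
    )
    return cohort, labels
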