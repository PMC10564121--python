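"""Cohort data model: score weights, dosages, covariates, and phenotype adjustment.

A polygenic score (PS) for individual *i* is the weighted allele count

    PS_i = sum_j beta_j * G_ij

where ``beta_j`` is the per-effect-allele phenotype effect of variant *j*
and ``G_ij`` the dosage of the effect allele (0-2, possibly fractional for
imputed genotypes). Phenotypes and scores are analysed on the standardized
scale (mean 0, SD 1) after covariate adjustment and, for skewed traits, a
rank-inverse normal transformation (RINT).

Weights and dosages must arrive pre-harmonised to the same effect allele;
no strand or allele flipping is attempted here, so orientation mistakes
surface as sign errors rather than being silently "fixed".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

#: Blom offset used by the rank-inverse normal transformation.
BLOM_OFFSET = 0.375

_STATUS_ORDER = ("deviator_low", "deviator_high", "aligned", "intermediate")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightTable:
    """Per-variant effect sizes with effect-allele orientation.

    ``beta`` is in phenotype-SD units per effect allele; ``maf``, when
    present, is the effect-allele frequency folded into (0, 0.5].
    """

    variant_id: np.ndarray
    effect_allele: np.ndarray
    beta: np.ndarray
    maf: np.ndarray | None = None

    def __post_init__(self):
        vid = np.asarray(self.variant_id, dtype=object)
        beta = np.asarray(self.beta, dtype=float)
        object.__setattr__(self, "variant_id", vid)
        object.__setattr__(self, "effect_allele", np.asarray(self.effect_allele, dtype=object))
        object.__setattr__(self, "beta", beta)
        if len(vid) != len(beta) or len(vid) != len(self.effect_allele):
            raise FormatError("weight table columns have inconsistent lengths")
        uniq, counts = np.unique(vid, return_counts=True)
        if (counts > 1).any():
            dups = ", ".join(map(str, uniq[counts > 1][:5]))
            raise FormatError(f"duplicate variant_id in weight table: {dups}")
        if not np.isfinite(beta).all():
            raise FormatError("non-finite beta in weight table")
        if self.maf is not None:
            maf = np.asarray(self.maf, dtype=float)
            object.__setattr__(self, "maf", maf)
            if len(maf) != len(vid):
                raise FormatError("maf column length mismatch")
            ok = np.isnan(maf) | ((maf > 0) & (maf <= 0.5))
            if not ok.all():
                raise FormatError("maf values must lie in (0, 0.5]")

    def __len__(self) -> int:
        return len(self.variant_id)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "effect_allele": self.effect_allele,
                "beta": self.beta,
            }
        )
        if self.maf is not None:
            out["maf"] = self.maf
        return out


@dataclass(frozen=True)
class DosageMatrix:
    """Individuals x variants matrix of effect-allele dosages in [0, 2].

    Missing dosages are stored as NaN.
    """

    individual_ids: np.ndarray
    variant_ids: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        iid = np.asarray(self.individual_ids, dtype=object)
        vid = np.asarray(self.variant_ids, dtype=object)
        dos = np.asarray(self.dosage, dtype=float)
        object.__setattr__(self, "individual_ids", iid)
        object.__setattr__(self, "variant_ids", vid)
        object.__setattr__(self, "dosage", dos)
        for name, ids in (("individual", iid), ("variant", vid)):
            if len(np.unique(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids in dosage matrix")
        if dos.shape != (len(iid), len(vid)):
            raise FormatError(
                f"dosage shape {dos.shape} inconsistent with "
                f"{len(iid)} individuals x {len(vid)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(dos) & ((dos < 0) | (dos > 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"dosage out of [0, 2] for individual {iid[i]!r}, variant {vid[j]!r}: {dos[i, j]}"
            )

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    @property
    def m(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.dosage, columns=self.variant_ids)
        out.insert(0, "individual_id", self.individual_ids)
        return out


# ---------------------------------------------------------------------------
# file I/O (plain TSV dialects)
# ---------------------------------------------------------------------------


def read_weights(path) -> WeightTable:
    """Read a tab-separated weight table.

    Expected header: ``variant_id  effect_allele  beta  [maf]``. Duplicated
    variant ids and non-numeric effect sizes are rejected with the offending
    id / line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("variant_id", "effect_allele", "beta"):
        if col not in df.columns:
            raise FormatError(f"weight file {path} is missing required column {col!r}")
    beta = pd.to_numeric(df["beta"], errors="coerce")
    bad = beta.isna() & df["beta"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(
            f"non-numeric beta {df['beta'].iloc[row]!r} on line {row + 2} of {path}"
        )
    if beta.isna().any():
        row = int(np.flatnonzero(beta.isna().to_numpy())[0])
        raise FormatError(f"missing beta on line {row + 2} of {path}")
    maf = None
    if "maf" in df.columns:
        maf = pd.to_numeric(df["maf"], errors="coerce").to_numpy()
    return WeightTable(
        variant_id=df["variant_id"].to_numpy(),
        effect_allele=df["effect_allele"].to_numpy(),
        beta=beta.to_numpy(),
        maf=maf,
    )


def write_weights(weights: WeightTable, path) -> None:
    weights.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dosages(path) -> DosageMatrix:
    """Read a TSV dosage matrix: first column ``individual_id``, one column
    per variant, ``NA`` for missing."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "individual_id":
        raise FormatError(f"dosage file {path} must start with an individual_id column")
    return DosageMatrix(
        individual_ids=df["individual_id"].astype(str).to_numpy(),
        variant_ids=df.columns[1:].to_numpy(),
        dosage=df.iloc[:, 1:].to_numpy(dtype=float),
    )


def write_dosages(dosages: DosageMatrix, path) -> None:
    dosages.to_frame().to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )


def read_covariates(path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV keyed by ``individual_id``."""
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise FormatError(f"covariate file {path} is missing an individual_id column")
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate individual_id in {path}: {dup!r}")
    return df.astype({"individual_id": str})


def read_pairs(path) -> pd.DataFrame:
    """Read a standardized (score, phenotype) pair table."""
    df = pd.read_csv(path, sep="\t")
    for col in ("individual_id", "ps_z", "pheno_z"):
        if col not in df.columns:
            raise FormatError(f"pair file {path} is missing column {col!r}")
    return df.astype({"individual_id": str})


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.10g")


def validate_pairs(pairs: pd.DataFrame, tol: float = 1e-8) -> None:
    """Check the StandardizedPair contract: each column mean 0, SD 1 (ddof=1)."""
    for col in ("ps_z", "pheno_z"):
        v = pairs[col].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise DataError(f"non-finite values in {col}")
        if abs(v.mean()) > tol or abs(v.std(ddof=1) - 1.0) > tol:
            raise DataError(
                f"{col} is not standardized: mean={v.mean():.3g}, sd={v.std(ddof=1):.6g}"
            )


# ---------------------------------------------------------------------------
# polygenic score
# ---------------------------------------------------------------------------


def compute_polygenic_score(
    dosages: DosageMatrix,
    weights: WeightTable,
    *,
    missing_variants: str = "error",
    impute_missing: bool = True,
) -> np.ndarray:
    """Raw polygenic score per individual: ``sum_j beta_j * dosage_ij``.

    Weight variants absent from the dosage matrix raise (or are skipped with
    ``missing_variants='skip'``); dosage-matrix variants without a weight are
    ignored. Missing dosages are imputed to the per-variant mean dosage, or
    rejected with ``impute_missing=False``.
    """
    if missing_variants not in ("error", "skip"):
        raise ValueError("missing_variants must be 'error' or 'skip'")
    col_index = {v: j for j, v in enumerate(dosages.variant_ids)}
    present = np.array([v in col_index for v in weights.variant_id])
    if not present.all():
        absent = weights.variant_id[~present]
        if missing_variants == "error":
            shown = ", ".join(map(str, absent[:10]))
            raise DataError(
                f"{len(absent)} weight variant(s) absent from dosage matrix: {shown}"
            )
        logger.warning("skipping %d weight variants absent from dosages", len(absent))
    use = weights.variant_id[present]
    beta = weights.beta[present]
    cols = [col_index[v] for v in use]
    G = dosages.dosage[:, cols]
    if np.isnan(G).any():
        if not impute_missing:
            i, j = np.argwhere(np.isnan(G))[0]
            raise DataError(
                f"missing dosage for individual {dosages.individual_ids[i]!r}, "
                f"variant {use[j]!r} (strict mode)"
            )
        col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
        if np.isnan(col_mean).any():
            j = int(np.flatnonzero(np.isnan(col_mean))[0])
            raise DataError(f"variant {use[j]!r} has no observed dosages to impute from")
        G = np.where(np.isnan(G), col_mean[None, :], G)
    return G @ beta


# ---------------------------------------------------------------------------
# adjustment / standardisation
# ---------------------------------------------------------------------------


def standardize(values: np.ndarray, *, ddof: int = 1) -> np.ndarray:
    """Scale to mean 0, SD 1 (sample SD by default)."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=ddof)
    if not np.isfinite(sd) or sd < 1e-12:
        raise DataError("cannot standardize: zero (or non-finite) variance")
    return (v - v.mean()) / sd


def rint(values: np.ndarray) -> np.ndarray:
    """Rank-inverse normal transformation with the Blom offset.

    Maps ranks to normal quantiles, ``Phi^-1((rank - 3/8) / (n + 1/4))``;
    ties receive the average rank. The output is monotone in the input and
    approximately standard normal for continuous data.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise DataError(f"rint requires n >= 3, got {n}")
    if not np.isfinite(v).all():
        raise DataError("rint input contains non-finite values")
    if np.ptp(v) == 0:
        raise DataError("rint input is constant: no ordering information")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - BLOM_OFFSET) / (n + 1 - 2 * BLOM_OFFSET))


def design_matrix(
    covariates: pd.DataFrame, covariate_names: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Numeric design matrix (no intercept) for the requested covariates.

    Categorical/string columns are dummy-coded with the first level dropped.
    Missing values in any requested column are an error.
    """
    missing = [c for c in covariate_names if c not in covariates.columns]
    if missing:
        raise DataError(f"covariate column(s) not found: {', '.join(missing)}")
    sub = covariates[list(covariate_names)]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise DataError(f"missing values in covariate column(s): {', '.join(bad)}")
    parts, names = [], []
    for col in covariate_names:
        s = sub[col]
        if s.dtype.kind in "ifub":
            parts.append(s.to_numpy(dtype=float)[:, None])
            names.append(col)
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns.tolist())
    if not parts:
        return np.empty((len(covariates), 0)), []
    return np.hstack(parts), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Identify columns that add no rank (collinear with earlier ones)."""
    if X.shape[1] == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    culprits, kept = [], np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        cand = np.hstack([kept, X[:, j : j + 1]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            culprits.append(name)
    raise DataError(f"collinear covariate column(s): {', '.join(culprits)}")


def adjust_and_standardize(
    values: np.ndarray,
    covariates: pd.DataFrame | None = None,
    covariate_names: Sequence[str] = (),
    transform: str = "none",
) -> np.ndarray:
    """Residualise on covariates, optionally RINT, then standardize.

    The order is residualise -> RINT -> scale to mean 0 / SD 1, matching the
    convention of deriving rank-inverse normalised *residuals*. With no
    covariates the residual step only removes the mean.
    """
    if transform not in ("none", "rint"):
        raise ValueError("transform must be 'none' or 'rint'")
    v = np.asarray(values, dtype=float)
    if not np.isfinite(v).all():
        raise DataError("phenotype vector contains non-finite values")
    if covariate_names:
        if covariates is None:
            raise DataError("covariate_names given but no covariate table")
        if len(covariates) != len(v):
            raise DataError("values and covariates have different lengths")
        X, names = design_matrix(covariates, covariate_names)
        if len(v) < X.shape[1] + 2:
            raise DataError(
                f"insufficient data: n={len(v)} for {X.shape[1]} covariate columns"
            )
        Xc = np.hstack([np.ones((len(v), 1)), X])
        _check_full_rank(Xc, ["intercept"] + names)
        coef, *_ = np.linalg.lstsq(Xc, v, rcond=None)
        resid = v - Xc @ coef
    else:
        resid = v - v.mean()
    if transform == "rint":
        resid = rint(resid)
    return standardize(resid)


def build_pairs(
    individual_ids: np.ndarray, ps_z: np.ndarray, pheno_z: np.ndarray
) -> pd.DataFrame:
    """Assemble and validate a StandardizedPair table."""
    pairs = pd.DataFrame(
        {"individual_id": np.asarray(individual_ids, dtype=object), "ps_z": ps_z, "pheno_z": pheno_z}
    )
    validate_pairs(pairs)
    return pairs
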