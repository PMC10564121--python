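"""Four classifiers for individuals deviating from their polygenic prediction.

All four operate on a table of standardized (score, phenotype) pairs and
return a :class:`CallSet` assigning each individual one of four statuses:

``deviator_low`` / ``deviator_high``
    phenotype improbably far below / above the polygenic expectation;
``aligned``
    |standardized residual| < 1, the comparison group for enrichment;
``intermediate``
    neither — excluded from both groups.

Methods
-------
mahalanobis
    Squared Mahalanobis distance of each (ps_z, pheno_z) pair from the
    centre of a *simulated* null cohort, using the simulated covariance;
    D2 ~ chi2(2 df) under bivariate normality, so p = exp(-D2 / 2). A
    joint |residual z| > 2 rule removes points that are far out but still
    on the regression line (extreme score *and* phenotype, consistent with
    the additive model).
residual
    |standardized residual z| > k from the score-phenotype regression.
grs_rank
    Rank-matched empirical p-value: the observed phenotype at score rank k
    is compared with B simulated phenotypes at the same simulated score
    rank; p = (r + 1) / (B + 1) with r the count of replicates at least as
    extreme about the per-rank null median.
centile
    Non-parametric Tukey fences (Q1 - k*IQR, Q3 + k*IQR) on the phenotype
    within each centile bin of the score; no distributional assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .simulate import RankNullStore, _rank_by_score

__all__ = [
    "MahalanobisModel",
    "CallSet",
    "fit_mahalanobis",
    "mahalanobis_pvalues",
    "residual_z",
    "classify_mahalanobis",
    "classify_residual",
    "classify_grs_rank",
    "classify_centile",
    "centile_fences",
    "split_direction",
    "method_overlap",
]

STATUSES = ("deviator_low", "deviator_high", "aligned", "intermediate")


@dataclass(frozen=True)
class MahalanobisModel:
    """Centre and covariance of the simulated null (ps_z, pheno_z) cloud."""

    center: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        S = np.asarray(self.covariance, dtype=float)
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "covariance", S)
        if c.shape != (2,) or S.shape != (2, 2):
            raise DataError("Mahalanobis model must be bivariate")
        if not np.allclose(S, S.T):
            raise DataError("covariance matrix is not symmetric")
        if np.linalg.det(S) <= 0:
            raise DataError("covariance matrix is singular (|correlation| = 1?)")


@dataclass(frozen=True)
class CallSet:
    """Per-individual deviation calls for one method at one threshold.

    ``table`` columns: individual_id, status, statistic, p (NaN where the
    method defines no p-value).
    """

    method: str
    threshold_label: str
    table: pd.DataFrame

    def __post_init__(self):
        bad = set(self.table["status"]) - set(STATUSES)
        if bad:
            raise DataError(f"unknown status value(s): {sorted(bad)}")

    def ids(self, *statuses: str) -> set:
        mask = self.table["status"].isin(statuses)
        return set(self.table.loc[mask, "individual_id"])

    @property
    def deviators(self) -> set:
        return self.ids("deviator_low", "deviator_high")

    def counts(self) -> dict:
        c = self.table["status"].value_counts()
        return {s: int(c.get(s, 0)) for s in STATUSES}

    @property
    def label(self) -> str:
        return f"{self.method}:{self.threshold_label}"

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(1, "method", self.method)
        out.insert(2, "threshold_label", self.threshold_label)
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def _pairs_arrays(pairs: pd.DataFrame):
    x = pairs["ps_z"].to_numpy(dtype=float)
    y = pairs["pheno_z"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        i = int(np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))[0])
        raise DataError(
            f"non-finite pair values for individual {pairs['individual_id'].iloc[i]!r}"
        )
    return x, y


# ---------------------------------------------------------------------------
# Mahalanobis
# ---------------------------------------------------------------------------


def fit_mahalanobis(sim_pairs: pd.DataFrame) -> MahalanobisModel:
    """Estimate centre and (n-1) sample covariance from a simulated null cohort."""
    if len(sim_pairs) < 3:
        raise DataError(f"need >= 3 simulated pairs, got {len(sim_pairs)}")
    x, y = _pairs_arrays(sim_pairs)
    r = np.corrcoef(x, y)[0, 1]
    if abs(r) > 1 - 1e-12:
        raise DataError("degenerate simulated pairs: |correlation| = 1")
    return MahalanobisModel(
        center=np.array([x.mean(), y.mean()]),
        covariance=np.cov(np.vstack([x, y]), ddof=1),
    )


def mahalanobis_pvalues(
    pairs: pd.DataFrame, model: MahalanobisModel
) -> tuple[np.ndarray, np.ndarray]:
    """Squared Mahalanobis distance and chi2(2 df) upper-tail p per individual.

    For 2 degrees of freedom the survival function has the closed form
    ``p = exp(-D2 / 2)``; the scipy chi2 tail is used and agrees to
    floating-point precision.
    """
    x, y = _pairs_arrays(pairs)
    X = np.vstack([x, y]).T - model.center
    Sinv = np.linalg.inv(model.covariance)
    d2 = np.einsum("ij,jk,ik->i", X, Sinv, X)
    return d2, stats.chi2.sf(d2, df=2)


# ---------------------------------------------------------------------------
# shared residual z and status assembly
# ---------------------------------------------------------------------------


def residual_z(pairs: pd.DataFrame, direction: str = "pheno_on_score") -> np.ndarray:
    """Standardized residuals of the score-phenotype regression.

    ``pheno_on_score`` (default) regresses phenotype on score, so z measures
    how far the phenotype sits from its polygenic prediction;
    ``score_on_pheno`` is the transposed regression. Both are mean-0, SD-1
    over the cohort.
    """
    if direction not in ("pheno_on_score", "score_on_pheno"):
        raise ConfigError(f"unknown regression direction {direction!r}")
    x, y = _pairs_arrays(pairs)
    if len(x) < 3:
        raise DataError("need >= 3 pairs for the residual regression")
    if direction == "score_on_pheno":
        x, y = y, x
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    resid = (y - y.mean()) - slope * (x - x.mean())
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise DataError("zero residual variance: pairs are perfectly correlated")
    return resid / sd


def _assemble(
    pairs: pd.DataFrame,
    method: str,
    threshold_label: str,
    deviator: np.ndarray,
    low: np.ndarray,
    z: np.ndarray,
    statistic: np.ndarray,
    p: np.ndarray,
    z_aligned: float,
) -> CallSet:
    status = np.where(
        deviator,
        np.where(low, "deviator_low", "deviator_high"),
        np.where(np.abs(z) < z_aligned, "aligned", "intermediate"),
    )
    table = pd.DataFrame(
        {
            "individual_id": pairs["individual_id"].to_numpy(),
            "status": status,
            "statistic": statistic,
            "p": p,
        }
    )
    return CallSet(method=method, threshold_label=threshold_label, table=table)


def _direction_low(
    pairs: pd.DataFrame, z: np.ndarray, rule: str
) -> np.ndarray:
    """Boolean mask: deviation is towards low phenotype."""
    y = pairs["pheno_z"].to_numpy(dtype=float)
    if rule == "phenotype":
        low = y < 0
        tie = y == 0
        if tie.any():  # fall back to residual sign, as logged
            low = np.where(tie, z < 0, low)
    elif rule == "residual":
        low = z < 0
    else:
        raise ConfigError(f"unknown direction rule {rule!r}")
    return low


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def classify_mahalanobis(
    pairs: pd.DataFrame,
    model: MahalanobisModel,
    alpha: float = 1e-3,
    z_dev: float = 2.0,
    z_aligned: float = 1.0,
    threshold_label: str | None = None,
    direction_rule: str = "phenotype",
    residual_direction: str = "pheno_on_score",
) -> CallSet:
    """Deviator iff Mahalanobis p < alpha AND |residual z| > z_dev.

    Use ``alpha = 0.05 / n`` for the stringent Bonferroni-style threshold.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    d2, p = mahalanobis_pvalues(pairs, model)
    z = residual_z(pairs, residual_direction)
    deviator = (p < alpha) & (np.abs(z) > z_dev)
    low = _direction_low(pairs, z, direction_rule)
    label = threshold_label or f"P<{alpha:g}"
    return _assemble(pairs, "mahalanobis", label, deviator, low, z, d2, p, z_aligned)


def classify_residual(
    pairs: pd.DataFrame,
    k: float = 2.0,
    z_aligned: float = 1.0,
    threshold_label: str | None = None,
    direction_rule: str = "phenotype",
    residual_direction: str = "pheno_on_score",
) -> CallSet:
    """Deviator iff |residual z| > k (k = 2 or 3 in practice)."""
    if k <= 0:
        raise ConfigError(f"k must be > 0, got {k}")
    z = residual_z(pairs, residual_direction)
    deviator = np.abs(z) > k
    low = _direction_low(pairs, z, direction_rule)
    p = 2.0 * stats.norm.sf(np.abs(z))  # normal-theory reference, not a calibrated p
    label = threshold_label or f"|z|>{k:g}"
    return _assemble(pairs, "residual", label, deviator, low, z, np.abs(z), p, z_aligned)


def classify_grs_rank(
    pairs: pd.DataFrame,
    null: RankNullStore,
    alpha: float = 1e-3,
    sided: str = "two",
    tie_seed: int = 0,
    z_aligned: float = 1.0,
    threshold_label: str | None = None,
    residual_direction: str = "pheno_on_score",
) -> CallSet:
    """Rank-matched empirical p-values against a simulated null store.

    Each individual is ranked by score (ties broken by a seeded random
    permutation); the observed phenotype at rank k is compared with the B
    null phenotypes at the same rank. With extremity measured about the
    per-rank null median, ``p = (r + 1) / (B + 1)`` where r counts null
    values at least as extreme; the smallest attainable p is 1 / (B + 1).
    Direction follows the sign of (observed - per-rank median).
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must be in (0, 1), got {alpha}")
    if sided not in ("two", "lower", "upper"):
        raise ConfigError(f"unknown sidedness {sided!r}")
    if null.n != len(pairs):
        raise DataError(
            f"rank-null store built for n={null.n}, cohort has n={len(pairs)}"
        )
    x, y = _pairs_arrays(pairs)
    rng = np.random.default_rng(tie_seed)
    ranks = _rank_by_score(x, rng)
    med = null.medians
    y_at_rank = np.empty(null.n)
    y_at_rank[ranks] = y
    dev_obs = y_at_rank - med
    dev_null = null.values - med[None, :]
    if sided == "two":
        r = (np.abs(dev_null) >= np.abs(dev_obs)[None, :]).sum(axis=0)
    elif sided == "lower":
        r = (dev_null <= dev_obs[None, :]).sum(axis=0)
    else:
        r = (dev_null >= dev_obs[None, :]).sum(axis=0)
    p_at_rank = (r + 1) / (null.B + 1)
    p = p_at_rank[ranks]
    extremity = np.abs(dev_obs)[ranks] if sided == "two" else dev_obs[ranks]
    deviator = p < alpha
    low = dev_obs[ranks] < 0
    z = residual_z(pairs, residual_direction)
    label = threshold_label or f"P<{alpha:g}"
    return _assemble(pairs, "grs_rank", label, deviator, low, z, extremity, p, z_aligned)


def centile_fences(
    pairs: pd.DataFrame, k_iqr: float = 1.5, bins: int = 100
) -> pd.DataFrame:
    """Tukey fences of the phenotype within each equal-count score bin.

    Quartiles use linear interpolation between order statistics. Returns one
    row per bin: bin, n, q1, q3, iqr, lower, upper.
    """
    if bins < 1:
        raise ConfigError(f"bins must be >= 1, got {bins}")
    x, y = _pairs_arrays(pairs)
    order = np.argsort(x, kind="stable")
    rows = []
    for b, chunk in enumerate(np.array_split(order, bins), start=1):
        q1, q3 = np.percentile(y[chunk], [25, 75])
        iqr = q3 - q1
        rows.append(
            {
                "bin": b,
                "n": len(chunk),
                "q1": q1,
                "q3": q3,
                "iqr": iqr,
                "lower": q1 - k_iqr * iqr,
                "upper": q3 + k_iqr * iqr,
            }
        )
    return pd.DataFrame(rows)


def classify_centile(
    pairs: pd.DataFrame,
    k_iqr: float = 1.5,
    bins: int = 100,
    z_aligned: float = 1.0,
    threshold_label: str | None = None,
    residual_direction: str = "pheno_on_score",
) -> CallSet:
    """Deviator iff phenotype falls outside the Tukey fences of its score bin.

    Direction is intrinsic (below the lower vs above the upper fence). The
    reported statistic is the exceedance beyond the nearer fence (0 inside).
    """
    if len(pairs) < bins * 4:
        import warnings

        warnings.warn(
            f"n={len(pairs)} is small for {bins} bins; quartiles will be noisy",
            stacklevel=2,
        )
    x, y = _pairs_arrays(pairs)
    fences = centile_fences(pairs, k_iqr=k_iqr, bins=bins)
    order = np.argsort(x, kind="stable")
    low = np.zeros(len(pairs), dtype=bool)
    high = np.zeros(len(pairs), dtype=bool)
    exceed = np.zeros(len(pairs))
    for chunk, row in zip(np.array_split(order, bins), fences.itertuples()):
        yl = y[chunk]
        low[chunk] = yl < row.lower
        high[chunk] = yl > row.upper
        exceed[chunk] = np.maximum.reduce([row.lower - yl, yl - row.upper, np.zeros(len(yl))])
    deviator = low | high
    z = residual_z(pairs, residual_direction)
    label = threshold_label or f"{k_iqr:g}xIQR"
    return _assemble(
        pairs, "centile", label, deviator, low, z, exceed, np.full(len(pairs), np.nan), z_aligned
    )


def split_direction(
    calls: CallSet, pairs: pd.DataFrame, rule: str = "phenotype"
) -> CallSet:
    """Re-assign deviator direction by phenotype sign (default) or residual sign."""
    indexed = pairs.set_index("individual_id")
    if not calls.table["individual_id"].isin(indexed.index).all():
        raise DataError("callset and pairs cover different individuals")
    ordered = indexed.loc[calls.table["individual_id"]].reset_index()
    z = residual_z(ordered)
    is_dev = calls.table["status"].isin(["deviator_low", "deviator_high"]).to_numpy()
    low = _direction_low(ordered, z, rule)
    status = calls.table["status"].to_numpy(dtype=object).copy()
    status[is_dev] = np.where(low[is_dev], "deviator_low", "deviator_high")
    table = calls.table.copy()
    table["status"] = status
    return replace(calls, table=table)


def method_overlap(callsets: list[CallSet]) -> pd.DataFrame:
    """Pairwise percentage overlap of deviators, per direction.

    For ordered methods (A, B): 100 * |A intersect B| / |A|, 0 when A is
    empty. Mirrors the layout of cross-method overlap tables.
    """
    if not callsets:
        raise DataError("no callsets given")
    cohorts = [set(c.table["individual_id"]) for c in callsets]
    if any(c != cohorts[0] for c in cohorts[1:]):
        raise DataError("callsets cover different cohorts")
    rows = []
    for direction in ("deviator_low", "deviator_high"):
        sets = {c.label: c.ids(direction) for c in callsets}
        for la, A in sets.items():
            for lb, B in sets.items():
                pct = 100.0 * len(A & B) / len(A) if A else 0.0
                rows.append(
                    {"direction": direction, "method_a": la, "method_b": lb, "pct": pct}
                )
    return pd.DataFrame(rows)
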