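"""Enrichment statistics: deviator groups versus the aligned group.

Deviator groups are small (tens to hundreds of individuals against a
comparison group of tens of thousands), so zero cells are common; odds
ratios use the Haldane-Anscombe 0.5 correction whenever any cell is zero.
Continuous outcomes are rank-inverse normalised by default so regression
coefficients read as SDs of the outcome per unit exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import design_matrix, rint as _rint
from .errors import ConfigError, DataError

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "binary_enrichment",
    "continuous_enrichment",
    "disease_risk",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: (a, b) exposed/unexposed deviators, (c, d) aligned."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise DataError(f"negative cell count in {cells}")
        if self.a + self.b == 0:
            raise DataError("empty deviator group (a + b = 0)")
        if self.c + self.d == 0:
            raise DataError("empty aligned group (c + d = 0)")

    @property
    def n_deviator(self) -> int:
        return self.a + self.b

    @property
    def n_aligned(self) -> int:
        return self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    """An odds ratio or regression coefficient with its 95% CI and p-value."""

    estimate_type: str  # "odds_ratio" | "beta"
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n_deviator: int
    n_aligned: int
    model: str  # "fisher_exact" | "logistic" | "linear"
    covariates: tuple = ()
    converged: bool = True

    def to_row(self) -> dict:
        return {
            "estimate_type": self.estimate_type,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_deviator": self.n_deviator,
            "n_aligned": self.n_aligned,
            "model": self.model,
            "covariates": ",".join(self.covariates),
            "converged": self.converged,
        }


def _haldane(t: ContingencyTable) -> tuple[float, float, float, float]:
    cells = (t.a, t.b, t.c, t.d)
    if 0 in cells:
        return tuple(x + 0.5 for x in cells)
    return tuple(float(x) for x in cells)


def binary_enrichment(
    table: ContingencyTable, method: str = "fisher_exact"
) -> EnrichmentResult:
    """Odds ratio ad/bc with Wald 95% CI on the log scale.

    The Haldane-Anscombe 0.5 is added to every cell when any cell is zero.
    ``method`` selects the p-value: Fisher's exact test on the raw counts,
    or a logistic-regression Wald test (whose MLE odds ratio equals ad/bc
    in the saturated 2x2 model).
    """
    if method not in ("fisher_exact", "logistic"):
        raise ConfigError(f"unknown method {method!r}")
    a, b, c, d = _haldane(table)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    if method == "fisher_exact":
        _, p = stats.fisher_exact([[table.a, table.b], [table.c, table.d]])
    else:
        # weighted saturated logistic: outcome=exposed, predictor=deviator
        y = np.array([1.0, 0.0, 1.0, 0.0])
        X = sm.add_constant(np.array([1.0, 1.0, 0.0, 0.0]))
        fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=np.array([a, b, c, d])).fit()
        log_or, se = fit.params[1], fit.bse[1]
        p = float(fit.pvalues[1])
    return EnrichmentResult(
        estimate_type="odds_ratio",
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        p=float(p),
        n_deviator=table.n_deviator,
        n_aligned=table.n_aligned,
        model=method,
    )


def _design(
    status: np.ndarray,
    covariates: Optional[pd.DataFrame],
    covariate_names: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    parts = [np.ones((len(status), 1)), np.asarray(status, dtype=float)[:, None]]
    names = ["intercept", "status"]
    if covariate_names:
        if covariates is None:
            raise DataError("covariate_names given but no covariate table")
        X, cnames = design_matrix(covariates, covariate_names)
        parts.append(X)
        names.extend(cnames)
    X = np.hstack(parts)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DataError("rank-deficient design; check covariates for collinearity")
    return X, names


def _check_status(status: np.ndarray) -> np.ndarray:
    s = np.asarray(status, dtype=float)
    if len(np.unique(s)) < 2:
        raise DataError("status indicator is constant")
    return s


def continuous_enrichment(
    outcome: np.ndarray,
    status: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Sequence[str] = (),
    rint_outcome: bool = True,
) -> EnrichmentResult:
    """OLS of a continuous outcome on deviator status plus covariates.

    With ``rint_outcome`` (default) the outcome is rank-inverse normalised
    first, so the status coefficient is in outcome-SD units.
    """
    y = np.asarray(outcome, dtype=float)
    s = _check_status(status)
    if len(y) != len(s):
        raise DataError("outcome and status lengths differ")
    if rint_outcome:
        y = _rint(y)
    X, _ = _design(s, covariates, covariate_names)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params[1])
    if fit.ssr < 1e-12 * max(1.0, float(np.sum(y**2))):
        # exact fit: no residual variance, CI collapses to the point
        return EnrichmentResult(
            estimate_type="beta", estimate=beta, ci_low=beta, ci_high=beta, p=0.0,
            n_deviator=int(s.sum()), n_aligned=int((1 - s).sum()),
            model="linear", covariates=tuple(covariate_names),
        )
    se = float(fit.bse[1])
    return EnrichmentResult(
        estimate_type="beta",
        estimate=beta,
        ci_low=beta - _Z95 * se,
        ci_high=beta + _Z95 * se,
        p=float(fit.pvalues[1]),
        n_deviator=int(s.sum()),
        n_aligned=int((1 - s).sum()),
        model="linear",
        covariates=tuple(covariate_names),
    )


def disease_risk(
    outcome: np.ndarray,
    status: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    covariate_names: Sequence[str] = (),
) -> EnrichmentResult:
    """Logistic regression of a binary outcome on deviator status.

    Covariates typically include the measured phenotype itself (does the
    misalignment carry risk information beyond the measurement?). Complete
    separation or non-convergence is flagged (``converged=False``) rather
    than raised, with a NaN estimate.
    """
    y = np.asarray(outcome, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise DataError("disease outcome must be binary 0/1")
    s = _check_status(status)
    X, _ = _design(s, covariates, covariate_names)
    n_dev, n_ali = int(s.sum()), int((1 - s).sum())

    def _flagged() -> EnrichmentResult:
        return EnrichmentResult(
            estimate_type="odds_ratio", estimate=float("nan"),
            ci_low=float("nan"), ci_high=float("nan"), p=float("nan"),
            n_deviator=n_dev, n_aligned=n_ali, model="logistic",
            covariates=tuple(covariate_names), converged=False,
        )

    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        return _flagged()
    bse = np.asarray(fit.bse)
    if not fit.mle_retvals.get("converged", False) or not np.isfinite(bse[1]) or bse[1] > 1e3:
        return _flagged()
    log_or, se = float(fit.params[1]), float(bse[1])
    return EnrichmentResult(
        estimate_type="odds_ratio",
        estimate=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - _Z95 * se)),
        ci_high=float(np.exp(log_or + _Z95 * se)),
        p=float(fit.pvalues[1]),
        n_deviator=n_dev,
        n_aligned=n_ali,
        model="logistic",
        covariates=tuple(covariate_names),
    )
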