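"""Fixed-effects beta regression with a logit mean link and constant precision.

This is the "traditional" per-probe model: each mark (5-mC or 5-hmC) is
analyzed separately, with the beta value regressed on group plus covariates.
The response is Beta(mu * phi, (1 - mu) * phi) with
mu = inverse-logit(X @ coef) and a single precision phi = exp(log_precision)
per fit (the mean is modeled; dispersion is not regressed on covariates).
Fitting is delegated to statsmodels' ``BetaModel``; this module owns the
interface, validation, and Wald machinery the rest of the package uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.othermod.betareg import BetaModel

__all__ = ["BetaRegFit", "squeeze", "fit_betareg", "wald"]


@dataclass
class BetaRegFit:
    """Result of a fixed-effects beta regression.

    ``coef``/``se`` are indexed by design-matrix column name and live on the
    logit-mean scale; ``log_precision`` is the log of the beta precision phi.
    """

    coef: pd.Series
    se: pd.Series
    log_precision: float
    loglik: float
    converged: bool
    n_obs: int
    df_resid: float = float("inf")
    message: str = field(default="")


def squeeze(y, epsilon: float = 1e-6):
    """Clamp proportions into (0, 1): min(max(y, eps), 1 - eps).

    The beta likelihood is undefined at exactly 0 or 1; the low-beta filter
    removes most zero-heavy probes but boundary values can survive.
    Idempotent; works on scalars and arrays.
    """
    if not (0 < epsilon < 0.5):
        raise ValueError(f"squeeze epsilon must lie in (0, 0.5), got {epsilon!r}")
    return np.clip(y, epsilon, 1.0 - epsilon)


def _validate_design(X: pd.DataFrame, y: np.ndarray) -> None:
    if X.shape[0] != y.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} rows but response has {y.shape[0]}"
        )
    if X.isna().any().any():
        raise ValueError("design matrix contains missing entries")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("response values must lie strictly inside (0, 1); squeeze first")
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns: {list(X.columns)})"
        )


def fit_betareg(X: pd.DataFrame, y) -> BetaRegFit:
    """Maximum-likelihood beta regression of y on the columns of X.

    X must be full column rank with no missing entries (include the intercept
    column explicitly); y must be strictly inside (0, 1). Standard errors
    come from the inverse observed information. Non-convergence does not
    raise: the fit is returned with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    _validate_design(X, y)
    model = BetaModel(
        y, X.to_numpy(dtype=float), exog_precision=np.ones((len(y), 1))
    )
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence is reported via the flag
        res = model.fit(disp=False, maxiter=200)
    p = X.shape[1]
    coef = pd.Series(res.params[:p], index=X.columns)
    se = pd.Series(res.bse[:p], index=X.columns)
    converged = bool(res.mle_retvals.get("converged", True))
    if not np.all(np.isfinite(se.to_numpy())):
        converged = False
    return BetaRegFit(
        coef=coef,
        se=se,
        log_precision=float(res.params[-1]),
        loglik=float(res.llf),
        converged=converged,
        n_obs=len(y),
        df_resid=float(len(y) - (p + 1)),  # mean params + precision
        message="" if converged else "optimizer did not converge",
    )


def wald(fit, term: str) -> tuple[float, float]:
    """Two-sided Wald test of a single coefficient: z = coef/se.

    Accepts any fit object exposing ``coef``/``se`` Series (fixed-effects or
    mixed). The tail probability uses a Student-t reference with the fit's
    residual degrees of freedom (infinite df degenerates to the normal);
    small-sample ML fits have t-like Wald statistics, and the regression
    framework this package mirrors reports t-based summaries. Returns
    (z, p); for a non-converged fit p is NaN.
    """
    if term not in fit.coef.index:
        raise KeyError(
            f"unknown term {term!r}; available: {list(fit.coef.index)}"
        )
    if not fit.converged:
        return float("nan"), float("nan")
    z = float(fit.coef[term] / fit.se[term])
    df = getattr(fit, "df_resid", float("inf"))
    if np.isfinite(df) and df > 0:
        p = float(2.0 * stats.t.sf(abs(z), df))
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return z, min(p, 1.0) if np.isfinite(p) else p
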