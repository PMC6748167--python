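"""Per-probe mixed-effects beta regression for paired 5-mC / 5-hmC data.

The two marks measured at one CpG in one sample are treated as repeated
measures of a single outcome, "DNA modification". For probe p and sample i
with mark j in {5mC, 5hmC}:

    y_ij ~ Beta(mu_ij * phi, (1 - mu_ij) * phi)
    logit(mu_ij) = X_ij @ coef + u_i,       u_i ~ Normal(0, sigma_b^2)

The fixed effects are the full factorial of group and modification category
(both main effects plus the group x mod interaction) with additive
covariates; treatment coding uses the control group and the 5-mC level as
references. Under that coding a positive interaction coefficient means the
case group shifts the balance toward a greater proportion of 5-hmC at the
probe; swapping either reference flips the sign. The shared random
intercept u_i absorbs the within-sample correlation between the two marks
that separate models ignore.

The marginal likelihood integrates u_i out by adaptive Gauss-Hermite
quadrature: for each sample the integrand is re-centered at its conditional
mode (found by Newton iteration) and re-scaled by its conditional curvature,
so a small number of nodes (9 by default) is accurate even when the
posterior of u_i is much narrower than its prior. With sigma_b -> 0 the
quadrature collapses and the marginal likelihood equals the independent
beta-regression likelihood exactly.

An optional second, independent random intercept per batch is available
(off by default); it is integrated by an outer prior-scaled Gauss-Hermite
rule nested around the adaptive per-sample integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .betareg import BetaRegFit, fit_betareg, squeeze

__all__ = [
    "MOD_LEVELS",
    "MixedFit",
    "InteractionResult",
    "to_long",
    "build_design",
    "fit_paired",
    "interaction_test",
    "interaction_lrt",
    "main_effect_model",
]

MOD_LEVELS = ("5mC", "5hmC")
_SIGMA_FLOOR = 1e-6
_INTERACTION = "group:mod_5hmC"


@dataclass
class MixedFit:
    """Fitted per-probe mixed model.

    ``coef``/``se`` index the fixed effects (intercept, group, mod_5hmC,
    group:mod_5hmC, covariates); ``sigma_b`` is the random-intercept SD,
    ``sigma_batch`` the optional batch-intercept SD (NaN when disabled).
    """

    coef: pd.Series
    se: pd.Series
    sigma_b: float
    log_precision: float
    loglik: float
    converged: bool
    quad_points: int
    n_obs: int
    df_resid: float = float("inf")
    sigma_batch: float = float("nan")
    message: str = field(default="")


@dataclass(frozen=True)
class InteractionResult:
    """Wald test of the group x modification-category interaction."""

    coef: float
    z: float
    p: float
    direction: str  # "toward-5hmC", "toward-5mC", or "none"


def to_long(
    mc: pd.DataFrame,
    hmc: pd.DataFrame,
    sheet: pd.DataFrame,
    probe: str,
    squeeze_eps: float = 1e-6,
) -> pd.DataFrame:
    """Reshape one probe's paired beta values into long (repeated-measures) form.

    Returns a frame with one row per sample x mark: columns ``sample_id``,
    ``group``, ``mod_cat``, ``y`` (squeezed into (0,1)), plus every covariate
    column of the sample sheet. Samples present in the sheet but absent from
    the matrices are an error; an entirely missing mark is an error (the
    missingness filter should have removed such probes).
    """
    for name, mat in (("5-mC", mc), ("5-hmC", hmc)):
        if probe not in mat.index:
            raise KeyError(f"probe {probe!r} absent from the {name} matrix")
    samples = sheet["sample_id"].tolist()
    for name, mat in (("5-mC", mc), ("5-hmC", hmc)):
        absent = [s for s in samples if s not in mat.columns]
        if absent:
            raise ValueError(f"samples {absent} absent from the {name} matrix")
        if mat.loc[probe, samples].isna().all():
            raise ValueError(
                f"probe {probe!r} has no observed {name} values; "
                "apply the missingness filter first"
            )
    rows = []
    covar_cols = [c for c in sheet.columns if c != "sample_id"]
    for _, srow in sheet.iterrows():
        sid = srow["sample_id"]
        for level, mat in zip(MOD_LEVELS, (mc, hmc)):
            rec = {
                "sample_id": sid,
                "mod_cat": level,
                "y": float(squeeze(mat.loc[probe, sid], squeeze_eps)),
            }
            for c in covar_cols:
                rec[c] = srow[c]
            rows.append(rec)
    return pd.DataFrame(rows)


def _group_codes(group: pd.Series, reference: str | None) -> tuple[np.ndarray, str, str]:
    levels = list(pd.unique(group))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    if reference is not None:
        if reference not in levels:
            raise ValueError(f"reference group {reference!r} not in {levels}")
        ref = reference
    else:
        ref = levels[0]
    other = [l for l in levels if l != ref][0]
    return (group == other).astype(float).to_numpy(), ref, other


def build_design(
    obs: pd.DataFrame,
    covariates: tuple[str, ...] = ("glial_proportion", "age"),
    reference_group: str | None = None,
    interaction: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Treatment-coded full-factorial design for the long frame.

    Columns: intercept, group (case indicator), mod_5hmC (5-hmC indicator),
    group:mod_5hmC (unless ``interaction=False``, the reduced model of the
    likelihood-ratio test), then covariates in the order given.
    """
    g, _, _ = _group_codes(obs["group"], reference_group)
    m = (obs["mod_cat"] == MOD_LEVELS[1]).astype(float).to_numpy()
    data = {
        "intercept": np.ones(len(obs)),
        "group": g,
        "mod_5hmC": m,
    }
    if interaction:
        data[_INTERACTION] = g * m
    for c in covariates:
        if c not in obs.columns:
            raise KeyError(f"covariate {c!r} absent from observations")
        data[c] = obs[c].to_numpy(dtype=float)
    X = pd.DataFrame(data, index=obs.index)
    return X, obs["y"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# beta log-density and its derivatives on the linear-predictor scale

_ETA_CLIP = 30.0


def _mu(eta: np.ndarray) -> np.ndarray:
    return special.expit(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def _beta_ll(ly: np.ndarray, l1my: np.ndarray, eta: np.ndarray, phi: float) -> np.ndarray:
    """Beta log-density given precomputed log(y) and log1p(-y)."""
    mu = _mu(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    return (
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * ly
        + (b - 1.0) * l1my
    )


def _beta_ll_d12(logit_y: np.ndarray, eta: np.ndarray, phi: float):
    """First and second derivatives of the beta log-density wrt eta."""
    mu = _mu(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    dl_dmu = phi * (logit_y - special.digamma(a) + special.digamma(b))
    d2l_dmu2 = -(phi**2) * (special.polygamma(1, a) + special.polygamma(1, b))
    w = mu * (1.0 - mu)
    d1 = dl_dmu * w
    d2 = d2l_dmu2 * w * w + dl_dmu * (1.0 - 2.0 * mu) * w
    return d1, d2


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite marginal likelihood

def _conditional_modes(ydat, eta2, phi, sigma, u0, max_iter=40, tol=1e-11):
    """Newton solve for the per-sample mode of the random-intercept integrand.

    eta2 has shape (S, r); returns (u_hat, curvature) of shape (S,).
    """
    u = u0.copy()
    inv_var = 1.0 / sigma**2
    gpp = None
    for _ in range(max_iter):
        d1, d2 = _beta_ll_d12(ydat.logit_y, eta2 + u[:, None], phi)
        gp = d1.sum(axis=1) - u * inv_var
        gpp = np.minimum(d2.sum(axis=1) - inv_var, -1e-8)
        step = gp / gpp
        np.clip(step, -2.0, 2.0, out=step)
        u -= step
        if np.max(np.abs(step)) < tol:
            break
    if gpp is None:  # pragma: no cover - max_iter >= 1 always
        gpp = np.full_like(u, -1.0 / sigma**2)
    return u, gpp


class _YData:
    """Precomputed response transforms shared across likelihood evaluations."""

    __slots__ = ("y2", "ly", "l1my", "logit_y", "ly3", "l1my3")

    def __init__(self, y2: np.ndarray):
        self.y2 = y2
        self.ly = np.log(y2)
        self.l1my = np.log1p(-y2)
        self.logit_y = self.ly - self.l1my
        self.ly3 = self.ly[:, :, None]
        self.l1my3 = self.l1my[:, :, None]


def _marginal_loglik(ydat, eta2, phi, sigma, nodes, log_wts, u_cache):
    """Sum over samples of log integral of the beta likelihood against the
    Normal(0, sigma^2) random-intercept density, by adaptive GH quadrature."""
    u_hat, gpp = _conditional_modes(ydat, eta2, phi, sigma, u_cache)
    u_cache[:] = u_hat
    sig_hat = 1.0 / np.sqrt(-gpp)
    # quadrature points per sample: u_hat + sqrt(2) * sig_hat * x_k
    z = u_hat[:, None] + np.sqrt(2.0) * sig_hat[:, None] * nodes[None, :]
    ll = _beta_ll(
        ydat.ly3, ydat.l1my3, eta2[:, :, None] + z[:, None, :], phi
    ).sum(axis=1)
    log_prior = -0.5 * (z / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2.0 * np.pi)
    integrand = log_wts[None, :] + nodes[None, :] ** 2 + ll + log_prior
    per_sample = (
        0.5 * np.log(2.0) + np.log(sig_hat) + special.logsumexp(integrand, axis=1)
    )
    return float(per_sample.sum())


def _start_values(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    eta0 = special.logit(np.clip(y, 1e-4, 1 - 1e-4))
    beta0, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    mu0 = _mu(X @ beta0)
    resid_var = float(np.var(y - mu0))
    if resid_var <= 0:
        phi0 = 50.0
    else:
        phi0 = float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0)
    return beta0, float(np.clip(phi0, 2.0, 200.0))


def _numeric_hessian(fun, x, step=1e-4):
    n = len(x)
    H = np.empty((n, n))
    h = step * np.maximum(1.0, np.abs(x))
    f0 = fun(x)
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        fpp = fun(x + ei); fmm = fun(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, n):
            ej = np.zeros(n); ej[j] = h[j]
            fpj = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmj = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpj - fpm - fmp + fmj) / (4 * h[i] * h[j])
    return H


def fit_paired(
    obs: pd.DataFrame,
    covariates: tuple[str, ...] = ("glial_proportion", "age"),
    include_batch_re: bool = False,
    n_quad: int = 9,
    reference_group: str | None = None,
    sigma_b_fixed: float | None = None,
    interaction: bool = True,
) -> MixedFit:
    """Fit the paired repeated-measures mixed beta regression for one probe.

    ``obs`` is a long frame from :func:`to_long` (two rows per sample, one
    per modification category). Maximizes the marginal likelihood over the
    fixed effects, log sigma_b and log phi with L-BFGS-B; sigma_b is floored
    at 1e-6 on the natural scale. ``sigma_b_fixed`` holds the random-
    intercept SD at a known value instead of estimating it (0 is mapped to
    the floor, under which the quadrature degenerates and the model reduces
    to an independent beta regression). Non-convergence is reported via the
    ``converged`` flag, never raised.
    """
    obs = obs.sort_values(["sample_id", "mod_cat"], kind="stable").reset_index(drop=True)
    counts = obs.groupby("sample_id", sort=False).size()
    if not (counts == 2).all():
        bad = counts[counts != 2]
        raise ValueError(
            f"expected exactly 2 rows (one per modification) per sample; "
            f"offending samples: {dict(bad)}"
        )
    levels = set(obs["mod_cat"])
    if levels != set(MOD_LEVELS):
        raise ValueError(f"mod_cat levels {levels} != {set(MOD_LEVELS)}")
    per_group = obs.drop_duplicates("sample_id").groupby("group").size()
    if (per_group < 4).any() or len(per_group) < 2:
        raise ValueError(
            f"need >=4 distinct samples in each of 2 groups, got {dict(per_group)}"
        )

    X_df, y = build_design(obs, covariates, reference_group, interaction=interaction)
    if np.linalg.matrix_rank(X_df.to_numpy(dtype=float)) < X_df.shape[1]:
        raise ValueError(f"singular design matrix (columns {list(X_df.columns)})")
    S = len(counts)
    ydat = _YData(y.reshape(S, 2))

    # optimize on a standardized covariate scale (conditioning), then map
    # coefficients and covariance back to the original scale
    X = X_df.to_numpy(dtype=float).copy()
    p = X.shape[1]
    T = np.eye(p)  # theta_orig = T @ theta_scaled for the fixed effects
    for j, col in enumerate(X_df.columns):
        if col in covariates:
            m, s = X[:, j].mean(), X[:, j].std()
            if s <= 0:
                raise ValueError(f"covariate {col!r} is constant")
            X[:, j] = (X[:, j] - m) / s
            T[j, j] = 1.0 / s
            T[0, j] = -m / s

    batch_groups = None
    if include_batch_re:
        if "batch" not in obs.columns:
            raise ValueError("include_batch_re=True requires a 'batch' column")
        sample_batch = obs.drop_duplicates("sample_id")["batch"].to_numpy()
        batch_groups = [
            np.flatnonzero(sample_batch == b) for b in pd.unique(sample_batch)
        ]

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_wts = np.log(weights)
    beta0, phi0 = _start_values(X, y)
    u_cache = np.zeros(S)

    def negloglik(theta):
        beta = theta[:p]
        sigma = np.exp(theta[p])
        phi = np.exp(theta[p + 1])
        eta2 = (X @ beta).reshape(S, 2)
        if batch_groups is None:
            ll = _marginal_loglik(ydat, eta2, phi, sigma, nodes, log_wts, u_cache)
        else:
            ll = _batch_marginal(
                ydat, eta2, phi, sigma, np.exp(theta[p + 2]),
                batch_groups, nodes, log_wts, u_cache,
            )
        return -ll if np.isfinite(ll) else 1e12

    if sigma_b_fixed is not None:
        log_sig0 = float(np.log(max(sigma_b_fixed, _SIGMA_FLOOR)))
        sigma_bounds = (log_sig0, log_sig0)
    else:
        log_sig0 = np.log(0.3)
        sigma_bounds = (np.log(_SIGMA_FLOOR), np.log(50.0))
    x0 = np.concatenate([beta0, [log_sig0, np.log(phi0)]])
    bounds = [(None, None)] * p + [
        sigma_bounds,
        (np.log(1e-2), np.log(1e6)),
    ]
    if batch_groups is not None:
        x0 = np.concatenate([x0, [np.log(0.2)]])
        bounds.append((np.log(_SIGMA_FLOOR), np.log(50.0)))

    with np.errstate(all="ignore"):
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-7},
        )
    theta = res.x
    converged = bool(res.success)
    message = "" if converged else str(res.message)

    # observed information; drop variance parameters stuck at their floor
    # (flat directions make the full Hessian numerically singular there)
    free = list(range(p + 2 + (1 if batch_groups is not None else 0)))
    for k in free[p:]:
        if k == p + 1:
            continue  # log phi is always estimated
        if theta[k] < np.log(_SIGMA_FLOOR) + 1e-3 or (
            k == p and sigma_b_fixed is not None
        ):
            free.remove(k)
    se = np.full(p, np.nan)
    with np.errstate(all="ignore"):
        H = _numeric_hessian(lambda t: negloglik(_embed(theta, free, t)), theta[free])
        try:
            cov = np.linalg.inv(H)
            cov_fixed = T @ cov[:p, :p] @ T.T
            d = np.diag(cov_fixed)
            if np.all(d > 0):
                se = np.sqrt(d)
            else:
                converged, message = False, "non-positive-definite information"
        except np.linalg.LinAlgError:
            converged, message = False, "singular information matrix"

    return MixedFit(
        coef=pd.Series(T @ theta[:p], index=X_df.columns),
        se=pd.Series(se, index=X_df.columns),
        sigma_b=float(np.exp(theta[p])),
        log_precision=float(theta[p + 1]),
        loglik=float(-res.fun),
        converged=converged,
        quad_points=n_quad,
        n_obs=len(y),
        # paired-design residual df: samples minus the number of groups;
        # the classical error df for a between x within interaction with
        # two within-subject levels
        df_resid=float(S - per_group.size),
        sigma_batch=(
            float(np.exp(theta[p + 2])) if batch_groups is not None else float("nan")
        ),
        message=message,
    )


def _embed(theta, free, t):
    full = theta.copy()
    full[free] = t
    return full


def _batch_marginal(ydat, eta2, phi, sigma, sigma_batch, batch_groups,
                    nodes, log_wts, u_cache):
    """Nested integral: outer prior-scaled GH over the batch intercept,
    inner adaptive GH over the per-sample intercept."""
    total = 0.0
    for members in batch_groups:
        ydat_b = _YData(ydat.y2[members])
        eb = eta2[members]
        per_node = np.empty(len(nodes))
        for k, x in enumerate(nodes):
            v = np.sqrt(2.0) * sigma_batch * x
            cache = u_cache[members].copy()
            per_node[k] = _marginal_loglik(
                ydat_b, eb + v, phi, sigma, nodes, log_wts, cache
            )
        total += special.logsumexp(log_wts + per_node) - 0.5 * np.log(np.pi)
    return total


def interaction_test(fit: MixedFit) -> InteractionResult:
    """Wald test of the group x modification interaction coefficient.

    Under treatment coding (control and 5-mC as references) a positive
    coefficient is a shift toward a greater proportion of 5-hmC in the case
    group; negative, toward 5-mC.
    """
    coef = float(fit.coef[_INTERACTION])
    if not fit.converged:
        return InteractionResult(coef, float("nan"), float("nan"), "none")
    se = float(fit.se[_INTERACTION])
    z = coef / se
    df = getattr(fit, "df_resid", float("inf"))
    if np.isfinite(df) and df > 0:
        p = min(float(2.0 * stats.t.sf(abs(z), df)), 1.0)
    else:
        p = min(float(2.0 * stats.norm.sf(abs(z))), 1.0)
    if coef > 0:
        direction = "toward-5hmC"
    elif coef < 0:
        direction = "toward-5mC"
    else:
        direction = "none"
    return InteractionResult(coef, z, p, direction)


def interaction_lrt(
    obs: pd.DataFrame,
    covariates: tuple[str, ...] = ("glial_proportion", "age"),
    n_quad: int = 9,
    reference_group: str | None = None,
) -> tuple[float, float]:
    """Likelihood-ratio test of the interaction: full vs no-interaction fit.

    Returns (LR statistic, p) with p from chi-square(1). An alternative to
    the default Wald test; roughly twice the cost (two marginal fits).
    NaN p when either fit fails to converge.
    """
    full = fit_paired(obs, covariates=covariates, n_quad=n_quad,
                      reference_group=reference_group)
    reduced = fit_paired(obs, covariates=covariates, n_quad=n_quad,
                         reference_group=reference_group, interaction=False)
    if not (full.converged and reduced.converged):
        return float("nan"), float("nan")
    lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return lr, float(stats.chi2.sf(lr, df=1))


def main_effect_model(
    obs: pd.DataFrame,
    mod_subset: str,
    covariates: tuple[str, ...] = ("glial_proportion", "age"),
    reference_group: str | None = None,
) -> BetaRegFit:
    """Separate fixed-effects model for one modification category.

    Restricts the long frame to ``mod_subset`` (one of {"5mC", "5hmC"}) and
    fits group + covariates by :func:`dualmark.betareg.fit_betareg` — this
    reproduces the traditional per-mark analysis exactly.
    """
    if mod_subset not in MOD_LEVELS:
        raise ValueError(f"mod_subset must be one of {MOD_LEVELS}, got {mod_subset!r}")
    sub = obs[obs["mod_cat"] == mod_subset].reset_index(drop=True)
    if sub["group"].nunique() < 2:
        raise ValueError("subset contains a single group; cannot test a group effect")
    g, _, _ = _group_codes(sub["group"], reference_group)
    data = {"intercept": np.ones(len(sub)), "group": g}
    for c in covariates:
        data[c] = sub[c].to_numpy(dtype=float)
    X = pd.DataFrame(data)
    return fit_betareg(X, sub["y"].to_numpy(dtype=float))
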