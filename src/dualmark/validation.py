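"""Monte-Carlo validation studies of the estimators and tests.

Each function here re-derives one calibration or operating-characteristic
property from scratch — estimator-vs-oracle agreement, confidence-interval
coverage, type-I error, power, sensitivity — by simulating data with
:mod:`dualmark.simulate` and running the package's own estimation and
testing code. They are shared by the test suite and by the reproduction
script, which only differ in the problem sizes they request.

Oracles used here (the likelihood grid searches, the step-up formula) are
written directly from the mathematical definition and share no code with
the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .betareg import fit_betareg, wald
from .inference import bh_adjust
from .mixed import build_design, fit_paired, interaction_test, main_effect_model, to_long
from .mle import SignalPair, estimate_paired_mle
from .simulate import EffectSpec, SimConfig, generate_dataset

__all__ = [
    "grid_mle_oracle",
    "mle_oracle_max_error",
    "simplex_max_deviation",
    "betareg_calibration",
    "mixed_reduction_max_diff",
    "interaction_type1_rate",
    "scenario_b_power",
    "scenario_a_sensitivity",
    "bh_oracle_max_error",
]


# ---------------------------------------------------------------------------
# constrained-MLE oracle

def grid_mle_oracle(m_bs, n_bs, m_ox, n_ox, step=1e-3):
    """Brute-force argmax of the joint binomial log-likelihood on a grid.

    Evaluates log Binom(m_ox; n_ox, beta_mc) + log Binom(m_bs; n_bs,
    beta_mc + beta_hmc) over the full 2-D grid of feasible
    (beta_mc, total) pairs at the given step.
    """
    g = np.arange(0.0, 1.0 + step / 2, step)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_ox = stats.binom.logpmf(m_ox, n_ox, g)  # term in beta_mc
        ll_bs = stats.binom.logpmf(m_bs, n_bs, g)  # term in beta_mc + beta_hmc
    # total modification must be >= beta_mc (beta_hmc >= 0)
    joint = ll_ox[:, None] + ll_bs[None, :]
    joint[np.tril_indices_from(joint, k=-1)] = -np.inf
    i, j = np.unravel_index(np.argmax(joint), joint.shape)
    return g[i], g[j] - g[i]


def mle_oracle_max_error(n_pairs: int = 500, seed: int = 0, step: float = 1e-3):
    """Max per-coordinate gap between the closed-form MLE and the grid oracle."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        n_bs = int(rng.integers(10, 201))
        n_ox = int(rng.integers(10, 201))
        m_bs = int(rng.integers(0, n_bs + 1))
        m_ox = int(rng.integers(0, n_ox + 1))
        call = estimate_paired_mle(SignalPair(m_bs, n_bs, m_ox, n_ox))
        mc_g, hmc_g = grid_mle_oracle(m_bs, n_bs, m_ox, n_ox, step=step)
        worst = max(worst, abs(call.beta_mc - mc_g), abs(call.beta_hmc - hmc_g))
    return worst


def simplex_max_deviation(n_calls: int = 2000, seed: int = 0) -> float:
    """Max |beta_mc + beta_hmc + beta_c - 1| over random estimation calls."""
    from .mle import estimate_naive

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_calls):
        if rng.random() < 0.5:
            n_bs = int(rng.integers(1, 200))
            n_ox = int(rng.integers(1, 200))
            call = estimate_paired_mle(
                SignalPair(
                    int(rng.integers(0, n_bs + 1)), n_bs,
                    int(rng.integers(0, n_ox + 1)), n_ox,
                )
            )
        else:
            call = estimate_naive(rng.random(), rng.random())
        worst = max(worst, abs(call.beta_mc + call.beta_hmc + call.beta_c - 1.0))
    return worst


# ---------------------------------------------------------------------------
# fixed-effects beta regression calibration

def betareg_calibration(
    n_sims: int = 1000,
    n_obs: int = 35,
    phi: float = 30.0,
    group_coef: float = 0.5,
    seed: int = 0,
):
    """Bias and Wald 95% CI coverage of the group coefficient.

    Simulates ``n_sims`` probes from the fixed-effects beta-regression model
    itself (logit mean = intercept + group_coef * case + covariates) and
    refits each; returns (mean error, coverage, n_converged).
    """
    rng = np.random.default_rng(seed)
    n_case = int(round(n_obs * 22 / 35))
    case = np.r_[np.zeros(n_obs - n_case), np.ones(n_case)]
    errors, covered = [], []
    for _ in range(n_sims):
        glial = rng.uniform(0.3, 0.7, n_obs)
        eta = -0.5 + group_coef * case + 0.5 * (glial - glial.mean())
        mu = expit(eta)
        y = rng.beta(mu * phi, (1 - mu) * phi)
        X = pd.DataFrame(
            {"intercept": np.ones(n_obs), "group": case, "glial_proportion": glial}
        )
        fit = fit_betareg(X, y)
        if not fit.converged:
            continue
        est, se = fit.coef["group"], fit.se["group"]
        crit = stats.t.ppf(0.975, fit.df_resid)  # matches the Wald p reference
        errors.append(est - group_coef)
        covered.append(abs(est - group_coef) <= crit * se)
    return float(np.mean(errors)), float(np.mean(covered)), len(errors)


# ---------------------------------------------------------------------------
# mixed model properties

def _default_sim(n_probes, seed, sigma_b=0.5, effects=()):
    return SimConfig(
        n_probes=n_probes,
        zero_inflation=0.0,
        sigma_b=sigma_b,
        hmc_mean_range=(0.12, 0.3),
        effects=tuple(effects),
        seed=seed,
    )


def mixed_reduction_max_diff(n_reps: int = 10, seed: int = 0) -> float:
    """Max fixed-effect gap between the paired model (sigma_b held at 0)
    and the independent beta regression, on independent-row data."""
    worst = 0.0
    for r in range(n_reps):
        cfg = _default_sim(1, seed=seed + r, sigma_b=0.0)
        study = generate_dataset(cfg)
        obs = to_long(study.mc, study.hmc, study.sheet, study.mc.index[0])
        mf = fit_paired(obs, sigma_b_fixed=0.0)
        X, y = build_design(obs)
        bf = fit_betareg(X, y)
        worst = max(
            worst, float(np.max(np.abs(mf.coef.to_numpy() - bf.coef.to_numpy())))
        )
    return worst


def interaction_type1_rate(
    n_probes: int = 2000, seed: int = 0, alpha: float = 0.05
):
    """Empirical rejection rate of the interaction test under the null.

    All probes are null (no group effects on either mark); data follow the
    paired model's own assumptions (shared sample intercept, beta noise).
    Returns (rate, n_tested).
    """
    study = generate_dataset(_default_sim(n_probes, seed))
    pvals = []
    for probe in study.mc.index:
        obs = to_long(study.mc, study.hmc, study.sheet, probe)
        fit = fit_paired(obs)
        it = interaction_test(fit)
        if np.isfinite(it.p):
            pvals.append(it.p)
    pvals = np.asarray(pvals)
    return float(np.mean(pvals < alpha)), len(pvals)


def scenario_b_power(
    n_probes: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    transfer: float = 0.05,
    mc_mean: float = 0.45,
    hmc_mean: float = 0.15,
):
    """Power of the paired interaction test vs each separate test when the
    truth is a constant-total 5-mC -> 5-hmC shift (matched alpha, raw p)."""
    effect = EffectSpec(
        n_probes=n_probes, scenario="B", transfer=transfer,
        mc_mean=mc_mean, hmc_mean=hmc_mean,
    )
    study = generate_dataset(_default_sim(n_probes, seed, effects=[effect]))
    p_int, p_mc, p_hmc = [], [], []
    for probe in study.mc.index:
        obs = to_long(study.mc, study.hmc, study.sheet, probe)
        it = interaction_test(fit_paired(obs))
        if np.isfinite(it.p):
            p_int.append(it.p)
        for store, level in ((p_mc, "5mC"), (p_hmc, "5hmC")):
            f = main_effect_model(obs, level)
            _, p = wald(f, "group")
            if np.isfinite(p):
                store.append(p)
    return {
        "paired": float(np.mean(np.asarray(p_int) < alpha)),
        "mc": float(np.mean(np.asarray(p_mc) < alpha)),
        "hmc": float(np.mean(np.asarray(p_hmc) < alpha)),
        "n": len(p_int),
    }


def scenario_a_sensitivity(
    n_probes: int = 500,
    seed: int = 0,
    sep_p: float = 0.001,
    dip_fdr: float = 0.05,
    mc_effect: float = -1.0,
    hmc_effect: float = 0.5,
):
    """Among probes significant in BOTH separate models (raw p < sep_p),
    the fraction that are DIPs at the given FDR.

    Scenario-A probes shift 5-mC down and 5-hmC up; FDR is computed over
    the full simulated probe set. Returns (fraction, n_overlap, n_dip).
    """
    effect = EffectSpec(
        n_probes=n_probes, scenario="A", mc_effect=mc_effect,
        hmc_effect=hmc_effect, mc_mean=0.5, hmc_mean=0.2,
    )
    study = generate_dataset(_default_sim(n_probes, seed, effects=[effect]))
    rows = []
    for probe in study.mc.index:
        obs = to_long(study.mc, study.hmc, study.sheet, probe)
        rec = {"probe": probe}
        for key, level in (("mc", "5mC"), ("hmc", "5hmC")):
            _, rec[key] = wald(main_effect_model(obs, level), "group")
        rec["int"] = interaction_test(fit_paired(obs)).p
        rows.append(rec)
    frame = pd.DataFrame(rows)
    frame["int_q"] = bh_adjust(frame["int"].to_numpy())
    both = (frame["mc"] < sep_p) & (frame["hmc"] < sep_p)
    dip = frame["int_q"] < dip_fdr
    n_both = int(both.sum())
    frac = float((both & dip).sum() / n_both) if n_both else float("nan")
    return frac, n_both, int(dip.sum())


# ---------------------------------------------------------------------------
# BH oracle

def _bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j, capped."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_i, idx in enumerate(order, start=1):
        candidates = [
            p[order[j - 1]] * m / j for j in range(rank_i, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def bh_oracle_max_error(n_vectors: int = 1000, seed: int = 0) -> float:
    """Max |bh_adjust - step-up oracle| over random p-vectors (len 1..500)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        m = int(rng.integers(1, 501))
        p = rng.random(m)
        if rng.random() < 0.2:  # exercise ties
            p = np.round(p, 2)
        worst = max(
            worst, float(np.max(np.abs(bh_adjust(p) - _bh_stepup_oracle(p))))
        )
    return worst
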