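"""Paired repeated-measures mixed beta regression."""

import numpy as np
import pandas as pd
import pytest

from dualmark.betareg import fit_betareg
from dualmark.mixed import (
    build_design,
    fit_paired,
    interaction_lrt,
    interaction_test,
    main_effect_model,
    to_long,
)


class TestToLong:
    def test_shape_and_identity(self, paired_study):
        st = paired_study
        probe = st.mc.index[0]
        obs = to_long(st.mc, st.hmc, st.sheet, probe)
        assert len(obs) == 2 * len(st.sheet)
        assert set(obs["mod_cat"]) == {"5mC", "5hmC"}
        sid = st.sheet["sample_id"].iloc[3]
        row = obs[(obs.sample_id == sid) & (obs.mod_cat == "5mC")]
        assert row["y"].iloc[0] == pytest.approx(st.mc.loc[probe, sid])

    def test_missing_probe_raises(self, paired_study):
        st = paired_study
        with pytest.raises(KeyError, match="nope"):
            to_long(st.mc, st.hmc, st.sheet, "nope")

    def test_entirely_missing_mark_raises(self, paired_study):
        st = paired_study
        hmc = st.hmc.copy()
        probe = st.mc.index[0]
        hmc.loc[probe] = np.nan
        with pytest.raises(ValueError, match="missingness"):
            to_long(st.mc, hmc, st.sheet, probe)

    def test_values_are_squeezed(self, paired_study):
        st = paired_study
        hmc = st.hmc.copy()
        probe = st.mc.index[0]
        hmc.loc[probe, hmc.columns[0]] = 0.0
        obs = to_long(st.mc, hmc, st.sheet, probe, squeeze_eps=1e-6)
        assert obs["y"].min() >= 1e-6


def _symmetric_obs():
    """Both groups contain the same multiset of (y_mc, y_hmc) pairs."""
    pairs = [(0.5, 0.1), (0.7, 0.3), (0.4, 0.2), (0.6, 0.25)]
    rows = []
    k = 0
    for group in ("control", "case"):
        for y_mc, y_hmc in pairs:
            sid = f"s{k}"
            k += 1
            rows.append({"sample_id": sid, "group": group, "mod_cat": "5mC", "y": y_mc})
            rows.append({"sample_id": sid, "group": group, "mod_cat": "5hmC", "y": y_hmc})
    return pd.DataFrame(rows)


def test_group_symmetric_data_zero_group_and_interaction():
    """Relabeling groups maps the data onto itself, so the group main effect
    and the interaction must vanish at the optimum."""
    fit = fit_paired(_symmetric_obs(), covariates=())
    assert fit.converged
    assert abs(fit.coef["group"]) < 1e-4
    assert abs(fit.coef["group:mod_5hmC"]) < 1e-4


def test_sigma_zero_reduces_to_fixed_effects(paired_study):
    """With the random-intercept SD held at 0 the marginal likelihood is the
    independent beta-regression likelihood; fixed effects must agree."""
    from dualmark.simulate import SimConfig, generate_dataset

    cfg = SimConfig(n_probes=2, zero_inflation=0.0, sigma_b=0.0,
                    hmc_mean_range=(0.12, 0.3), seed=55)
    st = generate_dataset(cfg)
    for probe in st.mc.index:
        obs = to_long(st.mc, st.hmc, st.sheet, probe)
        mf = fit_paired(obs, sigma_b_fixed=0.0)
        X, y = build_design(obs)
        bf = fit_betareg(X, y)
        assert np.max(np.abs(mf.coef.to_numpy() - bf.coef.to_numpy())) < 1e-3
        assert abs(mf.loglik - bf.loglik) < 1e-4


def test_interaction_parameter_recovery():
    """Planted interaction of -0.8 recovered within 3 SE (n=36 samples)."""
    from scipy.special import expit

    rng = np.random.default_rng(17)
    n = 36
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["control"] * 18 + ["case"] * 18,
        "age": rng.uniform(60, 95, n),
        "glial_proportion": rng.uniform(0.3, 0.7, n),
    })
    case = (sheet.group == "case").to_numpy(float)
    sigma_b, phi = 0.5, 30.0
    for _ in range(5):
        u = rng.normal(0, sigma_b, n)
        mu_mc = expit(0.2 + 0.0 * case + u)
        mu_hmc = expit(-1.2 + (-0.8) * case + u)
        mc = pd.DataFrame([rng.beta(mu_mc * phi, (1 - mu_mc) * phi)],
                          index=["p"], columns=sheet.sample_id)
        hmc = pd.DataFrame([rng.beta(mu_hmc * phi, (1 - mu_hmc) * phi)],
                           index=["p"], columns=sheet.sample_id)
        fit = fit_paired(to_long(mc, hmc, sheet, "p"))
        assert fit.converged
        est = fit.coef["group:mod_5hmC"]
        se = fit.se["group:mod_5hmC"]
        assert abs(est - (-0.8)) < 3 * se


def test_quadrature_node_stability(paired_study):
    """Interaction estimates with 5 vs 15 adaptive nodes differ < 1e-3."""
    st = paired_study
    for probe in st.mc.index[:3]:
        obs = to_long(st.mc, st.hmc, st.sheet, probe)
        f5 = fit_paired(obs, n_quad=5)
        f15 = fit_paired(obs, n_quad=15)
        assert abs(f5.coef["group:mod_5hmC"] - f15.coef["group:mod_5hmC"]) < 1e-3


class TestInteractionTest:
    def test_direction_sign_convention(self, paired_study):
        st = paired_study
        obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[0])
        fit = fit_paired(obs)
        res = interaction_test(fit)
        assert res.p > 0
        if res.coef > 0:
            assert res.direction == "toward-5hmC"
        elif res.coef < 0:
            assert res.direction == "toward-5mC"

    def test_nonconverged_gives_nan(self, paired_study):
        st = paired_study
        obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[0])
        fit = fit_paired(obs)
        fit.converged = False
        res = interaction_test(fit)
        assert np.isnan(res.p) and res.direction in ("toward-5hmC", "toward-5mC", "none")


def test_lrt_broadly_agrees_with_wald():
    """On a strong planted shift both tests reject; LR stat is non-negative."""
    from scipy.special import expit

    rng = np.random.default_rng(31)
    n = 36
    sheet = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "group": ["control"] * 18 + ["case"] * 18,
        "age": rng.uniform(60, 95, n),
        "glial_proportion": rng.uniform(0.3, 0.7, n),
    })
    case = (sheet.group == "case").to_numpy(float)
    u = rng.normal(0, 0.5, n)
    mu_mc = expit(0.2 + u)
    mu_hmc = expit(-1.2 - 1.5 * case + u)
    mc = pd.DataFrame([rng.beta(mu_mc * 30, (1 - mu_mc) * 30)],
                      index=["p"], columns=sheet.sample_id)
    hmc = pd.DataFrame([rng.beta(mu_hmc * 30, (1 - mu_hmc) * 30)],
                       index=["p"], columns=sheet.sample_id)
    obs = to_long(mc, hmc, sheet, "p")
    lr, p_lrt = interaction_lrt(obs)
    p_wald = interaction_test(fit_paired(obs)).p
    assert lr >= 0
    assert p_lrt < 0.01 and p_wald < 0.01


class TestMainEffectModel:
    def test_reproduces_separate_models(self, paired_study):
        st = paired_study
        obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[1])
        for level, mat in (("5mC", st.mc), ("5hmC", st.hmc)):
            fit = main_effect_model(obs, level)
            sub = obs[obs.mod_cat == level].reset_index(drop=True)
            g = (sub.group == "case").astype(float).to_numpy()
            X = pd.DataFrame({
                "intercept": np.ones(len(sub)), "group": g,
                "glial_proportion": sub.glial_proportion.to_numpy(),
                "age": sub.age.to_numpy(),
            })
            direct = fit_betareg(X, sub.y.to_numpy())
            assert np.allclose(fit.coef, direct.coef, atol=1e-8)

    def test_single_group_rejected(self, paired_study):
        st = paired_study
        obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[0])
        with pytest.raises(ValueError, match="single group"):
            main_effect_model(obs[obs.group == "case"], "5mC")

    def test_unknown_level_rejected(self, paired_study):
        st = paired_study
        obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[0])
        with pytest.raises(ValueError):
            main_effect_model(obs, "5fC")


def test_guard_rails(paired_study):
    st = paired_study
    obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[0])
    # too few samples per group
    small = obs[obs.sample_id.isin(st.sheet.sample_id[:6])]
    with pytest.raises(ValueError, match="4 distinct samples"):
        fit_paired(small)
    # odd rows per sample
    with pytest.raises(ValueError, match="2 rows"):
        fit_paired(obs.iloc[1:])


def test_batch_random_effect_runs(paired_study):
    """Optional batch intercept: fit converges and sigma_batch is small on
    batch-free data."""
    st = paired_study
    obs = to_long(st.mc, st.hmc, st.sheet, st.mc.index[0])
    fit = fit_paired(obs, include_batch_re=True)
    assert np.isfinite(fit.sigma_batch)
    assert fit.sigma_batch < 0.5  # no batch structure was simulated
    base = fit_paired(obs)
    assert abs(fit.coef["group:mod_5hmC"] - base.coef["group:mod_5hmC"]) < 0.05
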