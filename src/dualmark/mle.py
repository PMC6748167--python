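"""Maximum-likelihood estimation of 5-mC and 5-hmC proportions from paired
BS/oxBS measurements.

Bisulfite (BS) conversion leaves both 5-methylcytosine (5-mC) and
5-hydroxymethylcytosine (5-hmC) unconverted, so the BS channel measures the
sum ``beta_mc + beta_hmc``. Oxidative bisulfite (oxBS) first oxidizes 5-hmC
so that only 5-mC survives conversion; the oxBS channel measures ``beta_mc``
alone. Treating the modified-signal fractions of the two channels as binomial
proportions, the joint log-likelihood is

    L(beta_mc, beta_hmc) = log Binom(m_bs; n_bs, beta_mc + beta_hmc)
                         + log Binom(m_ox; n_ox, beta_mc)

maximized over the simplex {beta_mc >= 0, beta_hmc >= 0,
beta_mc + beta_hmc <= 1}. When the unconstrained optimum
(m_ox/n_ox, m_bs/n_bs - m_ox/n_ox) is feasible it is the exact MLE. When the
BS proportion falls below the oxBS proportion the optimum lies on the
boundary beta_hmc = 0, where the problem collapses to a single pooled
binomial proportion (m_bs + m_ox) / (n_bs + n_ox); such calls carry a
``boundary_flag`` because clipping at zero is a major source of the
zero-enrichment seen in estimated 5-hmC.

Array intensities are not integer counts; matrix inputs provide beta values
plus per-channel totals and are converted via ``m = round(beta * n)``, which
preserves the binomial form of the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SignalPair",
    "PairedModCall",
    "estimate_paired_mle",
    "estimate_naive",
    "estimate_matrix",
]


@dataclass(frozen=True)
class SignalPair:
    """Modified-signal counts and totals for one probe x sample pair.

    ``m_bs``/``n_bs`` are the modified count and total of the BS channel
    (which measures 5-mC + 5-hmC); ``m_ox``/``n_ox`` the same for the oxBS
    channel (5-mC only). Totals must be strictly positive and counts must
    not exceed totals.
    """

    m_bs: float
    n_bs: float
    m_ox: float
    n_ox: float

    def __post_init__(self) -> None:
        if not (self.n_bs > 0 and self.n_ox > 0):
            raise ValueError(
                f"channel totals must be strictly positive, got "
                f"n_bs={self.n_bs}, n_ox={self.n_ox}"
            )
        if not (0 <= self.m_bs <= self.n_bs):
            raise ValueError(
                f"BS count out of range: m_bs={self.m_bs}, n_bs={self.n_bs}"
            )
        if not (0 <= self.m_ox <= self.n_ox):
            raise ValueError(
                f"oxBS count out of range: m_ox={self.m_ox}, n_ox={self.n_ox}"
            )


@dataclass(frozen=True)
class PairedModCall:
    """Estimated (beta_mc, beta_hmc, beta_c) for one probe x sample pair.

    The three proportions live on the simplex: beta_mc + beta_hmc + beta_c
    = 1, each component in [0, 1]. ``boundary_flag`` records that the 5-hmC
    estimate was clipped at zero (the constrained optimum sat on the
    boundary of the simplex).
    """

    beta_mc: float
    beta_hmc: float
    beta_c: float
    boundary_flag: bool = False

    def __post_init__(self) -> None:
        total = self.beta_mc + self.beta_hmc + self.beta_c
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"beta components sum to {total!r}, not 1")
        for name in ("beta_mc", "beta_hmc", "beta_c"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v!r} outside [0, 1]")


def estimate_paired_mle(signal: SignalPair) -> PairedModCall:
    """Constrained joint-binomial MLE of (beta_mc, beta_hmc).

    Feasible case (BS proportion >= oxBS proportion): the channel-wise
    proportions are returned exactly. Infeasible case: the boundary solution
    with beta_hmc = 0 and the pooled proportion
    (m_bs + m_ox) / (n_bs + n_ox) for beta_mc, flagged.
    """
    p_bs = signal.m_bs / signal.n_bs
    p_ox = signal.m_ox / signal.n_ox
    if p_bs >= p_ox:
        beta_mc, beta_hmc, flagged = p_ox, p_bs - p_ox, False
    else:
        pooled = (signal.m_bs + signal.m_ox) / (signal.n_bs + signal.n_ox)
        beta_mc, beta_hmc, flagged = pooled, 0.0, True
    beta_c = max(0.0, 1.0 - beta_mc - beta_hmc)
    return PairedModCall(beta_mc, beta_hmc, beta_c, flagged)


def estimate_naive(beta_bs: float, beta_ox: float) -> PairedModCall:
    """Subtraction estimator: beta_hmc = max(0, beta_bs - beta_ox).

    Equivalent to the MLE when channel totals are equal and the difference
    is non-negative; it ignores relative channel precision otherwise.
    """
    for name, v in (("beta_bs", beta_bs), ("beta_ox", beta_ox)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name}={v!r} outside [0, 1]")
    diff = beta_bs - beta_ox
    flagged = diff < 0
    beta_hmc = max(0.0, diff)
    beta_c = max(0.0, 1.0 - beta_ox - beta_hmc)
    return PairedModCall(beta_ox, beta_hmc, beta_c, flagged)


def _aligned(name: str, ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    missing_rows = ref.index.difference(other.index)
    missing_cols = ref.columns.difference(other.columns)
    extra_rows = other.index.difference(ref.index)
    extra_cols = other.columns.difference(ref.columns)
    if len(missing_rows) or len(missing_cols) or len(extra_rows) or len(extra_cols):
        parts = []
        if len(missing_rows):
            parts.append(f"probes absent from {name}: {list(missing_rows[:5])}")
        if len(extra_rows):
            parts.append(f"probes only in {name}: {list(extra_rows[:5])}")
        if len(missing_cols):
            parts.append(f"samples absent from {name}: {list(missing_cols[:5])}")
        if len(extra_cols):
            parts.append(f"samples only in {name}: {list(extra_cols[:5])}")
        raise ValueError("matrix index mismatch: " + "; ".join(parts))
    return other.loc[ref.index, ref.columns]


def estimate_matrix(
    bs: pd.DataFrame,
    ox: pd.DataFrame,
    coverage: pd.DataFrame,
    coverage_ox: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Elementwise constrained MLE over probe x sample beta matrices.

    Parameters
    ----------
    bs, ox
        Beta-value matrices (probes x samples) for the BS and oxBS channels.
    coverage
        Total-signal matrix for the BS channel (and for the oxBS channel
        too when ``coverage_ox`` is omitted).
    coverage_ox
        Optional separate totals for the oxBS channel.

    Returns
    -------
    (beta_mc, beta_hmc, boundary) DataFrames sharing the input labels.
    Missing inputs (NaN beta or NaN/non-positive total) propagate to missing
    outputs; downstream filtering is the designated handler.
    """
    ox = _aligned("oxBS matrix", bs, ox)
    n_bs = _aligned("coverage matrix", bs, coverage).to_numpy(dtype=float)
    if coverage_ox is None:
        n_ox = n_bs
    else:
        n_ox = _aligned("oxBS coverage matrix", bs, coverage_ox).to_numpy(dtype=float)

    b_bs = bs.to_numpy(dtype=float)
    b_ox = ox.to_numpy(dtype=float)
    for name, arr in (("BS", b_bs), ("oxBS", b_ox)):
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"{name} beta outside [0, 1] at probe {bs.index[i]!r}, "
                f"sample {bs.columns[j]!r}: {arr[i, j]!r}"
            )

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bs_ok = np.where(n_bs > 0, n_bs, np.nan)
        n_ox_ok = np.where(n_ox > 0, n_ox, np.nan)
        m_bs = np.round(b_bs * n_bs_ok)
        m_ox = np.round(b_ox * n_ox_ok)
        p_bs = m_bs / n_bs_ok
        p_ox = m_ox / n_ox_ok
        feasible = p_bs >= p_ox
        pooled = (m_bs + m_ox) / (n_bs_ok + n_ox_ok)
        beta_mc = np.where(feasible, p_ox, pooled)
        beta_hmc = np.where(feasible, p_bs - p_ox, 0.0)
        boundary = np.where(feasible, 0.0, 1.0)

    missing = np.isnan(p_bs) | np.isnan(p_ox)
    beta_mc[missing] = np.nan
    beta_hmc[missing] = np.nan
    boundary[missing] = np.nan

    wrap = lambda a: pd.DataFrame(a, index=bs.index, columns=bs.columns)
    return wrap(beta_mc), wrap(beta_hmc), wrap(boundary)
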