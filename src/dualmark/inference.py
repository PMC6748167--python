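"""Multiple-testing correction, significance calling, and probe classification.

Per-probe p-values from the three channels (separate 5-mC model, separate
5-hmC model, paired interaction) are corrected by the Benjamini-Hochberg
step-up procedure within each channel. Probes are then classified:

* DMP  - differentially methylated probe (separate 5-mC model),
* DHMP - differentially hydroxymethylated probe (separate 5-hmC model),
* DIP  - differential interaction probe (paired model): the balance between
  5-mC and 5-hmC shifts with the experimental condition.

Default thresholds: FDR < 0.10 for the separate models, FDR < 0.05 for the
paired interaction, with a lenient raw p < 0.001 mode available for the
separate models (small studies rarely clear an FDR bar per mark, which is
exactly the regime the paired model is designed for).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "ComparisonSummary",
    "bh_adjust",
    "call_significant",
    "compare_paired_vs_separate",
    "summarize_directions",
]

CHANNELS = ("mc", "hmc", "interaction")
_PREFIX = {"mc": "mc", "hmc": "hmc", "interaction": "int"}
_FLAG = {"mc": "dmp", "hmc": "dhmp", "interaction": "dip"}


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1, where m counts the
    non-missing entries. Missing (NaN) p-values — e.g. from probes whose
    model did not converge — are excluded from m and returned as NaN, so
    valid tests are not penalized by failed ones. Order-preserving: ties
    receive equal q-values.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        bad = pv[(pv < 0) | (pv > 1)][0]
        raise ValueError(f"p-value outside [0, 1]: {bad!r}")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def call_significant(
    results: pd.DataFrame,
    channel: str,
    mode: str = "fdr",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Flag significant probes in one channel and record direction.

    ``channel`` is one of {"mc", "hmc", "interaction"}; ``mode`` selects the
    q-value ("fdr") or the raw p-value ("raw_p") column, compared strictly
    against ``threshold`` (defaults: 0.10 for separate channels under fdr,
    0.05 for the interaction, 0.001 under raw_p). Adds/overwrites the flag
    column (dmp/dhmp/dip) and ``direction_<flag>`` from the coefficient
    sign; exact zeros get direction "none". Missing p/q never flag.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    if mode not in ("fdr", "raw_p"):
        raise ValueError(f"unknown mode {mode!r}; expected 'fdr' or 'raw_p'")
    if threshold is None:
        if mode == "raw_p":
            threshold = 0.001
        else:
            threshold = 0.05 if channel == "interaction" else 0.10
    pre = _PREFIX[channel]
    col = f"{pre}_q" if mode == "fdr" else f"{pre}_p"
    if col not in results.columns:
        raise ValueError(f"channel column {col!r} absent from results")
    out = results.copy()
    vals = out[col].to_numpy(dtype=float)
    flags = np.zeros(len(out), dtype=bool)
    ok = ~np.isnan(vals)
    flags[ok] = vals[ok] < threshold
    coefs = out[f"{pre}_coef"].to_numpy(dtype=float)
    direction = np.where(coefs > 0, "positive", np.where(coefs < 0, "negative", "none"))
    flag_col = _FLAG[channel]
    out[flag_col] = flags
    out[f"direction_{flag_col}"] = np.where(flags, direction, "")
    return out


@dataclass(frozen=True)
class ComparisonSummary:
    """Set accounting of the paired (DIP) vs separate (DMP/DHMP) calls.

    ``n_overlap_sep`` counts probes significant in BOTH separate models;
    ``n_dip_covering_overlap`` counts how many of those the paired model
    also finds; ``n_dip_only``/``n_sep_only`` count probes found by exactly
    one of the two approaches.
    """

    n_dmp: int
    n_dhmp: int
    n_overlap_sep: int
    n_dip: int
    n_dip_covering_overlap: int
    n_dip_only: int
    n_sep_only: int

    def to_dict(self) -> dict:
        return asdict(self)


def compare_paired_vs_separate(results: pd.DataFrame) -> ComparisonSummary:
    """Compare the paired-model DIP set with the separate-model call sets.

    Requires dmp/dhmp/dip flag columns (see :func:`call_significant`).
    """
    for col in ("dmp", "dhmp", "dip"):
        if col not in results.columns:
            raise ValueError(f"flag column {col!r} missing; call all three channels first")
    probe = results["probe_id"]
    dmp = set(probe[results["dmp"].astype(bool)])
    dhmp = set(probe[results["dhmp"].astype(bool)])
    dip = set(probe[results["dip"].astype(bool)])
    sep = dmp | dhmp
    overlap = dmp & dhmp
    return ComparisonSummary(
        n_dmp=len(dmp),
        n_dhmp=len(dhmp),
        n_overlap_sep=len(overlap),
        n_dip=len(dip),
        n_dip_covering_overlap=len(dip & overlap),
        n_dip_only=len(dip - sep),
        n_sep_only=len(sep - dip),
    )


def summarize_directions(results: pd.DataFrame, channel: str) -> dict:
    """Count negative/positive coefficient signs among flagged probes.

    Zero coefficients are tallied separately as "zero" (no direction);
    percentages are over the flagged set.
    """
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}; expected one of {CHANNELS}")
    flag_col = _FLAG[channel]
    if flag_col not in results.columns:
        raise ValueError(f"channel {channel!r} has not been called yet")
    flagged = results[results[flag_col].astype(bool)]
    coefs = flagged[f"{_PREFIX[channel]}_coef"].to_numpy(dtype=float)
    n_neg = int(np.sum(coefs < 0))
    n_pos = int(np.sum(coefs > 0))
    n_zero = int(np.sum(coefs == 0))
    total = len(coefs)
    return {
        "channel": channel,
        "n_flagged": total,
        "negative": n_neg,
        "positive": n_pos,
        "zero": n_zero,
        "pct_negative": 100.0 * n_neg / total if total else 0.0,
        "pct_positive": 100.0 * n_pos / total if total else 0.0,
    }
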