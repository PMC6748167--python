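"""End-to-end study driver: filtering, per-probe modeling, and reporting.

Stage order follows the array-processing flow the package is built around:

1. detection filter — first drop samples whose fraction of failed probes
   (detection p above threshold) exceeds 10%, then drop probes failing in
   ANY remaining sample;
2. blacklist filter — cross-reactive / SNP-overlapping probes, supplied as
   an external list;
3. constrained MLE of (5-mC, 5-hmC) from the BS/oxBS channels;
4. low-beta filter — drop probes whose across-sample mean 5-mC OR mean
   5-hmC estimate is below 0.1 (strict); this removes the zero-inflated
   bulk of the 5-hmC distribution before beta regression;
5. missingness filter — drop probes with any missing estimate in either
   mark.

The low-beta rule runs AFTER estimation because it applies to the
estimated 5-hmC proportions, not to the raw BS channel. It is a
probe-level rule; the per-stage accounting is conserved
(input = final + sum of removals).

After filtering, each probe gets three models: separate beta regressions
per mark (the "traditional" analysis) and the paired repeated-measures
mixed model; p-values are BH-adjusted per channel, probes classified
(DMP/DHMP/DIP), the paired-vs-separate comparison summarized, and results
optionally annotated and written to disk.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import io as dio
from .betareg import wald
from .inference import (
    bh_adjust,
    call_significant,
    compare_paired_vs_separate,
    summarize_directions,
)
from .mixed import fit_paired, interaction_test, main_effect_model, to_long
from .mle import estimate_matrix
from .simulate import SimConfig, generate_dataset

__all__ = [
    "FilterReport",
    "StudyResult",
    "filter_detection",
    "filter_blacklist",
    "filter_low_beta",
    "filter_missing",
    "annotate",
    "replicate_correlation",
    "run_study",
]


@dataclass
class FilterReport:
    """Per-stage probe accounting; conserved: input = final + removals."""

    n_input_probes: int = 0
    n_removed_detection: int = 0
    n_removed_blacklist: int = 0
    n_removed_lowbeta: int = 0
    n_removed_missing: int = 0
    n_final: int = 0
    samples_excluded: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    def conserved(self) -> bool:
        return self.n_final == self.n_input_probes - (
            self.n_removed_detection
            + self.n_removed_blacklist
            + self.n_removed_lowbeta
            + self.n_removed_missing
        )


def _check_aligned(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    if not a.index.equals(b.index) or not a.columns.equals(b.columns):
        raise ValueError(f"{what} is not aligned with the beta matrices")


def filter_detection(
    matrices: dict[str, pd.DataFrame],
    detection_p: pd.DataFrame,
    p_threshold: float = 0.05,
    sample_fail_fraction: float = 0.10,
) -> tuple[dict[str, pd.DataFrame], int, list[str]]:
    """Sample-then-probe detection filtering.

    Samples whose fraction of failed probes (detection p > ``p_threshold``)
    exceeds ``sample_fail_fraction`` are excluded first; then any probe
    failing in any remaining sample is removed. ``matrices`` maps names to
    probe x sample frames sharing the detection matrix's labels; all are
    subset consistently. Returns (filtered matrices, probes removed,
    samples excluded).
    """
    ref = next(iter(matrices.values()))
    _check_aligned(ref, detection_p, "detection p-value matrix")
    failed = detection_p.to_numpy(dtype=float) > p_threshold
    frac_by_sample = failed.mean(axis=0)
    bad_samples = [
        s for s, f in zip(detection_p.columns, frac_by_sample)
        if f > sample_fail_fraction
    ]
    keep_samples = [s for s in detection_p.columns if s not in bad_samples]
    det = detection_p[keep_samples]
    keep_probes = det.index[(det.to_numpy(dtype=float) <= p_threshold).all(axis=1)]
    n_removed = len(det.index) - len(keep_probes)
    out = {k: v.loc[keep_probes, keep_samples] for k, v in matrices.items()}
    return out, n_removed, bad_samples


def filter_blacklist(
    matrices: dict[str, pd.DataFrame], blacklist
) -> tuple[dict[str, pd.DataFrame], int, int]:
    """Remove blacklisted probes; absent IDs are counted, not an error."""
    ref = next(iter(matrices.values()))
    listed = set(blacklist)
    present = [p for p in ref.index if p in listed]
    n_absent = len(listed) - len(present)
    keep = ref.index.difference(present, sort=False)
    out = {k: v.loc[keep] for k, v in matrices.items()}
    return out, len(present), n_absent


def filter_low_beta(
    mc: pd.DataFrame,
    hmc: pd.DataFrame,
    mean_threshold: float = 0.1,
    extra: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], int]:
    """Drop probes whose mean 5-mC OR mean 5-hmC is below the threshold.

    Means are across samples, excluding missing values; the comparison is
    strict (exactly-at-threshold probes are kept). Operates on ESTIMATED
    proportions, hence runs after the MLE stage.
    """
    _check_aligned(mc, hmc, "5-hmC matrix")
    low = (mc.mean(axis=1, skipna=True) < mean_threshold) | (
        hmc.mean(axis=1, skipna=True) < mean_threshold
    )
    keep = mc.index[~low]
    extra_out = {k: v.loc[keep] for k, v in (extra or {}).items()}
    return mc.loc[keep], hmc.loc[keep], extra_out, int(low.sum())


def filter_missing(
    mc: pd.DataFrame,
    hmc: pd.DataFrame,
    extra: dict[str, pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame], int]:
    """Drop probes with any missing value in either mark."""
    _check_aligned(mc, hmc, "5-hmC matrix")
    any_na = mc.isna().any(axis=1) | hmc.isna().any(axis=1)
    keep = mc.index[~any_na]
    extra_out = {k: v.loc[keep] for k, v in (extra or {}).items()}
    return mc.loc[keep], hmc.loc[keep], extra_out, int(any_na.sum())


def replicate_correlation(
    betas: pd.DataFrame, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """Optional QC report: per-pair Pearson correlation of technical replicates.

    ``pairs`` lists (sample_a, sample_b) column pairs. Purely diagnostic —
    replicate agreement is reported, never used as a filter.
    """
    rows = []
    for a, b in pairs:
        for s in (a, b):
            if s not in betas.columns:
                raise ValueError(f"replicate sample {s!r} absent from the matrix")
        sub = betas[[a, b]].dropna()
        r = float(sub[a].corr(sub[b])) if len(sub) > 1 else float("nan")
        rows.append({"sample_a": a, "sample_b": b, "n_probes": len(sub), "pearson_r": r})
    return pd.DataFrame(rows)


def annotate(results: pd.DataFrame, manifest: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Left-join probe annotation and tally unique genes over flagged probes.

    Multi-gene fields are split on ';'. Unmatched probes keep NA annotation.
    Returns (annotated results, unique gene count among DIP/DMP/DHMP probes).
    """
    if manifest["probe_id"].duplicated().any():
        dup = manifest["probe_id"][manifest["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate manifest key {dup!r}")
    cols = [c for c in ("probe_id", "chr", "pos", "gene") if c in manifest.columns]
    out = results.merge(manifest[cols], on="probe_id", how="left")
    flag_cols = [c for c in ("dmp", "dhmp", "dip") if c in out.columns]
    if flag_cols and "gene" in out.columns:
        flagged = out[out[flag_cols].any(axis=1)]
        genes: set[str] = set()
        for g in flagged["gene"].dropna():
            genes.update(s for s in str(g).split(";") if s)
        n_genes = len(genes)
    else:
        n_genes = 0
    return out, n_genes


_RESULT_COLUMNS = [
    "probe_id",
    "mc_coef", "mc_p", "mc_q",
    "hmc_coef", "hmc_p", "hmc_q",
    "int_coef", "int_p", "int_q",
    "dmp", "dhmp", "dip",
    "direction_dmp", "direction_dhmp", "direction_dip",
]


def _fit_all_probes(mc, hmc, sheet, cfg) -> tuple[pd.DataFrame, list[str]]:
    rows, rejects = [], []
    for probe in mc.index:
        obs = to_long(mc, hmc, sheet, probe, squeeze_eps=cfg.squeeze_eps)
        rec = {"probe_id": probe}
        try:
            for key, level in (("mc", "5mC"), ("hmc", "5hmC")):
                f = main_effect_model(
                    obs, level, covariates=cfg.covariates,
                    reference_group=cfg.reference_group,
                )
                _, p = wald(f, "group")
                rec[f"{key}_coef"] = float(f.coef["group"])
                rec[f"{key}_p"] = p
            pf = fit_paired(
                obs,
                covariates=cfg.covariates,
                include_batch_re=cfg.include_batch_re,
                n_quad=cfg.n_quad,
                reference_group=cfg.reference_group,
            )
            it = interaction_test(pf)
            rec["int_coef"] = it.coef
            rec["int_p"] = it.p
            if not pf.converged or np.isnan(it.p):
                rejects.append(probe)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rejects.append(probe)
            rec.setdefault("mc_coef", np.nan)
            rec.setdefault("mc_p", np.nan)
            rec.setdefault("hmc_coef", np.nan)
            rec.setdefault("hmc_p", np.nan)
            rec["int_coef"] = np.nan
            rec["int_p"] = np.nan
            rec["error"] = str(exc)
        rows.append(rec)
    frame = pd.DataFrame(rows)
    return frame, rejects


@dataclass
class StudyResult:
    """Everything a run produces, in memory."""

    results: pd.DataFrame
    comparison: object
    filter_report: FilterReport
    direction_summaries: dict
    log: dict
    paths: dict = field(default_factory=dict)


def run_study(config: dio.StudyConfig) -> StudyResult:
    """Execute the full pipeline for a configured or simulated study."""
    log: dict = {"seed": config.seed, "stages": []}
    report = FilterReport()

    manifest = None
    blacklist: list[str] = []
    detection = None
    coverage_ox = None

    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        effects = sim_kwargs.get("effects")
        if effects and isinstance(effects[0], dict):
            from .simulate import EffectSpec

            sim_kwargs["effects"] = tuple(EffectSpec(**e) for e in effects)
        study = generate_dataset(SimConfig(**sim_kwargs))
        bs, oxbs, coverage, sheet = study.bs, study.oxbs, study.coverage, study.sheet
        mc = hmc = None
        log["simulation"] = sim_kwargs | {"effects": str(sim_kwargs.get("effects"))}
    else:
        paths = config.inputs
        sheet = dio.read_sample_sheet(paths["sample_sheet"])
        if "mc" in paths and "hmc" in paths:
            mc = dio.read_beta_matrix(paths["mc"])
            hmc = dio.read_beta_matrix(paths["hmc"])
            bs = oxbs = coverage = None
        else:
            bs = dio.read_beta_matrix(paths["bs"])
            oxbs = dio.read_beta_matrix(paths["oxbs"])
            coverage = dio.read_beta_matrix(paths["coverage"])
            if "coverage_ox" in paths:
                coverage_ox = dio.read_beta_matrix(paths["coverage_ox"])
            mc = hmc = None
        if "detection_p" in paths:
            detection = dio.read_beta_matrix(paths["detection_p"])
        if "blacklist" in paths:
            blacklist = dio.read_blacklist(paths["blacklist"])
        if "manifest" in paths:
            manifest = dio.read_manifest(paths["manifest"])

    matrices = (
        {"mc": mc, "hmc": hmc}
        if mc is not None
        else {"bs": bs, "oxbs": oxbs, "coverage": coverage}
    )
    if coverage_ox is not None:
        matrices["coverage_ox"] = coverage_ox
    ref = next(iter(matrices.values()))
    report.n_input_probes = len(ref.index)

    # stage 1: detection
    if detection is not None:
        matrices, n_det, bad_samples = filter_detection(
            matrices, detection,
            p_threshold=config.detection_p_threshold,
            sample_fail_fraction=config.sample_fail_fraction,
        )
        report.n_removed_detection = n_det
        report.samples_excluded = bad_samples
        sheet = sheet[~sheet["sample_id"].isin(bad_samples)].reset_index(drop=True)
        log["stages"].append({"stage": "detection", "probes_removed": n_det,
                              "samples_excluded": bad_samples})

    # stage 2: blacklist
    matrices, n_blk, n_absent = filter_blacklist(matrices, blacklist)
    report.n_removed_blacklist = n_blk
    log["stages"].append({"stage": "blacklist", "probes_removed": n_blk,
                          "ids_not_found": n_absent})

    # stage 3: MLE estimation (channel inputs only)
    if "bs" in matrices:
        mc, hmc, boundary = estimate_matrix(
            matrices["bs"], matrices["oxbs"], matrices["coverage"],
            matrices.get("coverage_ox"),
        )
        n_boundary = int(np.nansum(boundary.to_numpy()))
        log["stages"].append({"stage": "mle", "boundary_calls": n_boundary})
    else:
        mc, hmc = matrices["mc"], matrices["hmc"]

    # stage 4: low mean beta (on estimated proportions)
    mc, hmc, _, n_low = filter_low_beta(mc, hmc, config.low_beta_threshold)
    report.n_removed_lowbeta = n_low
    log["stages"].append({"stage": "low_beta", "probes_removed": n_low})

    # stage 5: missingness
    mc, hmc, _, n_miss = filter_missing(mc, hmc)
    report.n_removed_missing = n_miss
    report.n_final = len(mc.index)
    log["stages"].append({"stage": "missing", "probes_removed": n_miss})
    assert report.conserved(), "filter accounting is not conserved"

    # restrict the sheet to samples present in the matrices
    sheet = sheet[sheet["sample_id"].isin(mc.columns)].reset_index(drop=True)

    # per-probe modeling
    results, rejects = _fit_all_probes(mc, hmc, sheet, config)
    log["model_rejects"] = rejects

    for key in ("mc", "hmc", "int"):
        results[f"{key}_q"] = bh_adjust(results[f"{key}_p"].to_numpy())
    results = call_significant(
        results, "mc", mode=config.separate_mode, threshold=config.separate_threshold
    )
    results = call_significant(
        results, "hmc", mode=config.separate_mode, threshold=config.separate_threshold
    )
    results = call_significant(
        results, "interaction", mode="fdr", threshold=config.paired_threshold
    )

    comparison = compare_paired_vs_separate(results)
    directions = {
        ch: summarize_directions(results, ch) for ch in ("mc", "hmc", "interaction")
    }

    if manifest is not None:
        results, n_genes = annotate(results, manifest)
        log["unique_genes_flagged"] = n_genes

    ordered = [c for c in _RESULT_COLUMNS if c in results.columns] + [
        c for c in results.columns if c not in _RESULT_COLUMNS
    ]
    results = results[ordered].sort_values("probe_id", kind="stable").reset_index(drop=True)

    log["filter_report"] = report.to_dict()
    out = StudyResult(
        results=results,
        comparison=comparison,
        filter_report=report,
        direction_summaries=directions,
        log=log,
    )
    if config.outdir:
        out.paths = dio.write_results(
            results, comparison, report, config.outdir, run_log=log
        )
    return out
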