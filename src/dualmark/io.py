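"""Readers and writers for the package's external formats.

Canonical output is tab-separated; on input the delimiter is sniffed (tab or
comma). Probe IDs are opaque strings — no array-specific validation — with
probes as rows and sample IDs as column headers; missing values are "NA".
The blacklist is plain text (one probe ID per line, '#' comments allowed);
the manifest is CSV/TSV with columns probe_id, chr, pos, gene; run
configuration is YAML.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "StudyConfig",
    "read_beta_matrix",
    "read_sample_sheet",
    "read_blacklist",
    "read_manifest",
    "read_config",
    "write_matrix",
    "write_results",
]

_NA = "NA"


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probe x sample numeric matrix (first column = probe IDs)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0, na_values=[_NA])
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate probe IDs in {path.name}: {list(dup[:5])}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            probe = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric value in {path.name} at probe {probe!r}, "
                f"sample {col!r}: {bad.iloc[0]!r}"
            )
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df.astype(float)


_REQUIRED_SHEET = ("sample_id", "group", "age", "glial_proportion")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read and validate the sample sheet.

    Requires sample_id, group, age, glial_proportion; extra columns (sex,
    batch, ...) are preserved as optional covariates.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in _REQUIRED_SHEET:
        if col not in df.columns:
            raise ValueError(f"sample sheet {path.name} is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample ID {dup!r} in sample sheet")
    for col in ("age", "glial_proportion"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and df[col].notna().any():
            bad = df.loc[coerced.isna(), col].iloc[0]
            raise ValueError(f"non-numeric {col!r} in sample sheet: {bad!r}")
        df[col] = coerced
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def read_blacklist(path) -> list[str]:
    """One probe ID per line; blank lines and '#' comments ignored."""
    ids = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            ids.append(line)
    return ids


def read_manifest(path) -> pd.DataFrame:
    """Probe annotation manifest with columns probe_id, chr, pos, gene."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if "probe_id" not in df.columns:
        raise ValueError(f"manifest {path.name} lacks a probe_id column")
    if df["probe_id"].duplicated().any():
        dup = df["probe_id"][df["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate manifest key {dup!r}")
    return df


@dataclass
class StudyConfig:
    """Validated run configuration (paths XOR a simulation spec).

    ``inputs`` holds file paths (bs, oxbs, coverage, and optionally
    coverage_ox, detection_p, sample_sheet, blacklist, manifest) or, for
    pre-estimated studies, mc/hmc matrices directly. ``simulation`` holds
    keyword arguments for :class:`dualmark.simulate.SimConfig`.
    """

    inputs: dict = field(default_factory=dict)
    simulation: dict | None = None
    detection_p_threshold: float = 0.05
    sample_fail_fraction: float = 0.10
    low_beta_threshold: float = 0.1
    separate_mode: str = "fdr"
    separate_threshold: float | None = None
    paired_threshold: float = 0.05
    squeeze_eps: float = 1e-6
    covariates: tuple = ("glial_proportion", "age")
    include_batch_re: bool = False
    n_quad: int = 9
    reference_group: str | None = None
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if bool(self.inputs) == (self.simulation is not None):
            raise ValueError(
                "config must provide exactly one of input paths or a simulation spec"
            )
        for name, lo, hi in (
            ("detection_p_threshold", 0, 1),
            ("sample_fail_fraction", 0, 1),
            ("low_beta_threshold", 0, 1),
            ("paired_threshold", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v!r} outside [{lo}, {hi}]")
        if self.separate_mode not in ("fdr", "raw_p"):
            raise ValueError(f"separate_mode must be 'fdr' or 'raw_p'")
        self.covariates = tuple(self.covariates)


def read_config(path) -> StudyConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in StudyConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**raw)


def write_matrix(df: pd.DataFrame, path) -> None:
    """Write a probe x sample matrix as TSV with NA for missing values."""
    df.to_csv(path, sep="\t", na_rep=_NA, float_format="%.10g")


def write_results(results: pd.DataFrame, comparison, report, outdir,
                  run_log: dict | None = None) -> dict:
    """Write the result table, comparison JSON, filter report, and run log.

    Byte-deterministic for identical inputs: fixed column order, fixed float
    formatting, sorted JSON keys. Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "results.tsv",
        "comparison": outdir / "comparison.json",
        "filter_report": outdir / "filter_report.json",
    }
    results.to_csv(paths["results"], sep="\t", index=False, na_rep=_NA,
                   float_format="%.10g")
    comp = comparison.to_dict() if hasattr(comparison, "to_dict") else dict(comparison)
    paths["comparison"].write_text(json.dumps(comp, indent=2, sort_keys=True) + "\n")
    rep = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    paths["filter_report"].write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
    if run_log is not None:
        paths["run_log"] = outdir / "run_log.json"
        paths["run_log"].write_text(
            json.dumps(run_log, indent=2, sort_keys=True, default=str) + "\n"
        )
    return paths
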