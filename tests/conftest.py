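import numpy as np
import pandas as pd
import pytest

from dualmark.simulate import SimConfig, generate_dataset, make_fixture


@pytest.fixture(scope="session")
def toy_fixture():
    """Deterministic 20-probe x 10-sample study with constructed filter triggers."""
    return make_fixture()


@pytest.fixture(scope="session")
def paired_study():
    """Small model-matched study (no zero inflation) for mixed-model tests."""
    cfg = SimConfig(
        n_probes=6,
        zero_inflation=0.0,
        sigma_b=0.5,
        hmc_mean_range=(0.12, 0.3),
        seed=101,
    )
    return generate_dataset(cfg)


@pytest.fixture()
def sheet35():
    """13 control + 22 case sample sheet with covariates."""
    rng = np.random.default_rng(7)
    n = 35
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:02d}" for i in range(n)],
            "group": ["control"] * 13 + ["case"] * 22,
            "age": np.round(rng.uniform(60, 95, n), 1),
            "glial_proportion": np.round(rng.uniform(0.3, 0.7, n), 3),
        }
    )


def write_fixture_files(fx, outdir):
    """Write a Fixture to disk in the pipeline's input formats."""
    from dualmark import io as dio

    outdir.mkdir(parents=True, exist_ok=True)
    dio.write_matrix(fx.bs, outdir / "bs.tsv")
    dio.write_matrix(fx.oxbs, outdir / "oxbs.tsv")
    dio.write_matrix(fx.coverage, outdir / "coverage.tsv")
    dio.write_matrix(fx.detection_p, outdir / "detection_p.tsv")
    fx.sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    (outdir / "blacklist.txt").write_text("\n".join(fx.blacklist) + "\n")
    fx.manifest.to_csv(outdir / "manifest.csv", index=False)
    return {
        "bs": str(outdir / "bs.tsv"),
        "oxbs": str(outdir / "oxbs.tsv"),
        "coverage": str(outdir / "coverage.tsv"),
        "detection_p": str(outdir / "detection_p.tsv"),
        "sample_sheet": str(outdir / "sample_sheet.tsv"),
        "blacklist": str(outdir / "blacklist.txt"),
        "manifest": str(outdir / "manifest.csv"),
    }
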