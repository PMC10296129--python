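"""Shared fixtures: a fitted normative model, a stroke cohort, and one
end-to-end pipeline run, all at desk-scale sizes."""

from __future__ import annotations

import pytest

from propriokit.normative import fit_normative_model
from propriokit.pipeline import RunConfig, run_pipeline
from propriokit.synthetic import (
    SyntheticConfig,
    control_observations,
    generate_control_cohort,
    generate_stroke_cohort,
)


@pytest.fixture(scope="session")
def control_setup():
    """A study-scale control cohort (799 subjects), its observation table, and the fitted model."""
    config = SyntheticConfig(n_controls=799, seed=20)
    cohort = generate_control_cohort(config)
    obs = control_observations(cohort)
    model = fit_normative_model(obs)
    return config, cohort, obs, model


@pytest.fixture(scope="session")
def norm_model(control_setup):
    return control_setup[3]


@pytest.fixture(scope="session")
def stroke_cohort(norm_model):
    """A default-sized stroke cohort (133 participants, lesions included)."""
    config = SyntheticConfig(n_controls=799, n_stroke=133, seed=77)
    return config, generate_stroke_cohort(config, norm_model)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One complete pipeline run on a small cohort; returns (config, run dir)."""
    out = tmp_path_factory.mktemp("pipeline")
    config = RunConfig(out_dir=out, synthetic=SyntheticConfig(n_controls=150, n_stroke=133), seed=11)
    run_pipeline(config)
    return config, out


@pytest.fixture(scope="session")
def feature_table(pipeline_run):
    import pandas as pd

    _, out = pipeline_run
    return pd.read_csv(out / "stats" / "feature_table.csv")
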