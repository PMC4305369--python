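"""Shared fixtures: one small simulated experiment reused across modules."""

import pandas as pd
import pytest

import stemsig as ss

SMALL_PLANTED = {
    "specific:CEF": 30,
    "specific:BM2": 30,
    "specific:cES": 12,
    "specific:cBC": 12,
    "shared_stem": 20,
    "germ": 15,
}


@pytest.fixture(scope="session")
def small_cfg() -> ss.SimulationConfig:
    return ss.SimulationConfig(
        n_probes=1500,
        planted_counts=dict(SMALL_PLANTED),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_experiment(small_cfg):
    scans, annotation, design, truth = ss.generate_experiment(small_cfg)
    return scans, annotation, design, truth


@pytest.fixture(scope="session")
def preprocessed(small_experiment) -> ss.ExpressionMatrix:
    scans, _, design, _ = small_experiment
    return ss.preprocess_experiment(scans, design)


@pytest.fixture(scope="session")
def contrasts(preprocessed):
    return ss.all_contrasts(preprocessed)


@pytest.fixture(scope="session")
def profiles(small_experiment, contrasts):
    _, annotation, design, _ = small_experiment
    groups = design.groups
    return {
        g: ss.build_profile(g, contrasts, groups, annotation=annotation)
        for g in groups
    }


def make_matrix(values, samples, groups, index=None, level="probe"):
    """Convenience: ExpressionMatrix from a plain nested list."""
    df = pd.DataFrame(values, columns=samples, dtype=float)
    if index is not None:
        df.index = index
    design = ss.DesignTable(pd.Series(groups, index=samples, name="group"))
    return ss.ExpressionMatrix(df, design, level=level)
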