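import dataclasses

import pytest

import pfmetallome as pm


@pytest.fixture(scope="session")
def design():
    """Default study design (the conditions the pipeline is validated under)."""
    return pm.RunDesign(seed=0)


@pytest.fixture(scope="session")
def noiseless_design(design):
    """Fully deterministic variant: no noise, no drift, no day effects."""
    return dataclasses.replace(
        design, noise_cv=0.0, interference_cv=0.0, drift_per_day=0.0, day_prep_cv=0.0
    )


@pytest.fixture(scope="session")
def records(design):
    return pm.generate_study(design)


@pytest.fixture(scope="session")
def noiseless_records(noiseless_design):
    return pm.generate_study(noiseless_design)


@pytest.fixture(scope="session")
def curves(records, design):
    return pm.fit_all(records, design.is_concentration)


@pytest.fixture(scope="session")
def limits_map(records, curves, design):
    return pm.compute_all_limits(records, curves, design.is_concentration)


@pytest.fixture(scope="session")
def bundle(design):
    cfg = pm.PipelineConfig(design=design)
    return pm.run_pipeline(cfg)


@pytest.fixture(scope="session")
def flat_matrix():
    """Matrix profile with the default composition but no residual suppression."""
    return pm.MatrixProfile(
        component_concentrations=dict(pm.instrument.DEFAULT_MATRIX_COMPONENTS)
    )
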