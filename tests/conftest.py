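"""Shared fixtures: a small synthetic cohort reused across unit tests."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import cfmethyl as cf

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_params() -> cf.SimParams:
    return cf.SimParams(
        n_regions=40, n_dmr_hyper=6, n_dmr_hypo=3,
        n_healthy=16, n_pre=8, n_post=8,
        n_tissue_tumor=20, n_tissue_normal=10,
        depth_mean=150.0, seed=123,
    )


@pytest.fixture(scope="session")
def small_panel(small_params):
    return cf.gen_panel(small_params)


@pytest.fixture(scope="session")
def small_plasma(small_panel, small_params):
    return cf.gen_plasma_cohort(small_panel, small_params)


@pytest.fixture(scope="session")
def small_tissue(small_panel, small_params):
    return cf.gen_tissue_cohort(small_panel, small_params)


@pytest.fixture(scope="session")
def small_plasma_amf(small_panel, small_plasma):
    counts, meta = small_plasma
    return cf.build_amf_matrix(counts, small_panel, cf.QCConfig(min_unique_molecules=0),
                               sample_order=meta["sample_id"].tolist())


@pytest.fixture(scope="session")
def small_tissue_amf(small_panel, small_tissue):
    counts, meta = small_tissue
    return cf.build_amf_matrix(counts, small_panel, cf.QCConfig(min_unique_molecules=0),
                               sample_order=meta["sample_id"].tolist())
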