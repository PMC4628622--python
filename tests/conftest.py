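"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import pytest

from cosegscan.annotation_filters import FilterConfig
from cosegscan.candidate_scan import ScanConfig
from cosegscan.pedigree_io import Individual, Pedigree
from cosegscan.segregation import InheritanceModel
from cosegscan.synthetic_data import (
    SimulationConfig,
    make_fig1a_fixture,
    write_fig1a_fixture,
)


@pytest.fixture()
def fig1a():
    return make_fig1a_fixture()


@pytest.fixture()
def fig1a_dir(tmp_path):
    out = tmp_path / "fixture"
    paths = write_fig1a_fixture(out)
    return out, paths


@pytest.fixture()
def fig1a_configs(fig1a):
    return dict(
        scan=ScanConfig(exception_ids=fig1a.exception_ids),
        filters=FilterConfig(),
        model=InheritanceModel(exception_ids=fig1a.exception_ids),
    )


@pytest.fixture()
def small_sim_config():
    """Desk-scale simulation settings (full-scale counts are exercised in
    the acceptance suite only)."""
    return SimulationConfig(
        seed=11, n_background_mean=600, n_background_sd=60, phenocopy_rate=0.0
    )


@pytest.fixture()
def trio():
    return Pedigree(
        [
            Individual("dad", sex="male", phenotype="affected"),
            Individual("mum", sex="female", phenotype="unaffected"),
            Individual("kid", father_id="dad", mother_id="mum", sex="male", phenotype="affected"),
        ],
        name="TRIO",
    )
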