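"""Shared fixtures: small seeded synthetic studies.

Everything is generated programmatically; session scope keeps the
dose-response fitting cost paid once.
"""

from __future__ import annotations

import pytest

import hipptox as h


@pytest.fixture(scope="session")
def noiseless_study():
    """Small noiseless study: exact ground-truth recovery is possible."""
    cfg = h.SimulationConfig(
        n_chemicals_per_class={"pulmonotoxic": 5, "non_pulmonotoxic": 6, "test": 3},
        n_features=8,
        noise_sd=0.0,
        nc_chemical_ids=("tox_01", "tox_02"),
        seed=11,
    )
    wells, annotations, truth = h.simulate_study(cfg)
    return cfg, wells, annotations, truth


@pytest.fixture(scope="session")
def noiseless_matrix(noiseless_study):
    cfg, wells, annotations, truth = noiseless_study
    matrix, report = h.build_delta_matrix(wells, annotations)
    return matrix, report


@pytest.fixture(scope="session")
def noisy_study():
    """Reference-chemical-sized study at the default noise level."""
    cfg = h.SimulationConfig(
        n_chemicals_per_class={"pulmonotoxic": 13, "non_pulmonotoxic": 20, "test": 17},
        n_features=10,
        nc_chemical_ids=("tox_01", "tox_02", "tox_03", "tox_04"),
        seed=5,
    )
    wells, annotations, truth = h.simulate_study(cfg)
    matrix, _ = h.build_delta_matrix(wells, annotations)
    labels = {
        a.chemical_id: a.tox_class is h.ToxClass.PULMONOTOXIC
        for a in annotations
        if a.tox_class is not h.ToxClass.TEST
    }
    nc_flags = h.nc_flags_from_wells(wells, annotations, h.NCRuleParams())
    return cfg, matrix, labels, nc_flags, truth
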