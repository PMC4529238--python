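"""Shared fixtures.

Expensive simulation fixtures are session-scoped so the calibration-level and
sampling-level checks reuse one set of track libraries and coincidence
libraries; sizes are chosen so the whole suite runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurodose import morphology, scoring, tracks


@pytest.fixture(scope="session")
def fe_spec():
    return tracks.PARTICLES["fe"]


@pytest.fixture(scope="session")
def fe_params():
    return tracks.DEFAULT_PARAMS["fe"]


@pytest.fixture(scope="session")
def fe_library_small(fe_spec, fe_params):
    """A dozen Fe histories for structural / IO / kernel-shape tests."""
    return tracks.generate_library(fe_spec, fe_params, 12, seed=420)


@pytest.fixture(scope="session")
def fe_library_300(fe_spec, fe_params):
    """Calibration-scale Fe library (LET / mean ED / containment checks)."""
    return tracks.generate_library(fe_spec, fe_params, 300, seed=42)


@pytest.fixture(scope="session")
def c_library(fe_spec):
    return tracks.generate_library(tracks.PARTICLES["c"],
                                   tracks.DEFAULT_PARAMS["c"], 400, seed=3)


@pytest.fixture(scope="session")
def core_only_library(fe_spec):
    """Fe histories with the delta-ray component switched off: every deposit
    stays within a few nm of the beam axis (useful for geometric tests)."""
    params = tracks.DEFAULT_PARAMS["fe"].replace(delta_fraction=0.0)
    return tracks.generate_library(fe_spec, params, 10, seed=9)


@pytest.fixture(scope="session")
def small_neuron():
    """A small synthetic tree (fast decoration / scoring tests)."""
    return morphology.synth_neuron(target_l_dn_um=200.0, n_branches=4, seed=11,
                                   target_extent_um=(60.0, 70.0, 30.0),
                                   dendrite_volume_um3=220.0)


@pytest.fixture(scope="session")
def small_decorated(small_neuron):
    return morphology.decorate(small_neuron, morphology.DecorationParams(), seed=5)


@pytest.fixture(scope="session")
def reference_neuron():
    """Synthetic granule-cell fixture at the reference scale."""
    return morphology.synth_neuron(seed=0)


@pytest.fixture(scope="session")
def reference_decorated(reference_neuron):
    return morphology.decorate(reference_neuron, morphology.DecorationParams(), seed=1)


@pytest.fixture(scope="session")
def scaled_geometry(reference_decorated):
    rn = reference_decorated.base.bounding_radius
    return scoring.ScoringGeometry(r_neuron_um=rn, r_gap_um=12.0,
                                   l_forward_um=40.0, l_backward_um=40.0,
                                   l_max_neuron_um=2.0 * rn + 1.0)


@pytest.fixture(scope="session")
def full_geometry():
    return scoring.ScoringGeometry(r_neuron_um=128.0, r_gap_um=150.0,
                                   l_forward_um=80.0, l_backward_um=80.0,
                                   l_max_neuron_um=262.5)


@pytest.fixture(scope="session")
def fe_coincidence_scaled(fe_library_300, reference_decorated, scaled_geometry):
    """15k Fe trials in the reduced geometry: drives the dose-sampling tests."""
    return scoring.run_trials(15000, fe_library_300, reference_decorated,
                              scaled_geometry, seed=8)


@pytest.fixture(scope="session")
def fe_coincidence_full(fe_library_300, reference_decorated, full_geometry):
    """20k Fe trials in the full-size geometry (hit-composition statistics)."""
    return scoring.run_trials(20000, fe_library_300, reference_decorated,
                              full_geometry, seed=12, volume_basis="bare")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
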