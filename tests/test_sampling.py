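"""Poisson dose realizations, compartment statistics, CV power law."""

import numpy as np
import pytest

from neurodose import morphology, sampling, scoring
from neurodose.morphology import DecorationParams, decorate
from neurodose.sampling import (
    compartment_stats,
    cv_curve,
    fit_power_law,
    sample_realization,
)


def test_zero_target_gives_empty_realization(fe_coincidence_scaled):
    r = sample_realization(fe_coincidence_scaled, 0.0, seed=1)
    assert r.n_beams == 0 and r.neuron_dose_gy == 0.0
    assert r.compartment_ed_ev.sum() == 0.0


def test_realization_energy_conservation(fe_coincidence_scaled):
    """Neuron ED equals the compartment sum and the per-trial sum exactly."""
    r = sample_realization(fe_coincidence_scaled, 0.05, seed=2)
    assert r.neuron_ed_ev == pytest.approx(r.compartment_ed_ev.sum(), rel=1e-12)
    per_trial = fe_coincidence_scaled.trial_neuron_ed_ev[r.trial_ids].sum()
    assert r.neuron_ed_ev == pytest.approx(per_trial, rel=1e-9)


def test_mean_realized_dose_unbiased_for_target(fe_coincidence_scaled, rng):
    """Library-mean calibration: realizations average to the target dose."""
    doses = np.array([sample_realization(fe_coincidence_scaled, 0.05, rng).neuron_dose_gy
                      for _ in range(300)])
    se = doses.std(ddof=1) / np.sqrt(doses.size)
    assert doses.mean() == pytest.approx(0.05, abs=3 * se)


def test_fluence_basis_mean_equals_target_times_capture(fe_coincidence_scaled, rng):
    """With the nominal dose-per-beam basis the realized neuron dose is the
    fluence target times the library's capture ratio."""
    lib = fe_coincidence_scaled
    doses = np.array([sample_realization(lib, 0.05, rng, basis="fluence").neuron_dose_gy
                      for _ in range(300)])
    expected = 0.05 * lib.capture_ratio
    se = doses.std(ddof=1) / np.sqrt(doses.size)
    assert doses.mean() == pytest.approx(expected, abs=3 * se)


def test_library_too_small_raises(fe_coincidence_scaled):
    with pytest.raises(ValueError, match="trials required"):
        sample_realization(fe_coincidence_scaled, 5.0, seed=0)


def _uniform_voxel_library(n_trials=400, seed=77):
    """Artificial library: one uniform random point deposit per trial inside
    the bounding box of eight identical, disjoint dendrite cylinders."""
    k, r, h, spacing = 8, 1.0, 8.0, 6.0
    p0 = np.array([[j * spacing, 0.0, 0.0] for j in range(k)])
    p1 = p0 + [0.0, 0.0, h]
    neuron = morphology.Neuron(p0, p1, np.full(k, r),
                               np.full(k, morphology.KIND_DENDRITE, np.int8))
    d = decorate(neuron, DecorationParams(spine_density=(0, 0),
                                          filopodia_density=(0, 0)), seed=0)
    lo = np.array([-r, -r, 0.0])
    hi = np.array([(k - 1) * spacing + r, r, h])
    box_vol = np.prod(hi - lo)
    rng = np.random.default_rng(seed)
    pts = lo + rng.random((n_trials, 3)) * (hi - lo)
    comp = np.full(n_trials, -1)
    for j in range(k):
        inside = ((pts[:, 2] >= 0) & (pts[:, 2] <= h)
                  & ((pts[:, 0] - j * spacing) ** 2 + pts[:, 1] ** 2 <= r * r))
        comp[inside] = j
    ed = 100.0
    counts = (comp >= 0).astype(np.int64)
    rec_ptr = np.concatenate(([0], np.cumsum(counts)))
    rec_comp = comp[comp >= 0].astype(np.int64)
    lib = scoring.CoincidenceLibrary(
        particle="toy", geometry=scoring.ScoringGeometry(r_neuron_um=50.0),
        decorated=d, dose_per_beam_gy=1e-6, n_trials=n_trials,
        hit=counts.astype(bool), trial_neuron_ed_ev=counts * ed,
        l_neuron_um=np.zeros(n_trials), quaternion=np.zeros((n_trials, 4)),
        entry=np.zeros((n_trials, 2)), translation_z=np.zeros(n_trials),
        rec_ptr=rec_ptr, rec_xyz=np.zeros((rec_comp.size, 3)),
        rec_ed=np.full(rec_comp.size, ed), rec_segment=rec_comp.copy(),
        rec_compartment=rec_comp)
    p_hit = np.pi * r * r * h / box_vol  # per-trial per-compartment
    return lib, p_hit


def test_percent_hit_matches_poisson_occupancy_closed_form():
    """Uniform-deposit library: %hit per compartment follows 1 - exp(-lambda)
    with lambda = expected trials x per-trial hit probability."""
    lib, p_hit = _uniform_voxel_library()
    expected_beams = 30.0
    target = expected_beams * lib.mean_trial_neuron_dose_gy
    rng = np.random.default_rng(5)
    reals = [sample_realization(lib, target, rng) for _ in range(800)]
    stats = compartment_stats(reals, lib)
    row = stats.table.set_index("group").loc["dendrite"]
    lam = expected_beams * p_hit
    closed = 100.0 * (1.0 - np.exp(-lam))
    assert row["pct_hit_mean"] == pytest.approx(closed, abs=2.0)


def test_compartment_stats_requires_two_realizations(fe_coincidence_scaled):
    with pytest.raises(ValueError):
        compartment_stats([sample_realization(fe_coincidence_scaled, 0.01, seed=1)],
                          fe_coincidence_scaled)


def test_soma_always_hit_at_moderate_dose(fe_coincidence_scaled, rng):
    """The large soma compartment is hit in every realization at >= 100 mGy."""
    reals = [sample_realization(fe_coincidence_scaled, 0.1, rng) for _ in range(100)]
    stats = compartment_stats(reals, fe_coincidence_scaled)
    soma = stats.table.set_index("group").loc["soma"]
    assert soma["pct_hit_mean"] == pytest.approx(100.0, abs=1e-9)
    # conservation: per-type EDs add up to the realization total
    g = sampling._group_codes(fe_coincidence_scaled.decorated.compartment_type)
    for r in reals[:10]:
        by_group = sum(r.compartment_ed_ev[g == c].sum() for c in range(4))
        assert by_group == pytest.approx(r.neuron_ed_ev, rel=1e-12)


def test_protrusion_hit_dose_roughly_dose_independent(fe_coincidence_scaled, rng):
    """High-LET sub-micron compartments: the mean dose among hit spines and
    filopodia shows no strong growth with the target dose (single-traversal
    dominated), unlike the whole-neuron dose."""
    means = []
    for target in (0.05, 0.15, 0.4):
        reals = [sample_realization(fe_coincidence_scaled, target, rng)
                 for _ in range(60)]
        tab = compartment_stats(reals, fe_coincidence_scaled).table.set_index("group")
        means.append(tab.loc["spine", "hit_dose_mean_gy"])
    assert means[2] < 3.0 * means[0]


def test_cv_curve_and_power_law_on_fe(fe_coincidence_scaled):
    curve = cv_curve(fe_coincidence_scaled, np.array([10, 50, 150, 500]) * 1e-3,
                     400, seed=9)
    assert np.all(np.diff(curve["cv"].to_numpy()) < 0)  # CV falls with dose
    fit = fit_power_law(curve)
    assert fit.power == pytest.approx(-0.5, abs=0.08)


def test_cv_amplitude_orders_with_let(fe_coincidence_scaled, c_library,
                                      reference_decorated, scaled_geometry):
    """At matched doses on the same neuron, the higher-LET particle has the
    larger CV amplitude."""
    co_c = scoring.run_trials(7000, c_library, reference_decorated,
                              scaled_geometry, seed=14)
    grid = np.array([5, 10, 20]) * 1e-3
    fit_fe = fit_power_law(cv_curve(fe_coincidence_scaled, grid, 250, seed=3))
    fit_c = fit_power_law(cv_curve(co_c, grid, 250, seed=3))
    assert fit_fe.amplitude > fit_c.amplitude


def test_power_law_exact_closure():
    dose = np.array([0.01, 0.05, 0.2, 1.0])
    cv = 0.37 * dose ** -0.5123
    fit = fit_power_law((dose, cv))
    assert fit.power == pytest.approx(-0.5123, abs=1e-10)
    assert fit.amplitude == pytest.approx(0.37, rel=1e-10)
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)


def test_power_law_excludes_nonpositive_cv():
    dose = np.array([0.01, 0.05, 0.2, 1.0])
    cv = np.array([1.0, 0.5, 0.0, 0.25])
    with pytest.warns(UserWarning, match="non-positive"):
        fit = fit_power_law((dose, cv))
    assert fit.dose_gy.size == 3


def test_power_law_needs_three_points():
    with pytest.raises(ValueError):
        fit_power_law((np.array([0.1, 1.0]), np.array([1.0, 0.3])))


def test_cv_curve_rejects_nonpositive_grid(fe_coincidence_scaled):
    with pytest.raises(ValueError):
        cv_curve(fe_coincidence_scaled, [0.0, 0.1], 10, seed=1)
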