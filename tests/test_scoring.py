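"""Scoring: dose formulas, beam construction, coincidence detection."""

import numpy as np
import pytest

from neurodose import morphology, scoring, tracks
from neurodose.morphology import DecorationParams, decorate
from neurodose.scoring import (
    Beam,
    ScoringGeometry,
    build_beam,
    dose_from_track_crossing,
    dose_per_beam,
    orient_neuron,
    random_rotation,
    run_trials,
    score_trial,
    voxel_in_cylinder,
)


class TestDosePerBeam:
    def test_iron_reference_value(self):
        assert dose_per_beam(172.4, 278.0) == pytest.approx(1.14e-4, rel=0.01)

    def test_carbon_reference_value(self):
        # printed value carries LET rounding; <=1% apart
        assert dose_per_beam(12.9, 318.0) == pytest.approx(6.51e-6, rel=0.01)

    def test_zero_let(self):
        assert dose_per_beam(0.0, 100.0) == 0.0

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            dose_per_beam(10.0, 0.0)

    def test_fluence_dose_identity(self, fe_coincidence_scaled):
        lib = fe_coincidence_scaled
        assert lib.fluence_dose_gy == lib.n_trials * lib.dose_per_beam_gy


def test_soma_crossing_worked_example():
    """A 172 keV/um track crossing 10 um of soma, keeping 80% of its energy
    in a 2700 um^3 neuron, deposits ~81.5 mGy."""
    dose = dose_from_track_crossing(172.0, 10.0, 0.8, 2700.0)
    assert 1e3 * dose == pytest.approx(81.5, rel=0.005)


class TestBuildBeam:
    def test_ion_history_count_300um(self, fe_library_small):
        beam = build_beam(fe_library_small, (0, 0), 300.0, seed=1)
        assert beam.n_history == 15
        np.testing.assert_allclose(beam.z_offsets, np.arange(15) * 20.0)

    def test_ion_history_count_single(self, fe_library_small):
        assert build_beam(fe_library_small, (0, 0), 20.0, seed=1).n_history == 1

    def test_electron_chaining(self):
        lib = tracks.generate_library(tracks.PARTICLES["e"],
                                      tracks.DEFAULT_PARAMS["e"], 30, seed=2)
        beam = build_beam(lib, (1.0, -2.0), 300.0, seed=3)
        # each history starts at the previous history's final voxel z
        ends = np.array([lib.histories[h].final_z_um for h in beam.history_ids])
        np.testing.assert_allclose(beam.z_offsets[1:],
                                   np.cumsum(ends)[:-1], rtol=1e-12)
        assert beam.z_offsets[0] == 0.0
        assert beam.z_offsets[-1] + ends[-1] >= 300.0
        # mean extent ~46.4 um -> ~7 histories
        assert 6 <= beam.n_history <= 8

    def test_empty_library_rejected(self, fe_library_small):
        with pytest.raises(ValueError):
            build_beam(fe_library_small, (0, 0), 100.0, mode="muon", seed=0)


class TestOrientNeuron:
    def test_identity_rotation_preserves_z_extent(self, small_decorated):
        geom = ScoringGeometry(r_neuron_um=50.0, r_gap_um=10.0,
                               l_forward_um=20.0, l_backward_um=20.0)
        moved, l_n, (R, t) = orient_neuron(small_decorated, geom, seed=0,
                                           rotation=np.eye(3))
        segs = small_decorated.segments
        native = np.vstack((segs.p0, segs.p1))[:, 2]
        assert l_n == pytest.approx(native.max() - native.min())
        assert t[2] == pytest.approx(geom.l_forward + l_n / 2)

    def test_rigid_motion_preserves_pairwise_distances(self, small_decorated):
        geom = ScoringGeometry(r_neuron_um=50.0, r_gap_um=10.0)
        moved, _, _ = orient_neuron(small_decorated, geom, seed=3)
        a = small_decorated.segments
        da = np.linalg.norm(a.p1 - a.p0, axis=1)
        db = np.linalg.norm(moved.p1 - moved.p0, axis=1)
        np.testing.assert_allclose(da, db, atol=1e-9)
        ca = np.linalg.norm(a.p0[1:] - a.p0[:-1], axis=1)
        cb = np.linalg.norm(moved.p0[1:] - moved.p0[:-1], axis=1)
        np.testing.assert_allclose(ca, cb, atol=1e-9)

    def test_l_neuron_range_over_orientations(self, reference_decorated):
        geom = ScoringGeometry(r_neuron_um=130.0, r_gap_um=10.0)
        rng = np.random.default_rng(6)
        ls = [orient_neuron(reference_decorated, geom, rng)[1] for _ in range(200)]
        # thinnest projection well below the diagonal; never exceeds it
        assert min(ls) < 130.0
        assert max(ls) <= reference_decorated.base.diagonal + 1e-6


class TestVoxelInCylinder:
    P0, P1, R = np.zeros(3), np.array([0.0, 0.0, 4.0]), 1.5

    def test_axis_midpoint_inside(self):
        assert voxel_in_cylinder([0, 0, 2.0], self.P0, self.P1, self.R)

    def test_cap_exclusion(self):
        assert not voxel_in_cylinder([0, 0, 4.0 + 1e-9], self.P0, self.P1, self.R)
        assert voxel_in_cylinder([0, 0, 4.0], self.P0, self.P1, self.R)

    def test_degenerate_segment_absent(self):
        assert not voxel_in_cylinder([0, 0, 0], self.P0, self.P0, self.R)

    def test_agreement_with_transform_oracle(self, rng):
        """Independent membership oracle: express each point in the cylinder's
        orthonormal frame and compare coordinates against (h, r)."""
        for _ in range(10):
            p0 = rng.uniform(-5, 5, 3)
            axis = rng.standard_normal(3)
            h = rng.uniform(0.5, 4.0)
            p1 = p0 + h * axis / np.linalg.norm(axis)
            r = rng.uniform(0.2, 2.0)
            u = (p1 - p0) / h
            a = np.array([u[1] - u[2], u[2] - u[0], u[0] - u[1]])
            a -= (a @ u) * u
            e1 = a / np.linalg.norm(a)
            e2 = np.cross(u, e1)
            pts = p0 + rng.uniform(-1.2, 1.2, (1000, 3)) * (h + 2 * r)
            for p in pts[:100]:
                w = p - p0
                coords = np.array([w @ e1, w @ e2, w @ u])
                expected = (0 <= coords[2] <= h) and np.hypot(*coords[:2]) <= r
                assert voxel_in_cylinder(p, p0, p1, r) == expected


def _brute_force_score(beam: Beam, decorated, rotation, translation, center):
    """All-voxels vs all-segments reference scorer with the same priority rule
    (head > neck > dendrite > soma, lowest index on ties)."""
    x, y, z, ed = beam.voxels()
    pts = np.column_stack((x, y, z))
    q = (pts - translation) @ rotation + center  # rotation applied as R^T
    segs = decorated.segments
    out = []
    for i, p in enumerate(q):
        best = -1
        best_kind = -1
        for s in range(segs.n_segments):
            if voxel_in_cylinder(p, segs.p0[s], segs.p1[s], segs.radius[s]):
                k = int(segs.kind[s])
                if k > best_kind or (k == best_kind and s < best):
                    best_kind, best = k, s
        if best >= 0:
            out.append((i, best, ed[i]))
    return out


def test_pruned_scoring_equals_exhaustive(small_decorated, c_library):
    """Grid-indexed kernel scoring is exactly the brute-force result."""
    beam = build_beam(c_library, (2.0, -1.0), 40.0, seed=4)
    rng = np.random.default_rng(17)
    R = random_rotation(rng)
    center = small_decorated.base.center
    m = center + np.array([1.0, 0.5, -2.0])
    rec = score_trial(beam, small_decorated, ScoringGeometry(r_neuron_um=60.0),
                      rotation=R, translation=m)
    ref = _brute_force_score(beam, small_decorated, R, m, center)
    assert len(ref) == rec.voxel_ed.size
    ref_seg = sorted((s, round(e, 6)) for _, s, e in ref)
    got_seg = sorted(zip(rec.voxel_segment.tolist(),
                         np.round(rec.voxel_ed, 6).tolist()))
    assert ref_seg == got_seg


def test_coincident_energy_bounded_by_beam_energy(small_decorated, c_library):
    beam = build_beam(c_library, (0.0, 0.0), 40.0, seed=5)
    rec = score_trial(beam, small_decorated, ScoringGeometry(r_neuron_um=60.0))
    assert rec.neuron_ed_ev <= beam.total_ed + 1e-6


def test_distant_entry_cannot_hit(small_decorated, core_only_library):
    """With delta rays off, all deposits hug the axis: an entry far outside
    the neuron's bounding sphere cannot produce a coincidence."""
    far = small_decorated.base.bounding_radius + 50.0
    beam = build_beam(core_only_library, (far, 0.0), 40.0, seed=6)
    rec = score_trial(beam, small_decorated,
                      ScoringGeometry(r_neuron_um=far + 10))
    assert not rec.hit


def test_back_transformed_records_inside_tagged_segment(fe_coincidence_scaled,
                                                        reference_decorated):
    """Closure: recorded fixed-frame voxels lie inside their owning segment."""
    co = fe_coincidence_scaled
    segs = reference_decorated.segments
    take = min(co.rec_ed.size, 3000)
    idx = np.linspace(0, co.rec_ed.size - 1, take).astype(int)
    for i in idx:
        s = co.rec_segment[i]
        assert voxel_in_cylinder(co.rec_xyz[i], segs.p0[s], segs.p1[s],
                                 segs.radius[s] + 1e-6)


def test_hit_probability_monotone_in_target_radius(core_only_library):
    """Growing ball-like targets are hit more often at fixed track library."""
    fractions = []
    for radius in (4.0, 12.0, 30.0):
        p0 = np.array([[0.0, -radius, 0.0]])
        p1 = np.array([[0.0, radius, 0.0]])
        n = morphology.Neuron(p0, p1, np.array([radius]),
                              np.array([morphology.KIND_SOMA], np.int8))
        d = decorate(n, DecorationParams(spine_density=(0, 0),
                                         filopodia_density=(0, 0)), seed=0)
        geom = ScoringGeometry(r_neuron_um=40.0, r_gap_um=5.0,
                               l_forward_um=10.0, l_backward_um=10.0,
                               l_max_neuron_um=100.0)
        co = run_trials(400, core_only_library, d, geom, seed=3)
        fractions.append(co.hit_fraction)
    assert fractions[0] < fractions[1] < fractions[2]


def test_run_trials_rejects_empty(fe_library_small, small_decorated):
    with pytest.raises(ValueError):
        run_trials(0, fe_library_small, small_decorated,
                   ScoringGeometry(r_neuron_um=50.0), seed=0)


def test_scoring_invariant_under_neuron_frame_rotation(small_decorated, c_library):
    """Scoring a beam against the neuron placed by (R, t) equals scoring the
    rigidly pre-transformed neuron at identity placement (energy and count)."""
    rng = np.random.default_rng(31)
    R = random_rotation(rng)
    c0 = small_decorated.base.center
    m = np.array([0.0, 0.0, 60.0])
    beam = build_beam(c_library, (1.5, 0.5), 120.0, seed=9)
    rec = score_trial(beam, small_decorated, ScoringGeometry(r_neuron_um=60.0),
                      rotation=R, translation=m)

    # pre-transform the whole decorated neuron: p -> R (p - c0) + m
    segs = small_decorated.segments
    moved_base = small_decorated.base.transformed(R, m - R @ c0)
    moved_segs = morphology.Neuron((segs.p0 - c0) @ R.T + m,
                                   (segs.p1 - c0) @ R.T + m,
                                   segs.radius.copy(), segs.kind.copy())
    import dataclasses
    moved = dataclasses.replace(small_decorated, base=moved_base,
                                segments=moved_segs)
    rec2 = score_trial(beam, moved, ScoringGeometry(r_neuron_um=60.0),
                       rotation=np.eye(3), translation=moved_base.center)
    assert rec2.voxel_ed.size == rec.voxel_ed.size
    assert rec2.neuron_ed_ev == pytest.approx(rec.neuron_ed_ev, rel=1e-9)
    np.testing.assert_array_equal(np.sort(rec2.voxel_segment),
                                  np.sort(rec.voxel_segment))
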