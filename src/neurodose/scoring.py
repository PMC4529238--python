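"""Beam construction and beam-neuron coincidence scoring.

The scoring construction uses two co-axial cylinders along +z: the neuron is
bounded by Cyl_Neuron (radius R_Neuron) which is embedded, with build-up
margins L_Forward / L_Backward / R_Gap, in the fluence cylinder Cyl_Score
(radius R_Score = R_Gap + R_Neuron).  Each trial draws a beam entry point
uniformly on the R_Score disc, stitches random track histories along +z to
cover the trial's scoring length, rotates the neuron uniformly about its
geometric center, and records every beam voxel that falls inside a neuronal
segment, back-transformed into the fixed neuron frame and attributed to
exactly one segment (spine/filopodium head > neck > dendrite > soma).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._accel import score_trial_kernel
from .morphology import DecoratedNeuron, Neuron
from .tracks import TrackLibrary

logger = logging.getLogger(__name__)

__all__ = [
    "EV_UM3_TO_GY",
    "DEFAULT_R_SCORE_UM",
    "ScoringGeometry",
    "Beam",
    "TrialRecord",
    "CoincidenceLibrary",
    "dose_per_beam",
    "dose_from_track_crossing",
    "build_beam",
    "random_rotation",
    "orient_neuron",
    "voxel_in_cylinder",
    "score_trial",
    "run_trials",
]

# 1 eV deposited per um^3 of water: 1.602e-19 J / 1e-15 kg
EV_UM3_TO_GY = 1.602e-4

# fluence radii used with the reference neuron, per particle
DEFAULT_R_SCORE_UM = {"fe": 278.0, "c": 318.0, "h": 178.0, "e": 318.0}


@dataclass(frozen=True)
class ScoringGeometry:
    """Co-axial cylinder construction: R_Score = R_Gap + R_Neuron."""

    r_neuron_um: float = 128.0
    r_gap_um: float = 150.0
    l_forward_um: float = 80.0
    l_backward_um: float = 80.0
    l_max_neuron_um: float = 256.0

    def __post_init__(self) -> None:
        if self.r_neuron_um <= 0 or self.r_gap_um < 0:
            raise ValueError("radii must be positive (gap non-negative)")
        if self.l_forward_um < 0 or self.l_backward_um < 0:
            raise ValueError("build-up lengths must be non-negative")

    @property
    def r_neuron(self) -> float:
        return self.r_neuron_um

    @property
    def r_score(self) -> float:
        return self.r_gap_um + self.r_neuron_um

    @property
    def a_score_um2(self) -> float:
        return np.pi * self.r_score**2

    @property
    def l_forward(self) -> float:
        return self.l_forward_um

    @property
    def l_backward(self) -> float:
        return self.l_backward_um


def dose_per_beam(let_kev_um: float, r_score_um: float) -> float:
    """Mean dose (Gy) to the scoring cylinder from one traversal.

    0.16 * LET (keV/um) / A_Score (um^2): LET over the cylinder cross-section
    at water density, with 0.16 = 1.602e-16 J/keV over 1e-15 kg/um^3.
    """
    if r_score_um <= 0:
        raise ValueError("R_Score must be positive")
    if let_kev_um < 0:
        raise ValueError("LET must be non-negative")
    return 0.16 * let_kev_um / (np.pi * r_score_um**2)


def dose_from_track_crossing(let_kev_um: float, path_um: float,
                             deposited_fraction: float, volume_um3: float) -> float:
    """Dose (Gy) a single track crossing leaves in a compartment.

    LET * path length * retained fraction, normalized by the compartment's
    water mass — e.g. a 172 keV/um track crossing 10 um of soma and keeping
    80% of its energy in a 2700 um^3 neuron deposits ~81.5 mGy.
    """
    return let_kev_um * 1e3 * path_um * deposited_fraction * EV_UM3_TO_GY / volume_um3


@dataclass
class Beam:
    """Stitched particle beam entering Cyl_Score at (x, y, 0) along +z."""

    library: TrackLibrary
    entry: tuple[float, float]
    mode: str
    history_ids: np.ndarray
    z_offsets: np.ndarray
    l_score_um: float

    @property
    def n_history(self) -> int:
        return int(self.history_ids.size)

    def voxels(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Beam voxels in the scoring frame."""
        xs, ys, zs, es = [], [], [], []
        ex, ey = self.entry
        for hid, off in zip(self.history_ids, self.z_offsets):
            h = self.library.histories[hid]
            xs.append(h.x + ex)
            ys.append(h.y + ey)
            zs.append(h.z + off)
            es.append(h.ed)
        return (np.concatenate(xs), np.concatenate(ys),
                np.concatenate(zs), np.concatenate(es))

    @property
    def total_ed(self) -> float:
        return float(sum(self.library.histories[h].total_ed for h in self.history_ids))


def build_beam(lib: TrackLibrary, entry: tuple[float, float], l_score_um: float,
               mode: str | None = None, seed: int | np.random.Generator = 0) -> Beam:
    """Stitch random histories into a beam covering ``l_score_um``.

    Ions: N_History = ceil(L_Score / L_Track) histories at offsets k * L_Track.
    Electrons: each history starts at the previous history's final on-axis
    voxel z (the first at z = 0), re-centered laterally on the entry point,
    until the chain covers L_Score.
    """
    if lib.n_histories == 0:
        raise ValueError("empty track library")
    mode = mode or lib.spec.kind
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if mode == "ion":
        n = int(np.ceil(l_score_um / lib.spec.l_track_um))
        ids = rng.integers(0, lib.n_histories, n)
        offs = np.arange(n) * lib.spec.l_track_um
    elif mode == "electron":
        ids_list, offs_list = [], []
        z = 0.0
        while z < l_score_um:
            hid = int(rng.integers(0, lib.n_histories))
            ids_list.append(hid)
            offs_list.append(z)
            z += max(lib.histories[hid].final_z_um, 1e-6)
        ids = np.asarray(ids_list)
        offs = np.asarray(offs_list, dtype=float)
    else:
        raise ValueError(f"unknown beam mode {mode!r}")
    return Beam(lib, tuple(entry), mode, ids, offs, l_score_um)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion sampling)."""
    q = rng.standard_normal(4)
    return _quat_to_matrix(q / np.linalg.norm(q))


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def orient_neuron(decorated: DecoratedNeuron, geometry: ScoringGeometry,
                  seed: int | np.random.Generator,
                  rotation: np.ndarray | None = None
                  ) -> tuple[Neuron, float, tuple[np.ndarray, np.ndarray]]:
    """Randomly rotate the neuron about its geometric center and place it in
    the scoring cylinder.

    Returns the transformed segment set, the trial's z-extent L_Neuron_i, and
    the (rotation, translation) pair mapping fixed-frame points into the
    scoring frame: p_scoring = R @ (p_fixed - c0) + t.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R = random_rotation(rng) if rotation is None else np.asarray(rotation)
    c0 = decorated.base.center
    segs = decorated.segments
    pts = np.vstack((segs.p0, segs.p1)) - c0
    zr = pts @ R[2]
    l_neuron = float(zr.max() - zr.min())
    t = np.array([0.0, 0.0, geometry.l_forward + 0.5 * l_neuron])
    moved = Neuron((segs.p0 - c0) @ R.T + t, (segs.p1 - c0) @ R.T + t,
                   segs.radius.copy(), segs.kind.copy())
    return moved, l_neuron, (R, t)


def voxel_in_cylinder(p, p0, p1, radius: float) -> bool:
    """Point-in-cylinder test with closed caps and wall.

    True iff the axial projection lies in [0, h] and the radial distance from
    the axis is at most ``radius``.  Zero-length segments are treated as
    absent (logged once at debug level).
    """
    p, p0, p1 = (np.asarray(a, dtype=float) for a in (p, p0, p1))
    axis = p1 - p0
    h = np.linalg.norm(axis)
    if h == 0.0:
        logger.debug("degenerate zero-length segment treated as absent")
        return False
    u = axis / h
    w = p - p0
    t = float(w @ u)
    if t < 0.0 or t > h:
        return False
    return float(w @ w - t * t) <= radius * radius


@dataclass
class TrialRecord:
    """One scored trial: transform, hit flag and coincident voxels (fixed frame)."""

    trial_id: int
    rotation: np.ndarray
    translation: np.ndarray
    entry: tuple[float, float]
    l_neuron_um: float
    hit: bool
    voxel_xyz: np.ndarray
    voxel_ed: np.ndarray
    voxel_segment: np.ndarray
    voxel_compartment: np.ndarray

    @property
    def neuron_ed_ev(self) -> float:
        return float(self.voxel_ed.sum())


class _SegmentIndex:
    """Uniform-grid broad-phase index over a decorated neuron's segments."""

    def __init__(self, decorated: DecoratedNeuron, cell_um: float = 4.0):
        segs = decorated.segments
        axis = segs.p1 - segs.p0
        h = np.linalg.norm(axis, axis=1)
        keep = h > 0
        if not np.all(keep):
            logger.warning("%d zero-length segments excluded from scoring",
                           int((~keep).sum()))
        self.seg_p0 = np.ascontiguousarray(segs.p0)
        self.seg_u = np.zeros_like(self.seg_p0)
        self.seg_u[keep] = axis[keep] / h[keep, None]
        self.seg_h = np.where(keep, h, -1.0)
        self.seg_r2 = segs.radius**2
        self.seg_kind = segs.kind.astype(np.int8)
        self.seg_comp = decorated.segment_compartment.astype(np.int64)
        lo = np.minimum(segs.p0, segs.p1) - segs.radius[:, None]
        hi = np.maximum(segs.p0, segs.p1) + segs.radius[:, None]
        self.box_lo = lo.min(axis=0) - 1e-9
        self.box_hi = hi.max(axis=0) + 1e-9
        self.cell = cell_um
        dims = np.maximum(np.ceil((self.box_hi - self.box_lo) / cell_um), 1).astype(int)
        self.ncx, self.ncy, self.ncz = (int(d) for d in dims)
        ncell = self.ncx * self.ncy * self.ncz
        cells: list[list[int]] = [[] for _ in range(ncell)]
        ilo = np.floor((lo - self.box_lo) / cell_um).astype(int)
        ihi = np.floor((hi - self.box_lo) / cell_um).astype(int)
        ilo = np.clip(ilo, 0, dims - 1)
        ihi = np.clip(ihi, 0, dims - 1)
        for s in range(segs.n_segments):
            if not keep[s]:
                continue
            for cx in range(ilo[s, 0], ihi[s, 0] + 1):
                for cy in range(ilo[s, 1], ihi[s, 1] + 1):
                    for cz in range(ilo[s, 2], ihi[s, 2] + 1):
                        cells[(cx * self.ncy + cy) * self.ncz + cz].append(s)
        counts = np.array([len(c) for c in cells], dtype=np.int64)
        self.cell_ptr = np.concatenate(([0], np.cumsum(counts)))
        self.cell_list = (np.concatenate([np.asarray(c, dtype=np.int64) for c in cells])
                          if counts.sum() else np.empty(0, dtype=np.int64))
        c0 = decorated.base.center
        pts = np.vstack((segs.p0, segs.p1)) - c0
        pad = np.concatenate((segs.radius, segs.radius))
        self.bound_radius = float((np.linalg.norm(pts, axis=1) + pad).max())
        self.center = c0


def _bank(lib: TrackLibrary) -> tuple[np.ndarray, ...]:
    xs = np.concatenate([h.x for h in lib.histories])
    ys = np.concatenate([h.y for h in lib.histories])
    zs = np.concatenate([h.z for h in lib.histories])
    es = np.concatenate([h.ed for h in lib.histories])
    ptr = np.concatenate(([0], np.cumsum([h.n_voxels for h in lib.histories]))).astype(np.int64)
    return xs, ys, zs, es, ptr


def score_trial(beam: Beam, decorated: DecoratedNeuron, geometry: ScoringGeometry,
                trial_id: int = 0, rotation: np.ndarray | None = None,
                translation: np.ndarray | None = None,
                index: "_SegmentIndex | None" = None,
                buffer_size: int = 400_000) -> TrialRecord:
    """Score one beam against one oriented neuron.

    ``rotation``/``translation`` define the neuron placement (fixed frame ->
    scoring frame about the geometric center); identity placement is used if
    omitted.  Coincident voxels are reported back-transformed into the fixed
    neuron frame with one owning segment each.
    """
    if index is None:
        index = _SegmentIndex(decorated)
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    if translation is None:
        translation = index.center.copy()
    m = np.asarray(translation, dtype=float)
    bank_x, bank_y, bank_z, bank_ed, ptr = _bank(beam.library)
    sel = beam.history_ids.astype(np.int64)
    zoff = beam.z_offsets.astype(float)
    out_xyz = np.empty((buffer_size, 3))
    out_ed = np.empty(buffer_size)
    out_seg = np.empty(buffer_size, dtype=np.int64)
    rb = index.bound_radius
    n = score_trial_kernel(
        bank_x, bank_y, bank_z, bank_ed, ptr, sel, zoff,
        float(beam.entry[0]), float(beam.entry[1]),
        np.ascontiguousarray(R.T), m, index.center, rb * rb,
        index.box_lo, index.box_hi,
        index.box_lo, index.cell, index.ncx, index.ncy, index.ncz,
        index.cell_ptr, index.cell_list,
        index.seg_p0, index.seg_u, index.seg_h, index.seg_r2,
        index.seg_kind, index.seg_comp,
        out_xyz, out_ed, out_seg)
    if n < 0:
        raise RuntimeError("coincidence buffer overflow; raise buffer_size")
    seg = out_seg[:n].copy()
    return TrialRecord(
        trial_id=trial_id, rotation=R, translation=m, entry=beam.entry,
        l_neuron_um=0.0, hit=n > 0,
        voxel_xyz=out_xyz[:n].copy(), voxel_ed=out_ed[:n].copy(),
        voxel_segment=seg, voxel_compartment=index.seg_comp[seg])


@dataclass
class CoincidenceLibrary:
    """Per-trial coincidence records for one particle/neuron/geometry."""

    particle: str
    geometry: ScoringGeometry
    decorated: DecoratedNeuron
    dose_per_beam_gy: float
    n_trials: int
    hit: np.ndarray
    trial_neuron_ed_ev: np.ndarray
    l_neuron_um: np.ndarray
    quaternion: np.ndarray
    entry: np.ndarray
    translation_z: np.ndarray
    rec_ptr: np.ndarray
    rec_xyz: np.ndarray
    rec_ed: np.ndarray
    rec_segment: np.ndarray
    rec_compartment: np.ndarray
    seed: int | None = None
    volume_basis: str = "decorated"  # "decorated" | "bare"

    @property
    def neuron_volume_um3(self) -> float:
        if self.volume_basis == "bare":
            return self.decorated.base.total_volume
        return self.decorated.total_volume

    @property
    def fluence_dose_gy(self) -> float:
        """Exact by construction: trials x dose per beam."""
        return self.n_trials * self.dose_per_beam_gy

    @property
    def neuron_dose_gy(self) -> float:
        return float(self.trial_neuron_ed_ev.sum()) * EV_UM3_TO_GY / self.neuron_volume_um3

    @property
    def hit_fraction(self) -> float:
        return float(self.hit.mean())

    @property
    def mean_trial_neuron_dose_gy(self) -> float:
        return float(self.trial_neuron_ed_ev.mean()) * EV_UM3_TO_GY / self.neuron_volume_um3

    @property
    def capture_ratio(self) -> float:
        """Measured neuron dose / fluence dose (electronic-equilibrium deficit)."""
        return self.neuron_dose_gy / self.fluence_dose_gy

    def trial_records(self, ids) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(compartment, ed, xyz-row-index) records of the selected trials."""
        ids = np.asarray(ids)
        counts = self.rec_ptr[ids + 1] - self.rec_ptr[ids]
        idx = np.repeat(self.rec_ptr[ids], counts) + (
            np.arange(int(counts.sum())) -
            np.repeat(np.concatenate(([0], np.cumsum(counts)[:-1])), counts))
        return self.rec_compartment[idx], self.rec_ed[idx], idx


def run_trials(n_trials: int, lib: TrackLibrary, decorated: DecoratedNeuron,
               geometry: ScoringGeometry, seed: int,
               volume_basis: str = "decorated", cell_um: float = 4.0,
               chunk_log: int | None = None) -> CoincidenceLibrary:
    """Run ``n_trials`` independent beam-neuron coincidence trials.

    Each trial draws a fresh uniform entry point on the R_Score disc, a fresh
    uniform rotation of the neuron about its geometric center, stitches a beam
    over L_Score_i = L_Forward + L_Neuron_i + L_Backward, and records the
    coincident voxels in the fixed neuron frame.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    index = _SegmentIndex(decorated, cell_um)
    bank_x, bank_y, bank_z, bank_ed, ptr = _bank(lib)
    spec = lib.spec

    # per-trial randomness, drawn up-front in a fixed order
    q = rng.standard_normal((n_trials, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    rho = geometry.r_score * np.sqrt(rng.random(n_trials))
    phi = rng.uniform(0.0, 2.0 * np.pi, n_trials)
    entry = np.column_stack((rho * np.cos(phi), rho * np.sin(phi)))

    segs = decorated.segments
    pts = np.vstack((segs.p0, segs.p1)) - decorated.base.center

    hit = np.zeros(n_trials, dtype=bool)
    ned = np.zeros(n_trials)
    lneu = np.zeros(n_trials)
    tz = np.zeros(n_trials)
    rec_counts = np.zeros(n_trials, dtype=np.int64)
    buf_xyz = np.empty((400_000, 3))
    buf_ed = np.empty(400_000)
    buf_seg = np.empty(400_000, dtype=np.int64)
    all_xyz, all_ed, all_seg = [], [], []

    mean_hist_len = (spec.l_track_um if spec.kind == "ion"
                     else max(lib.mean_final_z_um, 1e-6))
    for i in range(n_trials):
        R = _quat_to_matrix(q[i])
        zr = pts @ R[2]
        l_n = float(zr.max() - zr.min())
        lneu[i] = min(l_n, geometry.l_max_neuron_um)
        l_score = geometry.l_forward + lneu[i] + geometry.l_backward
        if spec.kind == "ion":
            nh = int(np.ceil(l_score / spec.l_track_um))
            sel = rng.integers(0, lib.n_histories, nh).astype(np.int64)
            zoff = np.arange(nh) * spec.l_track_um
        else:
            nh_guess = int(np.ceil(l_score / mean_hist_len)) + 4
            while True:
                sel = rng.integers(0, lib.n_histories, nh_guess).astype(np.int64)
                ends = np.cumsum([lib.histories[s].final_z_um for s in sel])
                if ends[-1] >= l_score:
                    break
                nh_guess *= 2
            keep = int(np.searchsorted(ends, l_score) + 1)
            sel = sel[:keep]
            zoff = np.concatenate(([0.0], ends[:keep - 1]))
        tz[i] = geometry.l_forward + 0.5 * lneu[i]
        m = np.array([0.0, 0.0, tz[i]])
        nrec = score_trial_kernel(
            bank_x, bank_y, bank_z, bank_ed, ptr, sel, zoff.astype(float),
            float(entry[i, 0]), float(entry[i, 1]),
            np.ascontiguousarray(R.T), m, index.center,
            index.bound_radius**2, index.box_lo, index.box_hi,
            index.box_lo, index.cell, index.ncx, index.ncy, index.ncz,
            index.cell_ptr, index.cell_list,
            index.seg_p0, index.seg_u, index.seg_h, index.seg_r2,
            index.seg_kind, index.seg_comp,
            buf_xyz, buf_ed, buf_seg)
        if nrec < 0:
            raise RuntimeError("coincidence buffer overflow in trial %d" % i)
        rec_counts[i] = nrec
        if nrec:
            hit[i] = True
            ned[i] = buf_ed[:nrec].sum()
            all_xyz.append(buf_xyz[:nrec].copy())
            all_ed.append(buf_ed[:nrec].copy())
            all_seg.append(buf_seg[:nrec].copy())
        if chunk_log and (i + 1) % chunk_log == 0:
            logger.info("scored %d/%d trials (hit fraction %.3f)",
                        i + 1, n_trials, hit[:i + 1].mean())

    rec_ptr = np.concatenate(([0], np.cumsum(rec_counts)))
    if all_ed:
        rec_xyz = np.vstack(all_xyz)
        rec_ed = np.concatenate(all_ed)
        rec_seg = np.concatenate(all_seg)
    else:
        rec_xyz = np.empty((0, 3))
        rec_ed = np.empty(0)
        rec_seg = np.empty(0, dtype=np.int64)
    return CoincidenceLibrary(
        particle=spec.name, geometry=geometry, decorated=decorated,
        dose_per_beam_gy=dose_per_beam(spec.let_kev_um, geometry.r_score),
        n_trials=n_trials, hit=hit, trial_neuron_ed_ev=ned, l_neuron_um=lneu,
        quaternion=q, entry=entry, translation_z=tz,
        rec_ptr=rec_ptr, rec_xyz=rec_xyz, rec_ed=rec_ed, rec_segment=rec_seg,
        rec_compartment=index.seg_comp[rec_seg] if rec_seg.size else np.empty(0, np.int64),
        seed=seed, volume_basis=volume_basis)
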