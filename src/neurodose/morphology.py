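"""SWC neuron morphology, morphometrics, and stochastic spine/filopodia
decoration.

The soma and dendrites are right circular cylinders built from SWC
child-parent record pairs.  Spines and filopodia are added stochastically:
counts are drawn from normal linear densities per 10 um of dendrite, anchors
are uniform over the dendritic arc length with a minimum pairwise separation
enforced by re-placement, and each protrusion is realized as a neck cylinder
on the dendrite surface plus a distal head cylinder with per-instance
dimensions drawn from per-type normal distributions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "KIND_SOMA",
    "KIND_DENDRITE",
    "KIND_NECK",
    "KIND_HEAD",
    "COMPARTMENT_TYPES",
    "Neuron",
    "DecoratedNeuron",
    "ProtrusionGeometry",
    "DecorationParams",
    "read_swc",
    "morphometrics",
    "decorate",
    "compartment_table",
    "compartment_summary",
    "sample_protrusion_volumes",
    "protrusion_mean_volume",
    "synth_neuron",
]

# segment kinds (scoring priority order: head > neck > dendrite > soma)
KIND_SOMA, KIND_DENDRITE, KIND_NECK, KIND_HEAD = 0, 1, 2, 3
KIND_NAMES = {KIND_SOMA: "soma", KIND_DENDRITE: "dendrite",
              KIND_NECK: "neck", KIND_HEAD: "head"}

COMPARTMENT_TYPES = ("soma", "dendrite", "spine_long", "spine_mushroom",
                     "spine_stubby", "filopodium")
CTYPE_SOMA, CTYPE_DENDRITE = 0, 1
CTYPE_LONG, CTYPE_MUSHROOM, CTYPE_STUBBY, CTYPE_FILOPODIUM = 2, 3, 4, 5


class SWCError(ValueError):
    """Malformed SWC content."""


@dataclass
class Neuron:
    """Cylindrical-segment neuron: axis endpoints, radii and kinds.

    ``p0``/``p1`` are (n, 3) axis endpoints in um (parent end first), ``radius``
    the cylinder radii and ``kind`` the segment kinds.  ``node_id``/``parent_id``
    keep the SWC topology for branch counting.
    """

    p0: np.ndarray
    p1: np.ndarray
    radius: np.ndarray
    kind: np.ndarray
    node_id: np.ndarray | None = None
    parent_id: np.ndarray | None = None

    @property
    def n_segments(self) -> int:
        return int(self.radius.size)

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.p1 - self.p0, axis=1)

    @property
    def volumes(self) -> np.ndarray:
        return np.pi * self.radius**2 * self.lengths

    @property
    def l_dn(self) -> float:
        """Total dendritic branch length (um)."""
        return float(self.lengths[self.kind == KIND_DENDRITE].sum())

    @property
    def soma_volume(self) -> float:
        return float(self.volumes[self.kind == KIND_SOMA].sum())

    @property
    def dendrite_volume(self) -> float:
        return float(self.volumes[self.kind == KIND_DENDRITE].sum())

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def _points(self) -> np.ndarray:
        return np.vstack((self.p0, self.p1))

    @property
    def extents(self) -> tuple[float, float, float]:
        """Axis-aligned (width, height, depth) of all segment endpoints."""
        pts = self._points()
        w, h, d = pts.max(axis=0) - pts.min(axis=0)
        return float(w), float(h), float(d)

    @property
    def diagonal(self) -> float:
        return float(np.linalg.norm(self.extents))

    @property
    def center(self) -> np.ndarray:
        """Geometric center: midpoint of the axis-aligned bounding box."""
        pts = self._points()
        return 0.5 * (pts.max(axis=0) + pts.min(axis=0))

    @property
    def bounding_radius(self) -> float:
        """Radius of the sphere about the center enclosing every segment."""
        d = np.linalg.norm(self._points() - self.center, axis=1)
        pad = np.concatenate((self.radius, self.radius))
        return float((d + pad).max())

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Neuron":
        """Rigidly transformed copy: p -> R @ p + t."""
        R = np.eye(3) if rotation is None else np.asarray(rotation)
        t = np.zeros(3) if translation is None else np.asarray(translation)
        return Neuron((self.p0 @ R.T) + t, (self.p1 @ R.T) + t,
                      self.radius.copy(), self.kind.copy(),
                      None if self.node_id is None else self.node_id.copy(),
                      None if self.parent_id is None else self.parent_id.copy())


def read_swc(source) -> Neuron:
    """Parse SWC (id, type, x, y, z, radius, parent) into cylinder segments.

    Each child-parent record pair becomes one right cylinder with the child's
    radius and the parent-to-child axis; records of SWC type 1 whose parent is
    also type 1 become soma cylinders, everything else dendrite.  Root records
    (parent -1) anchor the tree but produce no cylinder of their own.
    """
    if isinstance(source, (str, bytes)) and "\n" in str(source):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=r"\s+", comment="#", header=None,
                     names=["id", "type", "x", "y", "z", "radius", "parent"])
    if df.empty:
        raise SWCError("empty SWC content")
    ids = df["id"].to_numpy(int)
    if len(np.unique(ids)) != len(ids):
        raise SWCError("duplicate SWC record ids")
    index = {i: k for k, i in enumerate(ids)}
    parents = df["parent"].to_numpy(int)
    radii = df["radius"].to_numpy(float)
    bad = np.nonzero(radii <= 0)[0]
    if bad.size:
        raise SWCError(f"non-positive radius at SWC record id {ids[bad[0]]}")
    for i, p in zip(ids, parents):
        if p != -1 and p not in index:
            raise SWCError(f"record {i} references missing parent {p}")
    # cycle check by walking to root
    state = {}
    for i in ids:
        path = []
        j = i
        while j != -1 and state.get(j) is None:
            path.append(j)
            state[j] = "visiting"
            j = int(parents[index[j]])
        if j != -1 and state.get(j) == "visiting":
            raise SWCError(f"cyclic parent links involving record {j}")
        for k in path:
            state[k] = "done"
    xyz = df[["x", "y", "z"]].to_numpy(float)
    types = df["type"].to_numpy(int)
    child = parents != -1
    ci = np.nonzero(child)[0]
    pi = np.array([index[p] for p in parents[ci]])
    p0, p1 = xyz[pi], xyz[ci]
    kind = np.where((types[ci] == 1) & (types[pi] == 1), KIND_SOMA, KIND_DENDRITE)
    return Neuron(p0, p1, radii[ci], kind.astype(np.int8),
                  node_id=ids[ci], parent_id=ids[pi])


def morphometrics(neuron: Neuron) -> dict:
    """Summary morphometry: lengths, volumes, bounding measures, branch count."""
    if neuron.n_segments == 0:
        raise ValueError("empty neuron")
    w, h, d = neuron.extents
    out = {
        "l_dn_um": neuron.l_dn,
        "soma_volume_um3": neuron.soma_volume,
        "dendrite_volume_um3": neuron.dendrite_volume,
        "total_volume_um3": neuron.total_volume,
        "width_um": w,
        "height_um": h,
        "depth_um": d,
        "diagonal_um": neuron.diagonal,
        "bounding_radius_um": neuron.bounding_radius,
        "n_segments": neuron.n_segments,
    }
    if neuron.node_id is not None:
        dend = neuron.kind == KIND_DENDRITE
        tips = ~np.isin(neuron.node_id[dend], neuron.parent_id[dend])
        out["n_branches"] = int(tips.sum())
    return out


# ---------------------------------------------------------------------------
# decoration


@dataclass(frozen=True)
class ProtrusionGeometry:
    """Two-cylinder protrusion dimensions, mean +- SD in um."""

    head_height: tuple[float, float]
    neck_height: tuple[float, float]
    head_diameter: tuple[float, float]
    neck_diameter: tuple[float, float]


# per-type heights and diameters of the neck (on the dendrite surface) and the
# distal head cylinder, for the three spine classes and filopodia
PROTRUSION_GEOMETRY: dict[str, ProtrusionGeometry] = {
    "spine_long": ProtrusionGeometry((0.4, 0.07), (1.0, 0.12), (0.35, 0.06), (0.3, 0.06)),
    "spine_mushroom": ProtrusionGeometry((0.42, 0.08), (0.35, 0.06), (0.6, 0.1), (0.24, 0.06)),
    "spine_stubby": ProtrusionGeometry((0.25, 0.04), (0.25, 0.04), (0.46, 0.04), (0.54, 0.04)),
    "filopodium": ProtrusionGeometry((1.1, 0.1), (0.3, 0.06), (0.3, 0.05), (0.38, 0.05)),
}


@dataclass(frozen=True)
class DecorationParams:
    """Densities, type ratios and geometry for spine/filopodia placement."""

    spine_density: tuple[float, float] = (4.3, 0.4)  # per 10 um, mean +- SD
    filopodia_density: tuple[float, float] = (4.3, 0.4)
    spine_ratios: tuple[float, float, float] = (0.38, 0.33, 0.29)  # long, mushroom, stubby
    geometry: dict = field(default_factory=lambda: dict(PROTRUSION_GEOMETRY))
    min_separation_um: float = 0.5
    dim_floor_um: float = 0.01
    max_replacements: int = 10_000

    def __post_init__(self) -> None:
        if abs(sum(self.spine_ratios) - 1.0) > 1e-9:
            raise ValueError("spine type ratios must sum to 1")
        if min(self.spine_density[0], self.filopodia_density[0]) < 0:
            raise ValueError("densities must be non-negative")
        if self.min_separation_um < 0:
            raise ValueError("separation must be non-negative")


@dataclass
class DecoratedNeuron:
    """A neuron plus its stochastic spine/filopodium decoration.

    Segment arrays concatenate the base neuron with two cylinders per
    protrusion.  ``segment_compartment`` maps every segment to a compartment
    (the soma is one compartment, each dendrite segment is one, each
    protrusion is one); ``compartment_type`` / ``compartment_volume`` describe
    the compartments.
    """

    base: Neuron
    segments: Neuron
    segment_compartment: np.ndarray
    compartment_type: np.ndarray
    compartment_volume: np.ndarray
    anchor_segment: np.ndarray
    anchor_offset: np.ndarray
    anchor_azimuth: np.ndarray
    anchor_xyz: np.ndarray
    n_spines: int
    n_filopodia: int
    type_counts: dict[str, int]
    seed: int

    @property
    def n_compartments(self) -> int:
        return int(self.compartment_volume.size)

    @property
    def total_volume(self) -> float:
        return float(self.segments.volumes.sum())


def _perp_frame(axis: np.ndarray, anchor_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame perpendicular to ``axis`` built from neuron-intrinsic
    reference directions so decoration commutes with rigid transforms."""
    u = axis / np.linalg.norm(axis)
    v = anchor_ref - np.dot(anchor_ref, u) * u
    n = np.linalg.norm(v)
    if n < 1e-9:  # reference parallel to axis: fall back to any perpendicular
        v = np.array([u[1] - u[2], u[2] - u[0], u[0] - u[1]])
        v -= np.dot(v, u) * u
        n = np.linalg.norm(v)
    e1 = v / n
    return e1, np.cross(u, e1)


def decorate(neuron: Neuron, params: DecorationParams, seed: int) -> DecoratedNeuron:
    """Stochastically place spines and filopodia along the dendrites.

    Counts: N = round((L_DN / 10) * Normal(density)).  Anchors are uniform over
    the dendritic arc length; any pair of anchors closer than the minimum
    separation triggers re-placement of one member until all pairs comply.
    Spine types are assigned by two normal draws plus remainder.  Cylinder
    dimensions are drawn per protrusion from the geometry table, truncated at
    a small positive floor.
    """
    rng = np.random.default_rng(seed)
    dend = np.nonzero(neuron.kind == KIND_DENDRITE)[0]
    if dend.size == 0 and (params.spine_density[0] > 0 or params.filopodia_density[0] > 0):
        raise ValueError("neuron has no dendrites to decorate")
    l_dn = neuron.l_dn

    def _count(density: tuple[float, float]) -> int:
        if density[0] == 0 and density[1] == 0:
            return 0
        n = int(np.rint((l_dn / 10.0) * rng.normal(*density)))
        return max(n, 0)

    n_spines = _count(params.spine_density)
    n_filo = _count(params.filopodia_density)
    n_total = n_spines + n_filo

    seg_len = neuron.lengths[dend]
    cum = np.cumsum(seg_len)

    def _draw_anchor(n: int) -> tuple[np.ndarray, np.ndarray]:
        u = rng.uniform(0.0, l_dn, n)
        j = np.searchsorted(cum, u, side="right")
        j = np.minimum(j, dend.size - 1)
        off = u - (cum[j] - seg_len[j])
        return dend[j], off

    seg_idx, offset = _draw_anchor(n_total)
    azimuth = rng.uniform(0.0, 2.0 * np.pi, n_total)

    # azimuth reference: length-weighted centroid of segment midpoints, which
    # (unlike the bounding-box center) transforms equivariantly under rigid
    # motions, so decoration commutes with pre-rotation of the neuron
    w = neuron.lengths
    center = ((neuron.p0 + neuron.p1) * 0.5 * w[:, None]).sum(axis=0) / w.sum()

    def _anchor_xyz(si, off, az):
        a0, a1 = neuron.p0[si], neuron.p1[si]
        axis = a1 - a0
        h = np.linalg.norm(axis)
        u = axis / h
        base = a0 + u * off
        mid = 0.5 * (a0 + a1)
        e1, e2 = _perp_frame(axis, mid - center)
        radial = np.cos(az) * e1 + np.sin(az) * e2
        return base + neuron.radius[si] * radial, radial

    pos = np.empty((n_total, 3))
    radial = np.empty((n_total, 3))
    for i in range(n_total):
        pos[i], radial[i] = _anchor_xyz(seg_idx[i], offset[i], azimuth[i])

    # minimum-separation rejection loop: re-place one member of each close pair
    replacements = 0
    while n_total > 1:
        pairs = cKDTree(pos).query_pairs(params.min_separation_um, output_type="ndarray")
        if pairs.size == 0:
            break
        offenders = np.unique(pairs[:, 1])
        replacements += offenders.size
        if replacements > params.max_replacements:
            raise RuntimeError(
                f"could not separate {n_total} anchors by "
                f"{params.min_separation_um} um on {l_dn:.0f} um of dendrite "
                f"within {params.max_replacements} re-placements")
        si, off = _draw_anchor(offenders.size)
        seg_idx[offenders], offset[offenders] = si, off
        azimuth[offenders] = rng.uniform(0.0, 2.0 * np.pi, offenders.size)
        for i in offenders:
            pos[i], radial[i] = _anchor_xyz(seg_idx[i], offset[i], azimuth[i])

    # spine type registration: two normal draws, remainder keeps N_ST fixed
    r_long, r_mush, _ = params.spine_ratios
    def _type_count(p: float) -> int:
        sd = np.sqrt(max(n_spines, 1) * p * (1 - p))
        return int(np.clip(np.rint(rng.normal(n_spines * p, sd)), 0, n_spines))
    n_long = _type_count(r_long)
    n_mush = min(_type_count(r_mush), n_spines - n_long)
    n_stub = n_spines - n_long - n_mush
    ptype = np.concatenate((
        np.full(n_long, CTYPE_LONG), np.full(n_mush, CTYPE_MUSHROOM),
        np.full(n_stub, CTYPE_STUBBY), np.full(n_filo, CTYPE_FILOPODIUM),
    )).astype(np.int8)
    order = rng.permutation(n_spines)
    ptype[:n_spines] = ptype[:n_spines][order]

    type_names = {CTYPE_LONG: "spine_long", CTYPE_MUSHROOM: "spine_mushroom",
                  CTYPE_STUBBY: "spine_stubby", CTYPE_FILOPODIUM: "filopodium"}

    def _draw_dim(mean_sd: tuple[float, float], n: int) -> np.ndarray:
        return np.maximum(rng.normal(*mean_sd, n), params.dim_floor_um)

    dims = np.empty((n_total, 4))  # head_h, neck_h, head_d, neck_d
    for code, name in type_names.items():
        sel = ptype == code
        g = params.geometry[name]
        k = int(sel.sum())
        dims[sel, 0] = _draw_dim(g.head_height, k)
        dims[sel, 1] = _draw_dim(g.neck_height, k)
        dims[sel, 2] = _draw_dim(g.head_diameter, k)
        dims[sel, 3] = _draw_dim(g.neck_diameter, k)

    # assemble segments: base neuron first, then neck+head per protrusion
    neck_p0 = pos
    neck_p1 = pos + radial * dims[:, 1:2]
    head_p1 = neck_p1 + radial * dims[:, 0:1]
    p0 = np.vstack((neuron.p0, neck_p0, neck_p1))
    p1 = np.vstack((neuron.p1, neck_p1, head_p1))
    rad = np.concatenate((neuron.radius, dims[:, 3] / 2, dims[:, 2] / 2))
    kind = np.concatenate((neuron.kind,
                           np.full(n_total, KIND_NECK, np.int8),
                           np.full(n_total, KIND_HEAD, np.int8)))
    segments = Neuron(p0, p1, rad, kind)

    # compartments: soma (one), each dendrite segment, each protrusion
    nb = neuron.n_segments
    seg_comp = np.empty(nb + 2 * n_total, dtype=np.int64)
    comp_types = []
    soma_mask = neuron.kind == KIND_SOMA
    has_soma = bool(soma_mask.any())
    next_comp = 0
    if has_soma:
        seg_comp[:nb][soma_mask] = 0
        comp_types.append(CTYPE_SOMA)
        next_comp = 1
    dend_ids = np.arange(int((~soma_mask).sum())) + next_comp
    seg_comp[:nb][~soma_mask] = dend_ids
    comp_types.extend([CTYPE_DENDRITE] * dend_ids.size)
    prot_ids = np.arange(n_total) + next_comp + dend_ids.size
    seg_comp[nb:nb + n_total] = prot_ids
    seg_comp[nb + n_total:] = prot_ids
    comp_types.extend(ptype.tolist())
    comp_types = np.asarray(comp_types, dtype=np.int8)
    comp_vol = np.bincount(seg_comp, weights=segments.volumes,
                           minlength=comp_types.size)

    counts = {name: int((ptype == code).sum()) for code, name in type_names.items()}
    return DecoratedNeuron(
        base=neuron, segments=segments, segment_compartment=seg_comp,
        compartment_type=comp_types, compartment_volume=comp_vol,
        anchor_segment=seg_idx, anchor_offset=offset, anchor_azimuth=azimuth,
        anchor_xyz=pos, n_spines=n_spines, n_filopodia=n_filo,
        type_counts=counts, seed=seed)


def compartment_table(decorated: DecoratedNeuron) -> pd.DataFrame:
    """Per-compartment table of type names and volumes."""
    return pd.DataFrame({
        "compartment_id": np.arange(decorated.n_compartments),
        "type": [COMPARTMENT_TYPES[t] for t in decorated.compartment_type],
        "volume_um3": decorated.compartment_volume,
    })


def compartment_summary(decorated: DecoratedNeuron) -> pd.DataFrame:
    """Mean +- SD compartment volume by type (spine classes pooled as well)."""
    tab = compartment_table(decorated)
    tab["group"] = tab["type"].str.replace(r"spine_.*", "spine", regex=True)
    return tab.groupby("group")["volume_um3"].agg(["count", "mean", "std"])


def sample_protrusion_volumes(geometry: ProtrusionGeometry, n: int, seed: int,
                              floor_um: float = 0.01) -> np.ndarray:
    """Monte-Carlo two-cylinder volumes with dimensions from the type normals."""
    rng = np.random.default_rng(seed)
    hh = np.maximum(rng.normal(*geometry.head_height, n), floor_um)
    hn = np.maximum(rng.normal(*geometry.neck_height, n), floor_um)
    dh = np.maximum(rng.normal(*geometry.head_diameter, n), floor_um)
    dn = np.maximum(rng.normal(*geometry.neck_diameter, n), floor_um)
    return np.pi / 4.0 * (dh**2 * hh + dn**2 * hn)


def protrusion_mean_volume(geometry: ProtrusionGeometry) -> float:
    """Closed-form expected two-cylinder volume, E[d^2] = mean^2 + sd^2."""
    (hh, _), (hn, _), (dh, sdh), (dn, sdn) = (
        geometry.head_height, geometry.neck_height,
        geometry.head_diameter, geometry.neck_diameter)
    return np.pi / 4.0 * ((dh**2 + sdh**2) * hh + (dn**2 + sdn**2) * hn)


# ---------------------------------------------------------------------------
# synthetic fixture neuron


def synth_neuron(target_l_dn_um: float = 1392.0, n_branches: int = 16,
                 seed: int = 0, target_extent_um: tuple[float, float, float] = (169.0, 180.0, 69.0),
                 dendrite_volume_um3: float = 1559.0,
                 soma: tuple[tuple[float, float], tuple[float, float]] = ((8.0, 4.0), (5.08, 4.0)),
                 section_um: float = 7.25, branch_angle_deg: float = 32.0) -> Neuron:
    """Generate a granule-cell-like random binary tree of cylinder segments.

    A two-cylinder soma sits at the origin with dendrites branching upward in
    a flattened cone until ``n_branches`` terminal tips exist.  Endpoints are
    rescaled so the total dendritic length matches ``target_l_dn_um`` exactly
    and the bounding extents approach ``target_extent_um``; radii are scaled
    to match ``dendrite_volume_um3``.  Defaults emulate a mouse dentate
    granule cell (~1400 um of dendrite, ~2700 um^3, ~256 um diagonal).
    """
    if target_l_dn_um <= 0 or n_branches < 1:
        raise ValueError("targets must be positive")

    theta = np.radians(branch_angle_deg)
    soma_top = np.array([0.0, soma[0][1] + soma[1][1], 0.0])
    depth = max(int(np.ceil(np.log2(n_branches))), 0)
    level_w = 0.88 ** np.arange(depth + 1)
    n_at_level = np.minimum(2 ** np.arange(depth + 1), n_branches)
    scale0 = target_l_dn_um / float(np.sum(n_at_level * level_w))

    def _grow(tort: float):
        """Grow one tree realization at a given tortuosity (fresh rng)."""
        rng = np.random.default_rng(seed)
        frontier = [(soma_top, np.array([0.0, 1.0, 0.0]), 0)]
        remaining = [n_branches]
        pieces: list[tuple[np.ndarray, np.ndarray, int]] = []
        while frontier:
            nxt, nxt_rem = [], []
            for (p, d, lev), rem in zip(frontier, remaining):
                length = scale0 * level_w[min(lev, depth)]
                n_pieces = max(int(np.ceil(length / section_um)), 1)
                step = length / n_pieces
                cur = p
                for _ in range(n_pieces):
                    dd = d + tort * rng.standard_normal(3) * np.array([1.0, 0.4, 1.0])
                    dd[1] = abs(dd[1])  # keep growing away from the soma
                    d = dd / np.linalg.norm(dd)
                    new = cur + step * d
                    pieces.append((cur, new, lev))
                    cur = new
                if rem <= 1 or lev >= depth:
                    continue
                perp = np.cross(d, rng.standard_normal(3))
                perp /= np.linalg.norm(perp)
                d1 = np.cos(theta) * d + np.sin(theta) * perp
                d2 = np.cos(theta) * d - np.sin(theta) * perp
                r1 = rem // 2
                nxt += [(cur, d1, lev + 1), (cur, d2, lev + 1)]
                nxt_rem += [r1, rem - r1]
            frontier, remaining = nxt, nxt_rem
        p0 = np.array([a for a, _, _ in pieces])
        p1 = np.array([b for _, b, _ in pieces])
        levels = np.array([l for _, _, l in pieces])
        # anisotropic fit to the target extents, then isotropic fit to the
        # exact dendritic length; the residual extent error measures whether
        # this tortuosity packs the arc length into the target box
        for _ in range(4):
            pts = np.vstack((p0, p1))
            span = np.maximum(pts.max(axis=0) - pts.min(axis=0), 1e-9)
            f = np.asarray(target_extent_um) / span
            p0 = (p0 - soma_top) * f + soma_top
            p1 = (p1 - soma_top) * f + soma_top
            length = np.linalg.norm(p1 - p0, axis=1).sum()
            c = target_l_dn_um / length
            p0 = (p0 - soma_top) * c + soma_top
            p1 = (p1 - soma_top) * c + soma_top
        return p0, p1, levels, c

    # the final isotropic factor c is monotone in tortuosity (more wiggle
    # packs more arc into the same box); bisect until extents match
    lo, hi = 0.2, 1.6
    for _ in range(18):
        tort = 0.5 * (lo + hi)
        p0, p1, levels, c = _grow(tort)
        if abs(c - 1.0) < 2e-3:
            break
        if c > 1.0:  # box too small for the arc: needs more wiggle
            lo = tort
        else:
            hi = tort
    p0, p1, levels, c = _grow(tort)

    # radii taper with level; scaled to the dendrite volume target
    radius = 0.85 * 0.82 ** levels
    seg_len = np.linalg.norm(p1 - p0, axis=1)
    vol = np.pi * np.sum(radius**2 * seg_len)
    radius *= np.sqrt(dendrite_volume_um3 / vol)

    rows = []
    (r1, h1), (r2, h2) = soma
    rows.append((1, 1, 0.0, 0.0, 0.0, r1, -1))
    rows.append((2, 1, 0.0, h1, 0.0, r1, 1))
    rows.append((3, 1, 0.0, h1 + h2, 0.0, r2, 2))
    next_id = 4
    key_to_id = {tuple(np.round(soma_top, 9)): 3}
    for a, b, r in zip(p0, p1, radius):
        ka, kb = tuple(np.round(a, 9)), tuple(np.round(b, 9))
        pid = key_to_id.get(ka, 3)
        rows.append((next_id, 3, b[0], b[1], b[2], r, pid))
        key_to_id[kb] = next_id
        next_id += 1
    swc = "\n".join(" ".join(str(v) for v in row) for row in rows)
    return read_swc(io.StringIO(swc))
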