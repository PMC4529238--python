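"""Numba kernel for voxel-segment coincidence scoring.

One trial transforms every beam voxel into the fixed neuron frame and tests
it against the cylinder segments indexed by a uniform grid.  A bounding-sphere
pre-test in the scoring frame rejects the vast majority of voxels before the
rotation is applied; exactness of the pruning is guaranteed by construction
(sphere and AABB both enclose every segment) and checked against an
exhaustive scorer in the test suite.
"""

from __future__ import annotations

import numba
import numpy as np

__all__ = ["score_trial_kernel"]


@numba.njit(cache=True, fastmath=True)
def score_trial_kernel(bank_x, bank_y, bank_z, bank_ed, hist_ptr,
                       sel, zoff, ex, ey,
                       rt, m, c0, rb2, box_lo, box_hi,
                       grid_origin, cell_size, ncx, ncy, ncz,
                       cell_ptr, cell_list,
                       seg_p0, seg_u, seg_h, seg_r2, seg_kind, seg_comp,
                       out_xyz, out_ed, out_seg):
    """Score one trial; returns the number of coincident voxels (or -1 on
    output-buffer overflow).  ``rt`` is the transpose of the neuron rotation;
    a beam voxel p maps to the fixed frame as q = rt @ (p - m) + c0."""
    count = 0
    cap = out_ed.shape[0]
    for s in range(sel.shape[0]):
        h = sel[s]
        dz = zoff[s]
        for i in range(hist_ptr[h], hist_ptr[h + 1]):
            px = ex + bank_x[i]
            py = ey + bank_y[i]
            pz = dz + bank_z[i]
            ax = px - m[0]
            ay = py - m[1]
            az = pz - m[2]
            if ax * ax + ay * ay + az * az > rb2:
                continue
            qx = rt[0, 0] * ax + rt[0, 1] * ay + rt[0, 2] * az + c0[0]
            qy = rt[1, 0] * ax + rt[1, 1] * ay + rt[1, 2] * az + c0[1]
            qz = rt[2, 0] * ax + rt[2, 1] * ay + rt[2, 2] * az + c0[2]
            if (qx < box_lo[0] or qx > box_hi[0] or qy < box_lo[1]
                    or qy > box_hi[1] or qz < box_lo[2] or qz > box_hi[2]):
                continue
            cx = int((qx - grid_origin[0]) / cell_size)
            cy = int((qy - grid_origin[1]) / cell_size)
            cz = int((qz - grid_origin[2]) / cell_size)
            if cx < 0 or cx >= ncx or cy < 0 or cy >= ncy or cz < 0 or cz >= ncz:
                continue
            cell = (cx * ncy + cy) * ncz + cz
            best = -1
            best_kind = -1
            for j in range(cell_ptr[cell], cell_ptr[cell + 1]):
                sg = cell_list[j]
                wx = qx - seg_p0[sg, 0]
                wy = qy - seg_p0[sg, 1]
                wz = qz - seg_p0[sg, 2]
                t = wx * seg_u[sg, 0] + wy * seg_u[sg, 1] + wz * seg_u[sg, 2]
                if t < 0.0 or t > seg_h[sg]:
                    continue
                d2 = wx * wx + wy * wy + wz * wz - t * t
                if d2 > seg_r2[sg]:
                    continue
                k = seg_kind[sg]
                if k > best_kind or (k == best_kind and sg < best):
                    best_kind = k
                    best = sg
            if best >= 0:
                if count >= cap:
                    return -1
                out_xyz[count, 0] = qx
                out_xyz[count, 1] = qy
                out_xyz[count, 2] = qz
                out_ed[count] = bank_ed[i]
                out_seg[count] = best
                count += 1
    return count
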