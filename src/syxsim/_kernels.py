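"""Compiled inner loops for the Brownian-dynamics engine.

Everything here mirrors the readable reference implementation in
:mod:`syxsim.model_core` exactly (same potentials, same Euler update);
tests assert the equivalence.  The integration loop lives entirely in
one jitted function so Python overhead is paid once per chunk, not once
per step.

Neighbor search uses Verlet pair lists (one list per interaction type:
anchor-anchor, head-head, anchor-head) built from a cell grid with a
1-nm skin and rebuilt whenever any particle has moved more than half
the skin since the last build, which guarantees no interacting pair is
ever missed.
"""

import numpy as np
from numba import njit

#: Verlet skin (nm) added to every interaction cutoff in the pair lists.
SKIN = 1.0

#: pair-list capacity per interaction type, in units of n_molecules
PAIR_CAPACITY = 96


@njit(cache=True, inline="always")
def _f_attr(dist, r_sum, i_rad, e_a):
    """Scalar force -dU/dd of the piecewise clustering potential."""
    if dist >= i_rad or e_a <= 0.0:
        return 0.0
    mid = 0.5 * (i_rad + r_sum)
    a = 2.0 * e_a / ((i_rad - r_sum) * (i_rad - r_sum))
    if dist < r_sum:
        return -e_a * (dist - r_sum)  # core stiffness k_core == e_a
    elif dist < mid:
        return -2.0 * a * (dist - r_sum)
    else:
        return 2.0 * a * (dist - i_rad)


@njit(cache=True, inline="always")
def _f_rep(dist, r_sum, k):
    if dist >= r_sum:
        return 0.0
    return -k * (dist - r_sum)


@njit(cache=True)
def _build_cells(pos, n, half_span, cell_edge, n_side, head, nxt, occ):
    # clear only the cells occupied at the previous build (occ holds the
    # cell index of each particle), so the cost is O(n), not O(grid)
    for i in range(n):
        if occ[i] >= 0:
            head[occ[i]] = -1
    for i in range(n):
        ix = int((pos[i, 0] + half_span) / cell_edge)
        iy = int((pos[i, 1] + half_span) / cell_edge)
        if ix < 0:
            ix = 0
        elif ix >= n_side:
            ix = n_side - 1
        if iy < 0:
            iy = 0
        elif iy >= n_side:
            iy = n_side - 1
        c = iy * n_side + ix
        nxt[i] = head[c]
        head[c] = i
        occ[i] = c


@njit(cache=True, fastmath=True)
def _grid_geometry(radius, cutoff, n):
    half_span = radius + 40.0
    n_side = max(1, int(2.0 * half_span / cutoff))
    # cap the grid so memory stays O(n) for sparse systems in huge
    # domains (larger cells only mean more neighbors scanned per cell)
    cap = int(np.sqrt(64.0 * max(n, 1))) + 1
    if n_side > cap:
        n_side = cap
    cell_edge = 2.0 * half_span / n_side
    return half_span, n_side, cell_edge


@njit(cache=True, fastmath=True)
def _rebuild_pairs(pos1, pos2, n, half_span, cell_edge, n_side,
                   head_a, nxt_a, occ_a, head_h, nxt_h, occ_h,
                   rc11, rc22, rc21,
                   pairs11, pairs22, pairs21, counts,
                   ref1, ref2):
    """Refill the three Verlet pair lists; returns 0, or 1 on overflow."""
    _build_cells(pos1, n, half_span, cell_edge, n_side, head_a, nxt_a, occ_a)
    _build_cells(pos2, n, half_span, cell_edge, n_side, head_h, nxt_h, occ_h)
    s11 = rc11 * rc11
    s22 = rc22 * rc22
    s21 = rc21 * rc21
    n11 = 0
    n22 = 0
    n21 = 0
    cap11 = pairs11.shape[0]
    cap22 = pairs22.shape[0]
    cap21 = pairs21.shape[0]

    for i in range(n):
        # cells around the anchor of i
        cx = int((pos1[i, 0] + half_span) / cell_edge)
        cy = int((pos1[i, 1] + half_span) / cell_edge)
        for oy in range(-1, 2):
            yy = cy + oy
            if yy < 0 or yy >= n_side:
                continue
            for ox in range(-1, 2):
                xx = cx + ox
                if xx < 0 or xx >= n_side:
                    continue
                c = yy * n_side + xx
                j = head_a[c]
                while j >= 0:
                    if j > i:  # unordered anchor-anchor pairs
                        dx = pos1[i, 0] - pos1[j, 0]
                        dy = pos1[i, 1] - pos1[j, 1]
                        dz = pos1[i, 2] - pos1[j, 2]
                        if dx * dx + dy * dy + dz * dz < s11:
                            if n11 >= cap11:
                                return 1
                            pairs11[n11, 0] = i
                            pairs11[n11, 1] = j
                            n11 += 1
                    j = nxt_a[j]
                # ordered anchor(i)-head(j) pairs
                j = head_h[c]
                while j >= 0:
                    if j != i:
                        dx = pos1[i, 0] - pos2[j, 0]
                        dy = pos1[i, 1] - pos2[j, 1]
                        dz = pos1[i, 2] - pos2[j, 2]
                        if dx * dx + dy * dy + dz * dz < s21:
                            if n21 >= cap21:
                                return 1
                            pairs21[n21, 0] = i
                            pairs21[n21, 1] = j
                            n21 += 1
                    j = nxt_h[j]
        # cells around the head of i: head-head pairs
        cx = int((pos2[i, 0] + half_span) / cell_edge)
        cy = int((pos2[i, 1] + half_span) / cell_edge)
        for oy in range(-1, 2):
            yy = cy + oy
            if yy < 0 or yy >= n_side:
                continue
            for ox in range(-1, 2):
                xx = cx + ox
                if xx < 0 or xx >= n_side:
                    continue
                c = yy * n_side + xx
                j = head_h[c]
                while j >= 0:
                    if j > i:
                        dx = pos2[i, 0] - pos2[j, 0]
                        dy = pos2[i, 1] - pos2[j, 1]
                        dz = pos2[i, 2] - pos2[j, 2]
                        if dx * dx + dy * dy + dz * dz < s22:
                            if n22 >= cap22:
                                return 1
                            pairs22[n22, 0] = i
                            pairs22[n22, 1] = j
                            n22 += 1
                    j = nxt_h[j]

    counts[0] = n11
    counts[1] = n22
    counts[2] = n21
    counts[3] = 1  # lists valid
    for i in range(n):
        for k in range(3):
            ref1[i, k] = pos1[i, k]
            ref2[i, k] = pos2[i, k]
    return 0


@njit(cache=True, fastmath=True)
def run_chunk(pos1, pos2, mobile, e_a, noise, step_offset, stride,
              r1, r2, k_m, k_rep, dt, d_p, radius, k_wall, k_bond,
              i_offset, out1, out2, out_t, t0, frame_start,
              head_a, nxt_a, occ_a, head_h, nxt_h, occ_h,
              pairs11, pairs22, pairs21, counts, ref1, ref2):
    """Integrate one chunk of Euler steps with pre-drawn noise.

    ``noise`` has shape (chunk_steps, n, 6): scaled Gaussian increments
    for the anchor (columns 0-2) and head (columns 3-5) of each
    molecule.  Pre-drawing the noise with numpy's vectorized generator
    is several times faster than drawing scalars in the jitted loop and
    keeps the stream reproducible.  Samples are written whenever the
    global step count reaches a multiple of ``stride``.  The pair-list
    state (``pairs*``, ``counts``, ``ref*``) persists across chunks.
    Returns (next_frame_index, n_big, status): n_big counts single-step
    anchor displacements exceeding r1; status 1 flags pair-list
    overflow (the driver raises).
    """
    n = pos1.shape[0]
    n_steps = noise.shape[0]

    r_sum_11 = 2.0 * r1
    i_rad = r_sum_11 + i_offset
    r_sum_22 = 2.0 * r2
    r_sum_21 = r1 + r2
    rest = r1 + r2

    cutoff = max(i_rad, r_sum_22, r_sum_21)
    half_span, n_side, cell_edge = _grid_geometry(radius, cutoff, n)

    rc11 = i_rad + SKIN
    rc22 = r_sum_22 + SKIN
    rc21 = r_sum_21 + SKIN
    half_skin_sq = 0.25 * SKIN * SKIN

    f1 = np.zeros((n, 3))
    f2 = np.zeros((n, 3))

    r1_sq = r1 * r1
    n_big = 0
    frame = frame_start

    for step in range(n_steps):
        # rebuild the pair lists when invalid or any particle drifted
        # more than half the skin from its reference position
        rebuild = counts[3] == 0
        if not rebuild:
            for i in range(n):
                d0 = pos1[i, 0] - ref1[i, 0]
                d1 = pos1[i, 1] - ref1[i, 1]
                d2 = pos1[i, 2] - ref1[i, 2]
                if d0 * d0 + d1 * d1 + d2 * d2 > half_skin_sq:
                    rebuild = True
                    break
                d0 = pos2[i, 0] - ref2[i, 0]
                d1 = pos2[i, 1] - ref2[i, 1]
                d2 = pos2[i, 2] - ref2[i, 2]
                if d0 * d0 + d1 * d1 + d2 * d2 > half_skin_sq:
                    rebuild = True
                    break
        if rebuild:
            status = _rebuild_pairs(
                pos1, pos2, n, half_span, cell_edge, n_side,
                head_a, nxt_a, occ_a, head_h, nxt_h, occ_h,
                rc11, rc22, rc21, pairs11, pairs22, pairs21, counts,
                ref1, ref2)
            if status != 0:
                return frame, n_big, 1

        # single-particle terms
        for i in range(n):
            f1[i, 0] = 0.0
            f1[i, 1] = 0.0
            f1[i, 2] = -k_m * pos1[i, 2]  # membrane restraint
            f2[i, 0] = 0.0
            f2[i, 1] = 0.0
            f2[i, 2] = 0.0

            rho = np.sqrt(pos1[i, 0] ** 2 + pos1[i, 1] ** 2)
            if rho > radius and rho > 0.0:
                fw = -k_wall * (rho - radius) / rho
                f1[i, 0] += fw * pos1[i, 0]
                f1[i, 1] += fw * pos1[i, 1]

            bx = pos1[i, 0] - pos2[i, 0]
            by = pos1[i, 1] - pos2[i, 1]
            bz = pos1[i, 2] - pos2[i, 2]
            bd = np.sqrt(bx * bx + by * by + bz * bz)
            if bd > 0.0:
                fb = -k_bond * (bd - rest) / bd
                f1[i, 0] += fb * bx
                f1[i, 1] += fb * by
                f1[i, 2] += fb * bz
                f2[i, 0] -= fb * bx
                f2[i, 1] -= fb * by
                f2[i, 2] -= fb * bz

        # pair terms (Newton's third law on each list entry)
        for p in range(counts[0]):
            i = pairs11[p, 0]
            j = pairs11[p, 1]
            dx = pos1[i, 0] - pos1[j, 0]
            dy = pos1[i, 1] - pos1[j, 1]
            dz = pos1[i, 2] - pos1[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dd < i_rad and dd > 0.0:
                ep = e_a[i] if e_a[i] > e_a[j] else e_a[j]
                fs = _f_attr(dd, r_sum_11, i_rad, ep)
                if fs != 0.0:
                    fs /= dd
                    f1[i, 0] += fs * dx
                    f1[i, 1] += fs * dy
                    f1[i, 2] += fs * dz
                    f1[j, 0] -= fs * dx
                    f1[j, 1] -= fs * dy
                    f1[j, 2] -= fs * dz
        for p in range(counts[1]):
            i = pairs22[p, 0]
            j = pairs22[p, 1]
            dx = pos2[i, 0] - pos2[j, 0]
            dy = pos2[i, 1] - pos2[j, 1]
            dz = pos2[i, 2] - pos2[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dd < r_sum_22 and dd > 0.0:
                fs = _f_rep(dd, r_sum_22, k_rep) / dd
                f2[i, 0] += fs * dx
                f2[i, 1] += fs * dy
                f2[i, 2] += fs * dz
                f2[j, 0] -= fs * dx
                f2[j, 1] -= fs * dy
                f2[j, 2] -= fs * dz
        for p in range(counts[2]):
            i = pairs21[p, 0]  # anchor of molecule i
            j = pairs21[p, 1]  # head of molecule j
            dx = pos1[i, 0] - pos2[j, 0]
            dy = pos1[i, 1] - pos2[j, 1]
            dz = pos1[i, 2] - pos2[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if dd < r_sum_21 and dd > 0.0:
                fs = _f_rep(dd, r_sum_21, k_rep) / dd
                f1[i, 0] += fs * dx
                f1[i, 1] += fs * dy
                f1[i, 2] += fs * dz
                f2[j, 0] -= fs * dx
                f2[j, 1] -= fs * dy
                f2[j, 2] -= fs * dz

        # Euler-Maruyama update (mobility = D_p / k_BT, k_BT == 1)
        for i in range(n):
            if not mobile[i]:
                continue
            disp_sq = 0.0
            for k in range(3):
                d = d_p * f1[i, k] * dt + noise[step, i, k]
                pos1[i, k] += d
                disp_sq += d * d
            if disp_sq > r1_sq:
                n_big += 1
            for k in range(3):
                d = d_p * f2[i, k] * dt + noise[step, i, 3 + k]
                pos2[i, k] += d

        if (step_offset + step + 1) % stride == 0:
            out_t[frame] = t0 + (step_offset + step + 1) * dt
            for i in range(n):
                for k in range(3):
                    out1[frame, i, k] = pos1[i, k]
                    out2[frame, i, k] = pos2[i, k]
            frame += 1

    return frame, n_big, 0


@njit(cache=True)
def forces_kernel(pos1, pos2, e_a, r1, r2, k_m, k_rep, radius, k_wall,
                  k_bond, i_offset):
    """All-pairs force evaluation (no neighbor lists) for cross-checking.

    Returns (f1, f2); identical physics to :func:`run_chunk`.
    """
    n = pos1.shape[0]
    f1 = np.zeros((n, 3))
    f2 = np.zeros((n, 3))
    r_sum_11 = 2.0 * r1
    i_rad = r_sum_11 + i_offset
    r_sum_22 = 2.0 * r2
    r_sum_21 = r1 + r2
    rest = r1 + r2

    for i in range(n):
        f1[i, 2] += -k_m * pos1[i, 2]
        rho = np.sqrt(pos1[i, 0] ** 2 + pos1[i, 1] ** 2)
        if rho > radius and rho > 0.0:
            f1[i, 0] += -k_wall * (rho - radius) * pos1[i, 0] / rho
            f1[i, 1] += -k_wall * (rho - radius) * pos1[i, 1] / rho
        bx = pos1[i, 0] - pos2[i, 0]
        by = pos1[i, 1] - pos2[i, 1]
        bz = pos1[i, 2] - pos2[i, 2]
        bd = np.sqrt(bx * bx + by * by + bz * bz)
        if bd > 0.0:
            fb = -k_bond * (bd - rest) / bd
            f1[i, 0] += fb * bx
            f1[i, 1] += fb * by
            f1[i, 2] += fb * bz
            f2[i, 0] -= fb * bx
            f2[i, 1] -= fb * by
            f2[i, 2] -= fb * bz

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dx = pos1[i, 0] - pos1[j, 0]
            dy = pos1[i, 1] - pos1[j, 1]
            dz = pos1[i, 2] - pos1[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if 0.0 < dd < i_rad:
                ep = e_a[i] if e_a[i] > e_a[j] else e_a[j]
                fs = _f_attr(dd, r_sum_11, i_rad, ep) / dd
                f1[i, 0] += fs * dx
                f1[i, 1] += fs * dy
                f1[i, 2] += fs * dz
            dx = pos2[i, 0] - pos2[j, 0]
            dy = pos2[i, 1] - pos2[j, 1]
            dz = pos2[i, 2] - pos2[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if 0.0 < dd < r_sum_22:
                fs = _f_rep(dd, r_sum_22, k_rep) / dd
                f2[i, 0] += fs * dx
                f2[i, 1] += fs * dy
                f2[i, 2] += fs * dz
            dx = pos1[i, 0] - pos2[j, 0]
            dy = pos1[i, 1] - pos2[j, 1]
            dz = pos1[i, 2] - pos2[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if 0.0 < dd < r_sum_21:
                fs = _f_rep(dd, r_sum_21, k_rep) / dd
                f1[i, 0] += fs * dx
                f1[i, 1] += fs * dy
                f1[i, 2] += fs * dz
            dx = pos2[i, 0] - pos1[j, 0]
            dy = pos2[i, 1] - pos1[j, 1]
            dz = pos2[i, 2] - pos1[j, 2]
            dd = np.sqrt(dx * dx + dy * dy + dz * dz)
            if 0.0 < dd < r_sum_21:
                fs = _f_rep(dd, r_sum_21, k_rep) / dd
                f2[i, 0] += fs * dx
                f2[i, 1] += fs * dy
                f2[i, 2] += fs * dz

    return f1, f2
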