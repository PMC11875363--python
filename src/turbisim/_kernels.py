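"""Numba kernels for the hot loops.

The relaxation sweep is grid-accelerated: nodes are binned into a uniform
grid with cell size equal to the largest exclusion radius, so scanning the
3x3 block of cells around a node is guaranteed to find every non-neighbour
within interaction range.  The result is bitwise identical to the all-pairs
reference sum in :mod:`turbisim.relax` (same arithmetic, same degenerate
handling), which the test suite asserts.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "paint_segments",
    "relax_sweeps",
    "count_within_radius",
    "count_segment_intersections",
    "grow_dla",
]


@njit(cache=True, inline="always")
def _hash_direction(i, j):
    h = math.sin(i * 12.9898 + j * 78.233) * 43758.5453
    ang = 2.0 * math.pi * (h - math.floor(h))
    return math.cos(ang), math.sin(ang)


@njit(cache=True)
def _exclusion_radii(pos, indptr, indices, r0, m):
    n = pos.shape[0]
    for i in range(n):
        best = 2.0 * r0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            d = math.hypot(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1])
            if d > best:
                best = d
        m[i] = best


@njit(cache=True)
def _bin_nodes(pos, cell, ox, oy, nx, ny, cell_start, cell_count, order, cell_of):
    n = pos.shape[0]
    ncells = nx * ny
    for c in range(ncells):
        cell_count[c] = 0
    for i in range(n):
        cx = int((pos[i, 0] - ox) / cell)
        cy = int((pos[i, 1] - oy) / cell)
        if cx < 0:
            cx = 0
        elif cx >= nx:
            cx = nx - 1
        if cy < 0:
            cy = 0
        elif cy >= ny:
            cy = ny - 1
        c = cy * nx + cx
        cell_of[i] = c
        cell_count[c] += 1
    acc = 0
    for c in range(ncells):
        cell_start[c] = acc
        acc += cell_count[c]
        cell_count[c] = 0
    for i in range(n):
        c = cell_of[i]
        order[cell_start[c] + cell_count[c]] = i
        cell_count[c] += 1


@njit(cache=True)
def relax_sweeps(
    pos, indptr, indices, birth, t_now, K, tau, r0, b, max_sweeps, tol, avoidance
):
    """Run synchronous relaxation sweeps in place.

    Sweeps run until the largest node step falls below ``tol`` or
    ``max_sweeps`` is reached; ``tol <= 0`` always runs exactly
    ``max_sweeps`` sweeps.  Returns ``(sweeps_run, coincident_pairs)``
    where the second count tracks exactly coincident non-neighbour pairs
    (resolved via the deterministic hashed direction).
    """
    n = pos.shape[0]
    m = np.empty(n)
    disp = np.empty((n, 2))
    coincident = 0
    sweeps = 0
    for _ in range(max_sweeps):
        _exclusion_radii(pos, indptr, indices, r0, m)
        # grid setup
        xmin = pos[0, 0]
        xmax = pos[0, 0]
        ymin = pos[0, 1]
        ymax = pos[0, 1]
        maxm = 2.0 * r0
        for i in range(n):
            if pos[i, 0] < xmin:
                xmin = pos[i, 0]
            if pos[i, 0] > xmax:
                xmax = pos[i, 0]
            if pos[i, 1] < ymin:
                ymin = pos[i, 1]
            if pos[i, 1] > ymax:
                ymax = pos[i, 1]
            if m[i] > maxm:
                maxm = m[i]
        cell = maxm * 1.000001
        nx = int((xmax - xmin) / cell) + 1
        ny = int((ymax - ymin) / cell) + 1
        cell_start = np.empty(nx * ny, dtype=np.int64)
        cell_count = np.empty(nx * ny, dtype=np.int64)
        order = np.empty(n, dtype=np.int64)
        cell_of = np.empty(n, dtype=np.int64)
        _bin_nodes(pos, cell, xmin, ymin, nx, ny, cell_start, cell_count, order, cell_of)

        inner = b - r0
        for i in range(n):
            if i == 0:
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                continue
            sx = 0.0
            sy = 0.0
            # boundary spring (one-sided, active within r0 of the wall)
            rad = math.hypot(pos[i, 0], pos[i, 1])
            if rad > inner and rad > 0.0:
                f = (rad - inner) / rad
                sx -= pos[i, 0] * f
                sy -= pos[i, 1] * f
            # chain springs
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                d = math.hypot(dx, dy)
                if d > 0.0:
                    f = (d - r0) / d
                    sx += dx * f
                    sy += dy * f
            # non-neighbour repulsion via 3x3 grid scan
            if avoidance:
                ci = cell_of[i]
                cx = ci % nx
                cy = ci // nx
                for gy in range(max(0, cy - 1), min(ny, cy + 2)):
                    for gx in range(max(0, cx - 1), min(nx, cx + 2)):
                        c = gy * nx + gx
                        for q in range(cell_start[c], cell_start[c] + cell_count[c]):
                            j = order[q]
                            if j == i:
                                continue
                            is_nbr = False
                            for k in range(indptr[i], indptr[i + 1]):
                                if indices[k] == j:
                                    is_nbr = True
                                    break
                            if is_nbr:
                                continue
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            d = math.hypot(dx, dy)
                            if d >= m[j]:
                                continue
                            if d == 0.0:
                                ux, uy = _hash_direction(i, j)
                                sx -= ux * m[j]
                                sy -= uy * m[j]
                                coincident += 1
                            else:
                                f = (d - m[j]) / d
                                sx += dx * f
                                sy += dy * f
            disp[i, 0] = sx
            disp[i, 1] = sy
        max_step = 0.0
        for i in range(1, n):
            k_i = K * math.exp(-(t_now - birth[i]) / tau)
            dx = k_i * disp[i, 0]
            dy = k_i * disp[i, 1]
            pos[i, 0] += dx
            pos[i, 1] += dy
            step = math.hypot(dx, dy)
            if step > max_step:
                max_step = step
        sweeps += 1
        if tol > 0.0 and max_step < tol:
            break
    return sweeps, coincident


@njit(cache=True, inline="always")
def _segs_cross(ax, ay, bx, by, ux, uy, vx, vy):
    o1 = _orient(ax, ay, bx, by, ux, uy)
    o2 = _orient(ax, ay, bx, by, vx, vy)
    o3 = _orient(ux, uy, vx, vy, ax, ay)
    o4 = _orient(ux, uy, vx, vy, bx, by)
    return o1 != o2 and o3 != o4 and o1 != 0 and o2 != 0 and o3 != 0 and o4 != 0


@njit(cache=True)
def relax_active(
    pos, indptr, indices, parents, birth, t_now, K, tau, r0, b,
    max_sweeps, tol, wake_eps, avoidance, active,
):
    """Active-set relaxation: exact forces, lazy updates, crossing guard.

    Only nodes flagged in ``active`` are moved.  A mover broadcasts a wake
    to everything that can feel it (its exclusion ball, chain partners and
    their balls) once its accumulated motion reaches ``wake_eps``; a node
    whose step falls below ``tol`` goes back to sleep, so quiescent regions
    cost nothing while their force balance stays exact.

    Self-avoidance is enforced both by the exclusion-radius repulsion and
    by a topological guard: a mover in deep repulsive overlap (the only
    place a crossing can initiate) has its step rejected if it would carry
    one of its incident segments across another segment.  Moves are applied
    in index order and checked against current positions, so the crossing
    number of the embedding is invariant.

    Spatial queries use a uniform grid with fixed cell (about ``3 r0``)
    rebuilt on drift; nodes whose exclusion radius outgrows the cell are
    kept in an explicit side list so the interaction set stays exact.
    Returns ``(sweeps, coincident_pairs)``.
    """
    n = pos.shape[0]
    m = np.empty(n)
    _exclusion_radii(pos, indptr, indices, r0, m)
    margin = 0.25 * r0
    eps = 1e-9
    cell = 3.0 * r0 + 2.0 * margin + eps
    big_thresh = cell - margin

    xmin = pos[:, 0].min() - margin - eps
    ymin = pos[:, 1].min() - margin - eps
    nx = int((pos[:, 0].max() + margin - xmin) / cell) + 1
    ny = int((pos[:, 1].max() + margin - ymin) / cell) + 1
    cell_start = np.empty(nx * ny, dtype=np.int64)
    cell_count = np.empty(nx * ny, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    _bin_nodes(pos, cell, xmin, ymin, nx, ny, cell_start, cell_count, order, cell_of)
    drift = 0.0

    big = np.empty(n, dtype=np.int64)
    nbig = 0
    is_big = np.zeros(n, dtype=np.uint8)
    maxm = 2.0 * r0
    for i in range(n):
        if m[i] > maxm:
            maxm = m[i]
        if m[i] > big_thresh:
            big[nbig] = i
            nbig += 1
            is_big[i] = 1

    disp = np.empty((n, 2))
    steplen = np.zeros(n)
    acc = np.zeros(n)  # unbroadcast accumulated motion per mover
    work = np.empty(n, dtype=np.int64)
    work2 = np.empty(n, dtype=np.int64)
    in_next = np.zeros(n, dtype=np.uint8)
    nw = 0
    for i in range(1, n):
        if active[i] == 1:
            work[nw] = i
            nw += 1
    coincident = 0
    sweeps = 0
    inner = b - r0
    while sweeps < max_sweeps and nw > 0:
        # displacement pass (synchronous: all from pre-move positions)
        for idx in range(nw):
            i = work[idx]
            sx = 0.0
            sy = 0.0
            rad = math.hypot(pos[i, 0], pos[i, 1])
            if rad > inner and rad > 0.0:
                f = (rad - inner) / rad
                sx -= pos[i, 0] * f
                sy -= pos[i, 1] * f
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                d = math.hypot(dx, dy)
                if d > 0.0:
                    f = (d - r0) / d
                    sx += dx * f
                    sy += dy * f
            if avoidance:
                cx = int((pos[i, 0] - xmin) / cell)
                cy = int((pos[i, 1] - ymin) / cell)
                if cx < 0:
                    cx = 0
                elif cx >= nx:
                    cx = nx - 1
                if cy < 0:
                    cy = 0
                elif cy >= ny:
                    cy = ny - 1
                for gy in range(max(0, cy - 1), min(ny, cy + 2)):
                    for gx in range(max(0, cx - 1), min(nx, cx + 2)):
                        c = gy * nx + gx
                        for q in range(cell_start[c], cell_start[c] + cell_count[c]):
                            j = order[q]
                            if j == i or is_big[j] == 1:
                                continue
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            d2 = dx * dx + dy * dy
                            if d2 >= m[j] * m[j]:
                                continue
                            is_nbr = False
                            for k in range(indptr[i], indptr[i + 1]):
                                if indices[k] == j:
                                    is_nbr = True
                                    break
                            if is_nbr:
                                continue
                            d = math.sqrt(d2)
                            if d == 0.0:
                                ux, uy = _hash_direction(i, j)
                                sx -= ux * m[j]
                                sy -= uy * m[j]
                                coincident += 1
                            else:
                                f = (d - m[j]) / d
                                sx += dx * f
                                sy += dy * f
                # heavily stretched nodes, checked exhaustively
                for bq in range(nbig):
                    j = big[bq]
                    if j == i:
                        continue
                    dx = pos[j, 0] - pos[i, 0]
                    dy = pos[j, 1] - pos[i, 1]
                    d2 = dx * dx + dy * dy
                    if d2 >= m[j] * m[j]:
                        continue
                    is_nbr = False
                    for k in range(indptr[i], indptr[i + 1]):
                        if indices[k] == j:
                            is_nbr = True
                            break
                    if is_nbr:
                        continue
                    d = math.sqrt(d2)
                    if d == 0.0:
                        ux, uy = _hash_direction(i, j)
                        sx -= ux * m[j]
                        sy -= uy * m[j]
                        coincident += 1
                    else:
                        f = (d - m[j]) / d
                        sx += dx * f
                        sy += dy * f
            k_i = K * math.exp(-(t_now - birth[i]) / tau)
            disp[i, 0] = k_i * sx
            disp[i, 1] = k_i * sy
        # apply in index order; every move is checked against current
        # positions so a step can never carry a segment across another
        # (the crossing number of the embedding is invariant)
        max_step = 0.0
        for idx in range(nw):
            i = work[idx]
            step = math.hypot(disp[i, 0], disp[i, 1])
            ok = True
            if avoidance and step > 0.0:
                nxp = pos[i, 0] + disp[i, 0]
                nyp = pos[i, 1] + disp[i, 1]
                # bounding box of the region node i's incident edges sweep
                bx0 = min(pos[i, 0], nxp)
                bx1 = max(pos[i, 0], nxp)
                by0 = min(pos[i, 1], nyp)
                by1 = max(pos[i, 1], nyp)
                for k in range(indptr[i], indptr[i + 1]):
                    e = indices[k]
                    if pos[e, 0] < bx0:
                        bx0 = pos[e, 0]
                    if pos[e, 0] > bx1:
                        bx1 = pos[e, 0]
                    if pos[e, 1] < by0:
                        by0 = pos[e, 1]
                    if pos[e, 1] > by1:
                        by1 = pos[e, 1]
                # candidate edges are found via their child endpoint, which
                # can sit a full edge length from the crossing point; edges
                # longer than big_thresh live on the big list instead
                pad = big_thresh + drift + margin
                gx0 = int((bx0 - pad - xmin) / cell)
                gx1 = int((bx1 + pad - xmin) / cell)
                gy0 = int((by0 - pad - ymin) / cell)
                gy1 = int((by1 + pad - ymin) / cell)
                if gx0 < 0:
                    gx0 = 0
                if gy0 < 0:
                    gy0 = 0
                if gx1 >= nx:
                    gx1 = nx - 1
                if gy1 >= ny:
                    gy1 = ny - 1
                for gy in range(gy0, gy1 + 1):
                    if not ok:
                        break
                    for gx in range(gx0, gx1 + 1):
                        if not ok:
                            break
                        c = gy * nx + gx
                        for q in range(cell_start[c], cell_start[c] + cell_count[c]):
                            j = order[q]
                            if j == 0:
                                continue
                            pj = parents[j]
                            if j == i or pj == i:
                                continue
                            if (
                                min(pos[j, 0], pos[pj, 0]) > bx1
                                or max(pos[j, 0], pos[pj, 0]) < bx0
                                or min(pos[j, 1], pos[pj, 1]) > by1
                                or max(pos[j, 1], pos[pj, 1]) < by0
                            ):
                                continue
                            for k in range(indptr[i], indptr[i + 1]):
                                e = indices[k]
                                if e == j or e == pj:
                                    continue
                                if _segs_cross(
                                    nxp, nyp, pos[e, 0], pos[e, 1],
                                    pos[j, 0], pos[j, 1], pos[pj, 0], pos[pj, 1],
                                ):
                                    ok = False
                                    break
                            if not ok:
                                break
                if ok:
                    for bq in range(nbig):
                        j = big[bq]
                        if j == 0:
                            continue
                        pj = parents[j]
                        if j == i or pj == i:
                            continue
                        if (
                            min(pos[j, 0], pos[pj, 0]) > bx1
                            or max(pos[j, 0], pos[pj, 0]) < bx0
                            or min(pos[j, 1], pos[pj, 1]) > by1
                            or max(pos[j, 1], pos[pj, 1]) < by0
                        ):
                            continue
                        for k in range(indptr[i], indptr[i + 1]):
                            e = indices[k]
                            if e == j or e == pj:
                                continue
                            if _segs_cross(
                                nxp, nyp, pos[e, 0], pos[e, 1],
                                pos[j, 0], pos[j, 1], pos[pj, 0], pos[pj, 1],
                            ):
                                ok = False
                                break
                        if not ok:
                            break
            if ok:
                pos[i, 0] += disp[i, 0]
                pos[i, 1] += disp[i, 1]
            steplen[i] = step
            acc[i] += step
            if step > max_step:
                max_step = step
        sweeps += 1
        drift += max_step
        # incremental exclusion-radius update for movers and their partners
        for idx in range(nw):
            i = work[idx]
            best = 2.0 * r0
            for k in range(indptr[i], indptr[i + 1]):
                j = indices[k]
                d = math.hypot(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1])
                if d > best:
                    best = d
                pb = 2.0 * r0
                for kk in range(indptr[j], indptr[j + 1]):
                    l = indices[kk]
                    dd = math.hypot(pos[l, 0] - pos[j, 0], pos[l, 1] - pos[j, 1])
                    if dd > pb:
                        pb = dd
                m[j] = pb
                if pb > maxm:
                    maxm = pb
                if pb > big_thresh and is_big[j] == 0:
                    big[nbig] = j
                    nbig += 1
                    is_big[j] = 1
            m[i] = best
            if best > maxm:
                maxm = best
            if best > big_thresh and is_big[i] == 0:
                big[nbig] = i
                nbig += 1
                is_big[i] = 1
        # wake / sleep pass -> next worklist
        nw2 = 0
        for idx in range(nw):
            i = work[idx]
            asleep = steplen[i] < tol
            if not asleep and in_next[i] == 0:
                in_next[i] = 1
                work2[nw2] = i
                nw2 += 1
            if asleep:
                active[i] = 0
            if acc[i] < wake_eps:
                continue
            amt = acc[i]
            acc[i] = 0.0
            for src in range(indptr[i], indptr[i + 1] + 1):
                if src == indptr[i + 1]:
                    p = i
                    wr = m[i] + amt + margin
                else:
                    p = indices[src]
                    wr = m[p] + amt + margin
                    if p != 0 and in_next[p] == 0:
                        active[p] = 1
                        in_next[p] = 1
                        work2[nw2] = p
                        nw2 += 1
                span = int((wr + drift) / cell) + 1
                wr2 = wr * wr
                pcx = int((pos[p, 0] - xmin) / cell)
                pcy = int((pos[p, 1] - ymin) / cell)
                if pcx < 0:
                    pcx = 0
                elif pcx >= nx:
                    pcx = nx - 1
                if pcy < 0:
                    pcy = 0
                elif pcy >= ny:
                    pcy = ny - 1
                for gy in range(max(0, pcy - span), min(ny, pcy + span + 1)):
                    for gx in range(max(0, pcx - span), min(nx, pcx + span + 1)):
                        c = gy * nx + gx
                        for q in range(cell_start[c], cell_start[c] + cell_count[c]):
                            j = order[q]
                            if j == 0 or j == p or in_next[j] == 1:
                                continue
                            dx = pos[j, 0] - pos[p, 0]
                            dy = pos[j, 1] - pos[p, 1]
                            if dx * dx + dy * dy < wr2:
                                active[j] = 1
                                in_next[j] = 1
                                work2[nw2] = j
                                nw2 += 1
        for idx in range(nw2):
            in_next[work2[idx]] = 0
            work[idx] = work2[idx]
        nw = nw2
        if drift > margin:
            xmin = pos[:, 0].min() - margin - eps
            ymin = pos[:, 1].min() - margin - eps
            nx = int((pos[:, 0].max() + margin - xmin) / cell) + 1
            ny = int((pos[:, 1].max() + margin - ymin) / cell) + 1
            if nx * ny > len(cell_start):
                cell_start = np.empty(nx * ny, dtype=np.int64)
                cell_count = np.empty(nx * ny, dtype=np.int64)
            _bin_nodes(
                pos, cell, xmin, ymin, nx, ny,
                cell_start[: nx * ny], cell_count[: nx * ny], order, cell_of,
            )
            drift = 0.0
    return sweeps, coincident


@njit(cache=True)
def new_edge_crosses(pos, parents, site, px, py, reach):
    """True if segment (site -> (px, py)) would cross an existing segment."""
    n = pos.shape[0]
    for j in range(1, n):
        pj = parents[j]
        if j == site or pj == site:
            continue
        if (
            min(pos[j, 0], pos[pj, 0]) > max(pos[site, 0], px) + reach
            or max(pos[j, 0], pos[pj, 0]) < min(pos[site, 0], px) - reach
            or min(pos[j, 1], pos[pj, 1]) > max(pos[site, 1], py) + reach
            or max(pos[j, 1], pos[pj, 1]) < min(pos[site, 1], py) - reach
        ):
            continue
        if _segs_cross(
            pos[site, 0], pos[site, 1], px, py,
            pos[j, 0], pos[j, 1], pos[pj, 0], pos[pj, 1],
        ):
            return True
    return False


@njit(cache=True)
def count_within_radius(pos, queries, r):
    """For each query index, count other nodes within Euclidean distance r."""
    n = pos.shape[0]
    xmin = pos[0, 0]
    ymin = pos[0, 1]
    xmax = pos[0, 0]
    ymax = pos[0, 1]
    for i in range(n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        if pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        if pos[i, 1] > ymax:
            ymax = pos[i, 1]
    cell = r * 1.000001
    nx = int((xmax - xmin) / cell) + 1
    ny = int((ymax - ymin) / cell) + 1
    cell_start = np.empty(nx * ny, dtype=np.int64)
    cell_count = np.empty(nx * ny, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    _bin_nodes(pos, cell, xmin, ymin, nx, ny, cell_start, cell_count, order, cell_of)
    out = np.zeros(len(queries), dtype=np.int64)
    for qi in range(len(queries)):
        i = queries[qi]
        ci = cell_of[i]
        cx = ci % nx
        cy = ci // nx
        cnt = 0
        for gy in range(max(0, cy - 1), min(ny, cy + 2)):
            for gx in range(max(0, cx - 1), min(nx, cx + 2)):
                c = gy * nx + gx
                for q in range(cell_start[c], cell_start[c] + cell_count[c]):
                    j = order[q]
                    if j == i:
                        continue
                    d = math.hypot(pos[j, 0] - pos[i, 0], pos[j, 1] - pos[i, 1])
                    if d <= r:
                        cnt += 1
        out[qi] = cnt
    return out


@njit(cache=True, inline="always")
def _orient(ax, ay, bx, by, cx, cy):
    v = (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)
    if v > 0.0:
        return 1
    if v < 0.0:
        return -1
    return 0


@njit(cache=True)
def count_segment_intersections(pos, parents):
    """Count proper crossings between non-adjacent backbone segments."""
    n = pos.shape[0]
    if n < 2:
        return 0
    # grid over segment midpoints; cell sized to the longest segment
    nseg = n - 1
    mx = np.empty(nseg)
    my = np.empty(nseg)
    maxlen = 1e-12
    for e in range(nseg):
        c = e + 1
        p = parents[c]
        mx[e] = 0.5 * (pos[c, 0] + pos[p, 0])
        my[e] = 0.5 * (pos[c, 1] + pos[p, 1])
        L = math.hypot(pos[c, 0] - pos[p, 0], pos[c, 1] - pos[p, 1])
        if L > maxlen:
            maxlen = L
    xmin = mx.min()
    ymin = my.min()
    cell = maxlen * 1.000001
    nx = int((mx.max() - xmin) / cell) + 1
    ny = int((my.max() - ymin) / cell) + 1
    mid = np.empty((nseg, 2))
    mid[:, 0] = mx
    mid[:, 1] = my
    cell_start = np.empty(nx * ny, dtype=np.int64)
    cell_count = np.empty(nx * ny, dtype=np.int64)
    order = np.empty(nseg, dtype=np.int64)
    cell_of = np.empty(nseg, dtype=np.int64)
    _bin_nodes(mid, cell, xmin, ymin, nx, ny, cell_start, cell_count, order, cell_of)
    hits = 0
    for e in range(nseg):
        a = e + 1
        b = parents[a]
        ci = cell_of[e]
        cx = ci % nx
        cy = ci // nx
        for gy in range(max(0, cy - 1), min(ny, cy + 2)):
            for gx in range(max(0, cx - 1), min(nx, cx + 2)):
                c = gy * nx + gx
                for q in range(cell_start[c], cell_start[c] + cell_count[c]):
                    f = order[q]
                    if f <= e:
                        continue
                    u = f + 1
                    v = parents[u]
                    # skip segments sharing a node
                    if a == u or a == v or b == u or b == v:
                        continue
                    o1 = _orient(pos[a, 0], pos[a, 1], pos[b, 0], pos[b, 1], pos[u, 0], pos[u, 1])
                    o2 = _orient(pos[a, 0], pos[a, 1], pos[b, 0], pos[b, 1], pos[v, 0], pos[v, 1])
                    o3 = _orient(pos[u, 0], pos[u, 1], pos[v, 0], pos[v, 1], pos[a, 0], pos[a, 1])
                    o4 = _orient(pos[u, 0], pos[u, 1], pos[v, 0], pos[v, 1], pos[b, 0], pos[b, 1])
                    if o1 != o2 and o3 != o4 and o1 != 0 and o2 != 0 and o3 != 0 and o4 != 0:
                        hits += 1
    return hits


@njit(cache=True)
def grow_dla(n_particles, max_radius, seed):
    """On-lattice diffusion-limited aggregation from a central seed.

    Walkers launch from a circle just outside the cluster, take unit
    lattice steps (with long radial jumps while far away, which leaves the
    hitting distribution unchanged), stick on 8-neighbour contact and are
    relaunched if they stray beyond the kill radius.  Returns the occupancy
    grid and the number of particles placed.
    """
    size = 2 * max_radius + 3
    grid = np.zeros((size, size), dtype=np.uint8)
    c = size // 2
    grid[c, c] = 1
    placed = 1
    r_clu = 0.0
    rng_state = np.uint64(seed * 2654435761 + 1)

    def _next(state):
        # xorshift64*
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        return state

    while placed < n_particles and r_clu < max_radius - 2:
        r_launch = r_clu + 5.0
        r_kill = 2.0 * r_launch + 20.0
        rng_state = _next(rng_state)
        ang = 2.0 * math.pi * (np.float64(rng_state) / 1.8446744073709552e19)
        x = c + r_launch * math.cos(ang)
        y = c + r_launch * math.sin(ang)
        while True:
            d_c = math.hypot(x - c, y - c)
            if d_c > r_kill:
                rng_state = _next(rng_state)
                ang = 2.0 * math.pi * (np.float64(rng_state) / 1.8446744073709552e19)
                x = c + r_launch * math.cos(ang)
                y = c + r_launch * math.sin(ang)
                continue
            if d_c > r_clu + 6.0:
                # far from the cluster: jump most of the gap in one move
                jump = d_c - r_clu - 4.0
                rng_state = _next(rng_state)
                ang = 2.0 * math.pi * (np.float64(rng_state) / 1.8446744073709552e19)
                x += jump * math.cos(ang)
                y += jump * math.sin(ang)
                continue
            rng_state = _next(rng_state)
            step = int(np.float64(rng_state) / 1.8446744073709552e19 * 4.0)
            if step == 0:
                x += 1.0
            elif step == 1:
                x -= 1.0
            elif step == 2:
                y += 1.0
            else:
                y -= 1.0
            xi = int(round(x))
            yi = int(round(y))
            if xi < 1 or xi >= size - 1 or yi < 1 or yi >= size - 1:
                continue
            # stick on 8-neighbour contact
            touching = False
            for dx in range(-1, 2):
                for dy in range(-1, 2):
                    if grid[xi + dx, yi + dy] == 1:
                        touching = True
                        break
                if touching:
                    break
            if touching:
                grid[xi, yi] = 1
                placed += 1
                d_new = math.hypot(xi - c, yi - c)
                if d_new > r_clu:
                    r_clu = d_new
                break
    return grid, placed


@njit(cache=True)
def paint_segments(grid, xs0, ys0, xs1, ys1, r):
    """Paint thick segments (round caps) by exact centre-in-stadium tests.

    A pixel is set when its centre lies within distance ``r`` of the
    segment, which keeps the painted area unbiased as resolution grows.
    """
    H, W = grid.shape
    r2 = r * r
    for e in range(len(xs0)):
        x0 = xs0[e]
        y0 = ys0[e]
        x1 = xs1[e]
        y1 = ys1[e]
        dx = x1 - x0
        dy = y1 - y0
        L2 = dx * dx + dy * dy
        ix0 = max(0, int(math.floor(min(x0, x1) - r)))
        ix1 = min(W - 1, int(math.ceil(max(x0, x1) + r)))
        iy0 = max(0, int(math.floor(min(y0, y1) - r)))
        iy1 = min(H - 1, int(math.ceil(max(y0, y1) + r)))
        for iy in range(iy0, iy1 + 1):
            cy = iy + 0.5
            for ix in range(ix0, ix1 + 1):
                if grid[iy, ix] == 1:
                    continue
                cx = ix + 0.5
                if L2 > 0.0:
                    t = ((cx - x0) * dx + (cy - y0) * dy) / L2
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                else:
                    t = 0.0
                qx = x0 + t * dx
                qy = y0 + t * dy
                if (cx - qx) ** 2 + (cy - qy) ** 2 <= r2:
                    grid[iy, ix] = 1
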