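"""Overdamped relaxation dynamics of the elastic backbone.

Each relaxation sweep moves every non-root node by ``k(age) * s_i``, where
``k(age) = K * exp(-age / tau)`` implements progressive rigidification and
``s_i`` is the sum of three displacement terms:

* a one-sided inward spring confining nodes to the boundary disc,
* a chain spring keeping neighbour nodes at separation ``r0``,
* a purely repulsive non-neighbour interaction keeping node ``i`` at least
  ``m_j = max(2 r0, longest chain edge at j)`` away from every
  non-neighbour ``j`` — the self-avoidance mechanism.

The functions here are the plain-NumPy reference path (all-pairs sums); the
production simulation uses the grid-accelerated kernel in
:mod:`turbisim._kernels`, which is required to produce identical results.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .params import SimParams
from .tree import BackboneTree, BoundaryState

logger = logging.getLogger(__name__)

__all__ = [
    "stiffness",
    "neighbor_displacement",
    "exclusion_radius",
    "nonneighbor_displacement",
    "boundary_displacement",
    "total_displacement",
    "relax_step",
    "update_boundary",
    "coincident_direction",
]


def stiffness(t_now: float, t_birth: float, params: SimParams) -> float:
    """Mobility gain ``K * exp(-(t_now - t_birth) / tau)`` of a node."""
    age = t_now - t_birth
    if age < 0:
        raise ValueError(f"negative node age: t_now={t_now} < t_birth={t_birth}")
    return params.K * math.exp(-age / params.tau)


def neighbor_displacement(r_i, r_j, r0: float) -> np.ndarray:
    """Chain-spring displacement on ``i`` from neighbour ``j`` (rest length r0)."""
    d = np.asarray(r_j, float) - np.asarray(r_i, float)
    dist = math.hypot(*d)
    if dist == 0.0:
        logger.warning("coincident chain neighbours; spring direction undefined")
        return np.zeros(2)
    return d / dist * (dist - r0)


def exclusion_radius(tree: BackboneTree, j: int, r0: float) -> float:
    """Self-avoidance radius ``m_j``.

    The exclusion distance of node ``j`` is at least ``2 r0`` and at least
    the distance to its furthest chain neighbour, so stretched chain
    segments cannot be threaded by other branches.
    """
    nbrs = tree.chain_neighbors(j)
    if not nbrs:
        return 2.0 * r0
    pj = tree.positions[j]
    far = max(math.hypot(*(tree.positions[l] - pj)) for l in nbrs)
    return max(2.0 * r0, far)


def coincident_direction(i: int, j: int) -> np.ndarray:
    """Deterministic pseudo-random unit vector for coincident node pairs.

    Hashed from the (ordered) node ids so a degenerate configuration always
    resolves the same way instead of producing NaNs.
    """
    h = math.sin(i * 12.9898 + j * 78.233) * 43758.5453
    ang = 2.0 * math.pi * (h - math.floor(h))
    return np.array([math.cos(ang), math.sin(ang)])


def nonneighbor_displacement(r_i, r_j, m_j: float, pair_ids=None) -> np.ndarray:
    """Repulsive displacement on ``i`` from non-neighbour ``j``.

    Zero beyond ``m_j``; inside, points away from ``j`` with magnitude
    ``m_j - |dr|``.  Coincident nodes repel along a deterministic hashed
    direction (see :func:`coincident_direction`).
    """
    d = np.asarray(r_j, float) - np.asarray(r_i, float)
    dist = math.hypot(*d)
    if dist >= m_j:
        return np.zeros(2)
    if dist == 0.0:
        i, j = pair_ids if pair_ids is not None else (0, 1)
        return -coincident_direction(i, j) * m_j
    return d / dist * (dist - m_j)


def boundary_displacement(r_i, boundary: BoundaryState, r0: float) -> np.ndarray:
    """One-sided inward spring confining a node to the boundary disc.

    Vanishes in the interior (``|r| <= b - r0``) and ramps linearly within
    ``r0`` of the wall; same stiffness family as the chain spring.  The
    root node is exempt (it sits on the boundary by construction) — the
    exemption is applied by the caller, not here.
    """
    r = np.asarray(r_i, float)
    dist = math.hypot(*r)
    inner = boundary.b - r0
    if dist <= inner or dist == 0.0:
        return np.zeros(2)
    return -r / dist * (dist - inner)


def all_exclusion_radii(tree: BackboneTree, r0: float) -> np.ndarray:
    """Vector of ``m_j`` for every node (vectorized over the edge list)."""
    m = np.full(tree.n, 2.0 * r0)
    if tree.n > 1:
        lengths = tree.edge_lengths()
        parents = tree.parents[1:]
        children = np.arange(1, tree.n)
        np.maximum.at(m, parents, lengths)
        np.maximum.at(m, children, lengths)
        np.maximum(m, 2.0 * r0, out=m)
    return m


def total_displacement(
    tree: BackboneTree, i: int, boundary: BoundaryState, params: SimParams
) -> np.ndarray:
    """All-pairs displacement sum on node ``i`` (reference path).

    The production kernel restricts the non-neighbour sum to nodes within
    range using a uniform grid; its result must be identical to this sum.
    """
    if i == tree.root_id:
        raise ValueError("the root node is fixed and accumulates no displacement")
    r0 = params.r0
    pos = tree.positions
    nbrs = set(tree.chain_neighbors(i))
    s = boundary_displacement(pos[i], boundary, r0)
    for j in nbrs:
        s = s + neighbor_displacement(pos[i], pos[j], r0)
    if params.avoidance:
        m = all_exclusion_radii(tree, r0)
        for j in range(tree.n):
            if j == i or j in nbrs:
                continue
            s = s + nonneighbor_displacement(pos[i], pos[j], m[j], pair_ids=(i, j))
    return s


def relax_step(
    tree: BackboneTree,
    boundary: BoundaryState,
    t_now: int,
    params: SimParams,
) -> BackboneTree:
    """One synchronous relaxation sweep (reference path).

    Every non-root node is moved by ``k(age) * s_i`` where all ``s_i`` are
    evaluated at the pre-step positions; the root stays fixed and the tree
    topology is untouched.
    """
    new = tree.copy()
    for i in range(1, tree.n):
        k = stiffness(t_now, tree.birth_times[i], params)
        step = k * total_displacement(tree, i, boundary, params)
        new.positions[i] = tree.positions[i] + step
        if not np.all(np.isfinite(new.positions[i])):
            raise FloatingPointError(f"non-finite position for node {i} after relaxation")
    return new


def update_boundary(boundary: BoundaryState, A_b: float, params: SimParams) -> float:
    """Boundary radius update maintaining the target porosity.

    Solves ``phi_target = 1 - A_b / (pi b'^2)`` for ``b'``, clamps from
    below so the cavity never shrinks and from above at the maximum radius
    ``B``.
    """
    if A_b <= 0:
        raise ValueError("no bone area: cannot define porosity")
    phi = 1.0 - A_b / (math.pi * boundary.b**2)
    if phi >= 1.0:
        raise ValueError("no bone area: porosity >= 1")
    b_new = boundary.b * math.sqrt(max(1.0 - phi, 0.0) / (1.0 - params.phi_target))
    return min(boundary.b_max, max(boundary.b, b_new))
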