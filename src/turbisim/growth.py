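"""Growth step and the main simulation loop.

A run alternates stochastic growth events with deterministic relaxation:
each growth step a branch tip is selected with probability inversely
proportional to local node density, a new node (or a fork of two) is placed
on a circle of radius ``r0 / 10`` around it, the tree is relaxed for
``n_relax`` sweeps, and the boundary radius is updated so the analytic
porosity tracks the target.  Forking is disabled from the birth timestep
``t_B`` on, so the postnatal phase only elongates existing branches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .params import SimParams
from .tree import BackboneTree, BoundaryState

__all__ = [
    "SimState",
    "GrowthEvent",
    "SimResult",
    "seed_tree",
    "local_density",
    "select_growth_site",
    "grow",
    "simulate",
]

#: simulations with self-avoidance disabled are halted beyond this many
#: branch crossings; the collapse regime is established by then
MAX_COLLISIONS = 50

#: radius of the local-density counting ball, in units of r0.  The ball
#: must reach past the exclusion distance 2 r0 — self-avoidance keeps all
#: non-neighbours at least that far away, so a ball of radius r0 would
#: only ever contain a tip's own parent and the inverse-density rule
#: would not discriminate between crowded and open tips at all.  Three r0
#: is the smallest radius that sees the nearest neighbouring branch.
DENSITY_RADIUS_FACTOR = 3.0


@dataclass
class SimState:
    """Evolving state of one run."""

    tree: BackboneTree
    boundary: BoundaryState
    t: int
    t_max: int

    @property
    def t_star(self) -> float:
        return self.t / self.t_max


@dataclass
class GrowthEvent:
    parent_id: int
    mode: str  # "elongate" | "fork"
    child_ids: tuple[int, ...]
    t: int


@dataclass
class SimResult:
    """Final state plus per-step traces and requested snapshots."""

    state: SimState
    params: SimParams
    phi_trace: np.ndarray  # analytic porosity after each boundary update
    b_trace: np.ndarray
    leaf_trace: np.ndarray
    snapshots: dict[float, SimState] = field(default_factory=dict)
    events: list[GrowthEvent] | None = None
    collisions: int = 0
    stopped_early: bool = False

    @property
    def tree(self) -> BackboneTree:
        return self.state.tree

    @property
    def boundary(self) -> BoundaryState:
        return self.state.boundary


def seed_tree(params: SimParams) -> tuple[BackboneTree, BoundaryState]:
    """Initial four-node chain rooted to the left side of the boundary.

    The root sits on the boundary at angle pi with a three-edge chain at
    spacing ``r0`` extending inward; the initial radius is chosen so the
    analytic porosity of the seed already equals the target, avoiding a
    startup transient in the boundary update.
    """
    r0 = params.r0
    A_b = 3.0 * r0 * params.w
    b0 = math.sqrt(A_b / ((1.0 - params.phi_target) * math.pi))
    b0 = min(b0, params.B)
    pos = np.array([[-b0 + k * r0, 0.0] for k in range(4)])
    parents = np.array([-1, 0, 1, 2])
    births = np.zeros(4, dtype=np.int64)
    return BackboneTree(pos, parents, births), BoundaryState(b=b0, b_max=params.B)


def local_density(tree: BackboneTree, i: int, r0: float) -> int:
    """Number of other nodes within a closed ball of radius ``r0`` of node i."""
    d = np.hypot(*(tree.positions - tree.positions[i]).T)
    return int(np.sum(d <= r0)) - 1


def _tip_weights(tree: BackboneTree, params: SimParams, tips: np.ndarray) -> np.ndarray:
    if params.density_weighting:
        dens = _kernels.count_within_radius(
            tree.positions, tips, DENSITY_RADIUS_FACTOR * params.r0
        )
        # every tip has its parent within ~r0, so the local count is >= 1
        # in practice; the floor only guards degenerate configurations
        w = 1.0 / np.maximum(dens, 1)
    else:
        w = np.ones(len(tips))
    return w / w.sum()


def select_growth_site(tree: BackboneTree, params: SimParams, rng) -> int:
    """Sample a branch tip with probability inversely proportional to the
    local density (the number of nodes within ``r0`` of the tip)."""
    tips = tree.tips()
    if len(tips) == 0:
        raise RuntimeError("tree has no growable tips")
    p = _tip_weights(tree, params, tips)
    u = rng.random()
    idx = int(np.searchsorted(np.cumsum(p), u, side="right"))
    return int(tips[min(idx, len(tips) - 1)])


def grow(
    tree: BackboneTree,
    site: int,
    mode: str,
    t_now: int,
    params: SimParams,
    rng,
) -> GrowthEvent:
    """Insert one (elongate) or two (fork) children on the r0/10 circle."""
    if mode not in ("elongate", "fork"):
        raise ValueError(f"unknown growth mode: {mode!r}")
    if tree.degrees[site] != 1 or site == tree.root_id:
        raise ValueError(f"growth site {site} is not a branch tip")
    if mode == "fork" and t_now >= params.t_B:
        raise ValueError(f"fork requested at t={t_now} >= t_B={params.t_B}")
    n_children = 2 if mode == "fork" else 1
    children = []
    for _ in range(n_children):
        # redraw the angle (shrinking the circle if need be) when the new
        # tiny segment would cross an existing one, so the embedding stays
        # crossing-free from birth
        placed = False
        for radius in (params.r0 / 10.0, params.r0 / 50.0, params.r0 / 250.0):
            for _attempt in range(20):
                theta = rng.random() * 2.0 * math.pi
                p = tree.positions[site] + radius * np.array(
                    [math.cos(theta), math.sin(theta)]
                )
                if not params.avoidance or not _kernels.new_edge_crosses(
                    tree.positions, tree.parents, site, p[0], p[1], 0.0
                ):
                    placed = True
                    break
            if placed:
                break
        children.append(tree.add_node(site, p, t_now))
    return GrowthEvent(parent_id=site, mode=mode, child_ids=tuple(children), t=t_now)


def _neighbor_csr_fast(tree: BackboneTree) -> tuple[np.ndarray, np.ndarray]:
    n = tree.n
    if n == 1:
        return np.zeros(2, dtype=np.int64), np.zeros(0, dtype=np.int64)
    children = np.arange(1, n, dtype=np.int64)
    par = tree.parents[1:]
    rows = np.concatenate([children, par])
    cols = np.concatenate([par, children])
    order = np.argsort(rows, kind="stable")
    indices = cols[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(rows, minlength=n), out=indptr[1:])
    return indptr, indices


def _relax(
    tree: BackboneTree,
    boundary: BoundaryState,
    t_now: int,
    params: SimParams,
) -> int:
    """Run the relaxation sweeps in place on the tree's position array."""
    indptr, indices = _neighbor_csr_fast(tree)
    pos = tree.positions
    birth = tree.birth_times.astype(np.float64)
    if params.relax_mode == "fixed":
        max_sweeps, tol = params.n_relax, 0.0
    else:
        max_sweeps, tol = max(params.n_relax, 50), params.relax_tol * params.r0
    sweeps, _ = _kernels.relax_sweeps(
        pos, indptr, indices, birth, float(t_now),
        params.K, params.tau, params.r0, boundary.b,
        max_sweeps, tol, params.avoidance,
    )
    if not np.all(np.isfinite(pos)):
        bad = int(np.nonzero(~np.isfinite(pos).all(axis=1))[0][0])
        raise FloatingPointError(f"non-finite position for node {bad} during relaxation")
    return sweeps


def simulate(
    params: SimParams,
    snapshot_times: tuple[float, ...] = (),
    record_events: bool = False,
) -> SimResult:
    """Run one full growth trajectory; reproducible given ``params.seed``.

    Per growth step the stochastic draws consume the run generator in a
    fixed order: site-selection uniform, fork/elongate uniform, then one
    angle per new child.
    """
    rng = np.random.default_rng(params.seed)
    tree, boundary = seed_tree(params)
    phi_trace = np.empty(params.t_max)
    b_trace = np.empty(params.t_max)
    leaf_trace = np.empty(params.t_max, dtype=np.int64)
    snap_at = {int(round(ts * params.t_max)): ts for ts in snapshot_times}
    snapshots: dict[float, SimState] = {}
    events: list[GrowthEvent] | None = [] if record_events else None
    collisions = 0
    stopped = False
    active = np.ones(tree.n, dtype=np.uint8)
    tol = params.relax_tol * params.r0
    wake_eps = 0.05 * params.r0
    max_sweeps = max(params.n_relax, 50)
    t = 0
    for t in range(1, params.t_max + 1):
        site = select_growth_site(tree, params, rng)
        if t - 1 < params.t_B and rng.random() < params.p_fork:
            mode = "fork"
        else:
            mode = "elongate"
        ev = grow(tree, site, mode, t - 1, params, rng)
        if events is not None:
            events.append(ev)
        pos = tree.positions
        if len(active) < tree.n:
            grown = np.ones(tree.n, dtype=np.uint8)
            grown[: len(active)] = active
            active = grown
        # wake the neighbourhood of the growth site
        maxm = max(2.0 * params.r0, float(tree.edge_lengths().max(initial=0.0)))
        d_site = np.hypot(*(pos - pos[site]).T)
        active[d_site < maxm + params.r0] = 1
        active[0] = 0
        indptr, indices = _neighbor_csr_fast(tree)
        if params.relax_mode == "fixed":
            _kernels.relax_sweeps(
                pos, indptr, indices, tree.birth_times.astype(np.float64),
                float(t), params.K, params.tau, params.r0, boundary.b,
                params.n_relax, 0.0, params.avoidance,
            )
        else:
            if t % 200 == 0:
                active[1:] = 1  # periodic global flush of stale residuals
            _kernels.relax_active(
                pos, indptr, indices, tree.parents,
                tree.birth_times.astype(np.float64),
                float(t), params.K, params.tau, params.r0, boundary.b,
                max_sweeps, tol, wake_eps, params.avoidance, active,
            )
        if not np.all(np.isfinite(pos)):
            bad = int(np.nonzero(~np.isfinite(pos).all(axis=1))[0][0])
            raise FloatingPointError(f"non-finite position for node {bad} at t={t}")
        A_b = tree.total_length() * params.w
        from .relax import update_boundary  # local import avoids cycle

        b_old = boundary.b
        boundary.b = update_boundary(boundary, A_b, params)
        db = boundary.b - b_old
        # the root stays pinned to the wall as the cavity expands; wake the
        # wall band and the root's interaction field
        tree.positions[0] = (-boundary.b, 0.0)
        if db > 0:
            rad = np.hypot(*pos.T)
            active[rad > b_old - params.r0] = 1
            d_root = np.hypot(*(pos - pos[0]).T)
            active[d_root < maxm + db + params.r0] = 1
            active[0] = 0
        phi_trace[t - 1] = 1.0 - A_b / (math.pi * boundary.b**2)
        b_trace[t - 1] = boundary.b
        leaf_trace[t - 1] = tree.leaf_count()
        if t in snap_at:
            snapshots[snap_at[t]] = SimState(
                tree.copy(), BoundaryState(boundary.b, boundary.b_max), t, params.t_max
            )
        if not params.avoidance and t % 50 == 0:
            collisions = int(
                _kernels.count_segment_intersections(tree.positions, tree.parents)
            )
            if collisions > MAX_COLLISIONS:
                stopped = True
                break
    collisions = int(_kernels.count_segment_intersections(tree.positions, tree.parents))
    state = SimState(tree, boundary, t, params.t_max)
    return SimResult(
        state=state,
        params=params,
        phi_trace=phi_trace[:t],
        b_trace=b_trace[:t],
        leaf_trace=leaf_trace[:t],
        snapshots=snapshots,
        events=events,
        collisions=collisions,
        stopped_early=stopped,
    )
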