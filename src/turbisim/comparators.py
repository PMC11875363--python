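"""Baseline pattern generators for comparison with the growth model.

Two classic branching/aggregation processes serve as contrasts:

* on-lattice diffusion-limited aggregation (DLA), whose clusters are
  fractal with mass-radius dimension ~1.71 in the plane, and
* a branching-annihilating random walk (BARW) in the style of tip-based
  airway models: persistent random-walking tips that branch stochastically
  and terminate when they approach existing branches or the domain wall.

Both are calibrated (particle count / rates frozen in the shipped
defaults) so their median final porosity matches the growth model's
target, making the morphometric comparison like-for-like.  Neither
process regulates its channel width, which is the qualitative contrast
the metrics quantify.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._kernels import grow_dla
from .raster import RasterImage
from .tree import BackboneTree

__all__ = [
    "DLAParams",
    "BARWParams",
    "FractalEstimate",
    "simulate_dla",
    "simulate_barw",
    "fractal_dimension",
    "channel_width_cv",
]


@dataclass
class DLAParams:
    """On-lattice DLA configuration.

    ``n_particles`` and ``lattice_radius`` are alternatives for stopping:
    growth ends when the particle budget is spent or the cluster reaches
    the lattice edge.  ``target_porosity`` (if set) instead stops when the
    porosity of the enclosing disc drops to the target.
    """

    lattice_radius: int = 620
    n_particles: int = 30000
    target_porosity: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_radius <= 0:
            raise ValueError("lattice_radius must be positive")


@dataclass
class BARWParams:
    """Branching-annihilating random walk configuration.

    Tips advance ``step`` per iteration with Gaussian angular noise
    ``turn_sigma``; each active tip branches with probability
    ``branch_rate`` per step (new tip rotated ~70 degrees) and annihilates
    when it comes within ``annihilation_radius`` of previously deposited
    trail or leaves the domain disc.  Defaults are calibrated so the
    median porosity of the thickened trail inside the domain is ~0.75.
    """

    domain_radius: float = 55.0
    step: float = 1.0
    turn_sigma: float = 0.15
    branch_rate: float = 0.25
    branch_angle: float = 1.22  # ~70 degrees
    annihilation_radius: float = 2.0
    grace_steps: int = 5
    thickness: float = 0.5
    max_steps: int = 11000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.step, self.domain_radius) <= 0:
            raise ValueError("step and domain_radius must be positive")
        if self.branch_rate < 0 or self.annihilation_radius < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class FractalEstimate:
    D_f: float
    method: str
    r_squared: float


def simulate_dla(params: DLAParams) -> RasterImage:
    """Grow a DLA cluster; returns it as a binary raster (bone = cluster).

    Walkers launch from a circle just outside the cluster, stick on
    8-neighbour contact, and are relaunched if they wander far away.  With
    ``target_porosity`` set, growth stops once the air fraction of the
    disc enclosing the cluster reaches the target.
    """
    R = params.lattice_radius
    if params.target_porosity is None:
        grid, placed = grow_dla(params.n_particles, R, params.seed)
    else:
        # grow in chunks until the enclosing-disc porosity hits the target
        n = 1000
        grid = None
        while True:
            grid, placed = grow_dla(n, R, params.seed)
            size = grid.shape[0]
            c = size // 2
            ys, xs = np.nonzero(grid)
            r_clu = max(1.0, np.hypot(ys - c, xs - c).max())
            phi = 1.0 - placed / (math.pi * r_clu**2)
            if phi <= params.target_porosity or r_clu >= R - 2 or placed < n:
                break
            n *= 2
    size = grid.shape[0]
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    ys, xs = np.nonzero(grid)
    r_clu = max(1.0, float(np.hypot(ys - size // 2, xs - size // 2).max()))
    mask = (yy - c) ** 2 + (xx - c) ** 2 <= r_clu**2
    return RasterImage(
        grid=grid.astype(np.uint8), pixel_size=1.0, boundary_mask=mask,
        span=2 * r_clu,
    )


def simulate_barw(params: BARWParams) -> BackboneTree:
    """Run the branching-annihilating random walk; returns the trail tree.

    Deposited trail points are the nodes; each tip's track forms a chain,
    with branches attached where tip duplications occurred.
    """
    rng = np.random.default_rng(params.seed)
    R = params.domain_radius
    a = params.annihilation_radius
    cell = max(a, params.step, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}

    positions = [np.zeros(2)]
    parents = [-1]
    births = [0]

    def deposit(idx):
        x, y = positions[idx]
        grid.setdefault((int(x // cell), int(y // cell)), []).append(idx)

    def near_trail(p, exclude: set[int]) -> bool:
        if a <= 0:
            return False
        cx, cy = int(p[0] // cell), int(p[1] // cell)
        span = int(math.ceil(a / cell))
        for gy in range(cy - span, cy + span + 1):
            for gx in range(cx - span, cx + span + 1):
                for j in grid.get((gx, gy), ()):
                    if j in exclude:
                        continue
                    if np.hypot(*(positions[j] - p)) < a:
                        return True
        return False

    deposit(0)
    # tips: (node, heading, own recent trail ids, steps since birth)
    tips = [(0, rng.random() * 2 * math.pi, (0,), params.grace_steps)]
    step_count = 0
    n_excl = max(4, int(math.ceil(2.0 * a / max(params.step, 1e-9))))
    while tips and step_count < params.max_steps:
        new_tips = []
        for node, heading, recent, age in tips:
            step_count += 1
            heading += rng.normal(0.0, params.turn_sigma)
            p = positions[node] + params.step * np.array(
                [math.cos(heading), math.sin(heading)]
            )
            if np.hypot(*p) >= R:
                continue  # tip annihilates on the wall
            # a freshly branched tip gets a short grace period so it can
            # clear its parent and sibling before steric death applies
            if age >= params.grace_steps and near_trail(p, set(recent)):
                continue
            positions.append(p)
            parents.append(node)
            births.append(step_count)
            idx = len(positions) - 1
            deposit(idx)
            recent = (recent + (idx,))[-n_excl:]
            if rng.random() < params.branch_rate:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                new_tips.append(
                    (idx, heading + sign * params.branch_angle, recent, 0)
                )
            new_tips.append((idx, heading, recent, age + 1))
        tips = new_tips
    pos = np.array(positions)
    return BackboneTree(pos, np.array(parents), np.array(births))


def fractal_dimension(
    obj, method: str = "mass-radius", min_sites: int = 1000
) -> FractalEstimate:
    """Fractal dimension of a raster or point cloud.

    Mass-radius (default): slope of ``log N(<r)`` against ``log r`` about
    the cluster centre over the central scaling decade.  Box counting:
    slope of occupied-box count against inverse box size.
    """
    if isinstance(obj, RasterImage):
        ys, xs = np.nonzero(obj.grid)
        pts = np.column_stack([xs, ys]).astype(float)
    else:
        pts = np.asarray(obj, dtype=float)
    if len(pts) < min_sites:
        raise ValueError(f"need at least {min_sites} occupied sites")
    if method == "mass-radius":
        centre = pts.mean(axis=0)
        r = np.hypot(*(pts - centre).T)
        r_max = r.max()
        radii = np.logspace(math.log10(2.0), math.log10(r_max / 2.0), 24)
        counts = np.array([(r <= rad).sum() for rad in radii])
        good = counts > 10
        x = np.log10(radii[good])
        y = np.log10(counts[good])
    elif method == "box-counting":
        span = pts.max(axis=0) - pts.min(axis=0)
        base = pts - pts.min(axis=0)
        sizes = np.logspace(math.log10(2.0), math.log10(span.max() / 16.0), 12)
        x, y = [], []
        for s in sizes:
            boxes = {tuple((base[k] // s).astype(int)) for k in range(len(base))}
            x.append(math.log10(1.0 / s))
            y.append(math.log10(len(boxes)))
        x, y = np.array(x), np.array(y)
    else:
        raise ValueError(f"unknown method: {method}")
    slope, icpt = np.polyfit(x, y, 1)
    yhat = slope * x + icpt
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return FractalEstimate(
        D_f=float(abs(slope)),
        method=method,
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
    )


def channel_width_cv(img: RasterImage) -> float:
    """Coefficient of variation of local air-channel half-widths.

    The Euclidean distance transform of the air phase (inside the
    boundary mask) measures each air pixel's distance to bone; its local
    maxima trace the channel medial axis, so the ridge values sample the
    local channel half-width.  A structure with a well-regulated channel
    width has a small CV (the growth model sits near 0.6); structures
    with voids over a wide range of scales (DLA, BARW) exceed 2.
    """
    air = (~img.grid.astype(bool)) & img.boundary_mask.astype(bool)
    if not air.any():
        raise ValueError("no air phase")
    edt = ndimage.distance_transform_edt(air)
    ridge = (edt == ndimage.maximum_filter(edt, size=3)) & air & (edt > 0)
    vals = edt[ridge]
    if len(vals) == 0:
        raise ValueError("empty channel ridge")
    return float(vals.std() / vals.mean())
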