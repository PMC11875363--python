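"""Deterministic geometric fixtures with closed-form metric values.

Each generator returns the object plus a dict of analytically known
answers, so tests can compare measured metrics against exact geometry:
discs and annuli for the area/perimeter/hydraulic-diameter estimators,
paths and perfect binary trees for the Strahler machinery, combs and
boustrophedon meanders for the path-dimension estimator.
"""

from __future__ import annotations

import math

import numpy as np

from .raster import RasterImage
from .tree import BackboneTree

__all__ = ["generate_fixture"]


def _disc(size: int, r: float, cx=None, cy=None) -> np.ndarray:
    cx = (size - 1) / 2.0 if cx is None else cx
    cy = (size - 1) / 2.0 if cy is None else cy
    yy, xx = np.mgrid[0:size, 0:size]
    return ((xx - cx) ** 2 + (yy - cy) ** 2) <= r**2


def generate_fixture(kind: str, **kw):
    """Build a named fixture; returns ``(object, expected)``.

    Kinds: ``circle`` (solid bone disc), ``circular_airway`` (full-frame
    bone with one round hole), ``annulus``, ``path`` (straight chain),
    ``binary_tree`` (perfect, unit branch lengths), ``comb``, ``meander``
    (boustrophedon curve in a square).
    """
    if kind == "circle":
        r = kw.get("radius", 100.0)
        size = int(kw.get("size", 4 * r))
        grid = _disc(size, r).astype(np.uint8)
        mask = np.ones_like(grid, dtype=bool)
        img = RasterImage(grid=grid, pixel_size=1.0, boundary_mask=mask, span=2 * r)
        return img, {
            "A": math.pi * r**2,
            "P": 2 * math.pi * r,
            "C_x_self": 1.0,  # ln(P^2/4pi)/ln(A) with the disc's own area
        }
    if kind == "circular_airway":
        r = kw.get("radius", 60.0)
        size = int(kw.get("size", 6 * r))
        grid = (~_disc(size, r)).astype(np.uint8)  # bone everywhere but the hole
        mask = np.ones_like(grid, dtype=bool)
        img = RasterImage(grid=grid, pixel_size=1.0, boundary_mask=mask, span=size)
        return img, {"A_c": math.pi * r**2, "P": 2 * math.pi * r, "D_h": 2 * r}
    if kind == "annulus":
        r_in = kw.get("r_in", 40.0)
        r_out = kw.get("r_out", 80.0)
        size = int(kw.get("size", 4 * r_out))
        grid = (_disc(size, r_out) & ~_disc(size, r_in)).astype(np.uint8)
        mask = _disc(size, 2 * r_out)
        img = RasterImage(grid=grid, pixel_size=1.0, boundary_mask=mask, span=2 * r_out)
        return img, {
            "A_b": math.pi * (r_out**2 - r_in**2),
            "P": 2 * math.pi * (r_out + r_in),
        }
    if kind == "path":
        n = int(kw.get("n", 50))
        spacing = kw.get("spacing", 1.0)
        pos = np.column_stack([np.arange(n) * spacing, np.zeros(n)])
        parents = np.concatenate([[-1], np.arange(n - 1)])
        tree = BackboneTree(pos, parents, np.zeros(n, dtype=np.int64))
        return tree, {"H": 1, "d_m": 1.0}
    if kind == "binary_tree":
        depth = int(kw.get("depth", 4))
        # perfect binary tree, unit-length branches laid out radially
        pos = [np.zeros(2)]
        parents = [-1]
        level = [(0, 0.0, math.pi)]  # (node, angle_centre, angular_width)
        for d in range(depth):
            nxt = []
            for node, ang, width in level:
                for s in (-1, 1):
                    a = ang + s * width / 4
                    p = pos[node] + np.array([math.cos(a), math.sin(a)])
                    pos.append(p)
                    parents.append(node)
                    nxt.append((len(pos) - 1, a, width / 2))
            level = nxt
        tree = BackboneTree(
            np.array(pos), np.array(parents), np.zeros(len(pos), dtype=np.int64)
        )
        return tree, {"H": depth, "leaves": 2**depth, "R_B": 2.0, "R_L": 1.0}
    if kind == "comb":
        n_teeth = int(kw.get("n_teeth", 10))
        tooth = int(kw.get("tooth_nodes", 5))
        pos = [np.array([0.0, 0.0])]
        parents = [-1]
        spine_ids = [0]
        for k in range(1, n_teeth):
            pos.append(np.array([float(k), 0.0]))
            parents.append(spine_ids[-1])
            spine_ids.append(len(pos) - 1)
        for k, sid in enumerate(spine_ids):
            prev = sid
            for j in range(1, tooth + 1):
                pos.append(np.array([float(k), float(j)]))
                parents.append(prev)
                prev = len(pos) - 1
        tree = BackboneTree(
            np.array(pos), np.array(parents), np.zeros(len(pos), dtype=np.int64)
        )
        return tree, {"H": 2}
    if kind == "meander":
        # boustrophedon curve filling a square: d_m rises with line density
        n_lines = int(kw.get("n_lines", 10))
        length = kw.get("length", 40.0)
        spacing = kw.get("spacing", 2.0)
        pts = []
        for k in range(n_lines):
            xs = np.arange(0.0, length, 1.0)
            if k % 2:
                xs = xs[::-1]
            for x in xs:
                pts.append((x, k * spacing))
        pos = np.array(pts)
        parents = np.concatenate([[-1], np.arange(len(pos) - 1)])
        tree = BackboneTree(pos, parents, np.zeros(len(pos), dtype=np.int64))
        return tree, {"H": 1}
    raise ValueError(f"unknown fixture kind: {kind!r}")
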