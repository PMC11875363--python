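"""Replicate-run experiment driver and report aggregation.

Runs a batch of simulations (main model or a comparator) over distinct
seeds, measures the final structures with the full metrics stack, and
aggregates each quantity as mean +/- standard deviation across runs.
Presets reproduce the headline experiments: the default seal
configuration and the monk-seal generalization (target porosity 0.80).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .comparators import BARWParams, DLAParams, simulate_barw, simulate_dla
from .graphs import backbone_dimension, strahler_analysis, tree_to_graph
from .growth import simulate
from .params import SimParams, monk_params, seal_params
from .raster import rasterize, section_metrics

__all__ = ["ExperimentSpec", "MetricsReport", "run_experiment"]

METRIC_COLUMNS = [
    "phi", "A_b", "A_c", "P", "D_h", "D_h_star", "C_x", "S",
    "connectivity", "d_m", "H", "R_B", "R_L", "collisions",
]


@dataclass
class ExperimentSpec:
    """One batch: model, overrides, replicate seeds, metric list."""

    model: str = "main"  # main | dla | barw
    species: str = "seal"  # seal | monk (main model only)
    n_runs: int = 10
    seeds: tuple[int, ...] | None = None
    overrides: dict = field(default_factory=dict)
    resolution: float = 16.0
    n_pairs: int = 2000  # for the path-dimension fit
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.seeds is None:
            self.seeds = tuple(range(self.n_runs))
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")
        if self.model not in ("main", "dla", "barw"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class MetricsReport:
    per_run: pd.DataFrame
    spec: ExperimentSpec

    def aggregate(self) -> pd.DataFrame:
        num = self.per_run.select_dtypes("number")
        agg = pd.DataFrame({"mean": num.mean()})
        agg["sd"] = num.std(ddof=1) if len(num) > 1 else np.nan
        return agg

    def to_csv(self, path) -> None:
        self.per_run.to_csv(path, index=False)

    def to_json(self, path) -> None:
        doc = {
            "spec": {
                "model": self.spec.model,
                "species": self.spec.species,
                "seeds": list(self.spec.seeds),
            },
            "per_run": self.per_run.to_dict(orient="records"),
            "aggregate": {
                k: {"mean": float(v["mean"]), "sd": (None if pd.isna(v["sd"]) else float(v["sd"]))}
                for k, v in self.aggregate().iterrows()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def _measure_main(params: SimParams, spec: ExperimentSpec) -> dict:
    res = simulate(params, snapshot_times=spec.snapshot_times)
    img = rasterize(res.tree, params, boundary_radius=res.boundary.b,
                    resolution=spec.resolution)
    sm = section_metrics(img)
    sr = strahler_analysis(res.tree)
    bd = backbone_dimension(tree_to_graph(res.tree), n_pairs=spec.n_pairs,
                            rng=params.seed)
    row = sm.as_dict()
    row.update(
        d_m=bd.d_m, H=sr.H, R_B=sr.R_B, R_L=sr.R_L,
        collisions=res.collisions, seed=params.seed,
        nodes=res.tree.n, leaves=res.tree.leaf_count(),
        b_final=res.boundary.b,
        phi_trace_min=float(res.phi_trace.min()),
        phi_trace_max=float(res.phi_trace.max()),
    )
    return row


def _measure_barw(params: BARWParams, spec: ExperimentSpec) -> dict:
    tree = simulate_barw(params)
    sim_like = SimParams(w=params.thickness, B=params.domain_radius)
    img = rasterize(tree, sim_like, boundary_radius=params.domain_radius,
                    resolution=spec.resolution)
    sm = section_metrics(img)
    row = sm.as_dict()
    sr = strahler_analysis(tree)
    bd = backbone_dimension(tree_to_graph(tree), n_pairs=spec.n_pairs,
                            rng=params.seed)
    row.update(d_m=bd.d_m, H=sr.H, R_B=sr.R_B, R_L=sr.R_L, seed=params.seed,
               nodes=tree.n)
    return row


def _measure_dla(params: DLAParams, spec: ExperimentSpec) -> dict:
    from .comparators import fractal_dimension

    img = simulate_dla(params)
    sm = section_metrics(img)
    row = sm.as_dict()
    row.update(D_f=fractal_dimension(img).D_f, seed=params.seed)
    return row


def run_experiment(spec: ExperimentSpec) -> MetricsReport:
    """Execute all runs of a batch and collect per-run metrics.

    Results are keyed by seed and independent of execution order; failed
    runs raise (they are not silently dropped from the aggregate).
    """
    rows = []
    for seed in spec.seeds:
        if spec.model == "main":
            base = monk_params if spec.species == "monk" else seal_params
            params = base(seed=seed, **spec.overrides)
            rows.append(_measure_main(params, spec))
        elif spec.model == "barw":
            rows.append(_measure_barw(BARWParams(seed=seed, **spec.overrides), spec))
        else:
            rows.append(_measure_dla(DLAParams(seed=seed, **spec.overrides), spec))
    return MetricsReport(per_run=pd.DataFrame(rows), spec=spec)
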