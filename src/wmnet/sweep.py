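"""Sparsity-grid sweep and AUC integration.

Because any single threshold is arbitrary, each metric is computed at
every sparsity of an inclusive arithmetic grid (default 0.09 to 0.27 in
steps of 0.02, ten points) and summarized by the area under its curve
(trapezoidal rule over the actual grid spacing, units metric x
sparsity).  Sparsities are expressed as fractions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wmnet._seeds import derive_seed
from wmnet.core import (
    ConnectivityMatrix,
    IsolatedNodeError,
    check_no_isolated_nodes,
    threshold_by_sparsity,
)
from wmnet.metrics import (
    clustering_coefficient,
    characteristic_path_length,
    nodal_betweenness,
    nodal_efficiency,
    nodal_strength,
)
from wmnet.nulls import normalized_small_world

GLOBAL_METRICS = ("cp", "lp", "gamma", "lambda")
NODAL_METRICS = ("strength", "efficiency", "betweenness")

__all__ = [
    "GLOBAL_METRICS",
    "NODAL_METRICS",
    "MetricCurve",
    "SubjectCurves",
    "sparsity_grid",
    "compute_curves",
    "auc",
    "auc_tables",
    "curves_to_frame",
]


def sparsity_grid(s_min: float = 0.09, s_max: float = 0.27,
                  step: float = 0.02) -> np.ndarray:
    """Inclusive arithmetic grid of sparsities (fractions)."""
    if not (0 < s_min <= s_max <= 1):
        raise ValueError(f"invalid grid bounds [{s_min}, {s_max}]")
    if step <= 0:
        raise ValueError("step must be positive")
    npts = int(np.floor((s_max - s_min) / step + 1e-9)) + 1
    grid = np.round(s_min + step * np.arange(npts), 10)
    if grid.size == 0:
        raise ValueError("empty sparsity grid")
    return grid


@dataclass(frozen=True)
class MetricCurve:
    """One metric's values across the sparsity grid for one subject."""

    subject_id: str
    metric: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.size != values.size:
            raise ValueError("grid and values differ in length")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("metric curve has non-finite values")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)


def auc(curve: MetricCurve) -> float:
    """Trapezoidal integral of the curve over the actual grid spacing."""
    if curve.grid.size < 2:
        raise ValueError("AUC requires at least two grid points")
    return float(np.trapezoid(curve.values, curve.grid))


@dataclass
class SubjectCurves:
    """All metric curves for one subject across the grid.

    ``nodal`` maps metric name to a (grid points x N nodes) array.
    """

    subject_id: str
    grid: np.ndarray
    global_curves: dict[str, MetricCurve]
    nodal: dict[str, np.ndarray] = field(default_factory=dict)
    node_labels: tuple[str, ...] = ()


def compute_curves(m: ConnectivityMatrix, grid: np.ndarray, *,
                   weighted: bool = True, n_random: int = 1000,
                   seed: int = 0, swap_factor: int = 10,
                   include_nodal: bool = True) -> SubjectCurves:
    """Threshold one subject across the grid and compute every metric.

    At each sparsity: Cp, Lp, and their null-normalized gamma/lambda
    (ensemble of ``n_random`` surrogates, seeded deterministically from
    (seed, subject id, sparsity) so subject order cannot change
    results), plus the three nodal vectors when ``include_nodal``.

    Raises :class:`IsolatedNodeError` if the subject has an isolated
    node at the grid minimum; callers exclude such subjects with a
    logged reason.
    """
    grid = np.asarray(grid, dtype=float)
    n = m.n_nodes
    glob = {name: np.empty(grid.size) for name in GLOBAL_METRICS}
    nodal = {name: np.empty((grid.size, n)) for name in NODAL_METRICS} \
        if include_nodal else {}
    for gi, s in enumerate(grid):
        t = threshold_by_sparsity(m, float(s), binary=not weighted)
        if not check_no_isolated_nodes(t):
            raise IsolatedNodeError(
                f"subject {m.subject_id}: isolated node at sparsity {s:.3f}"
            )
        null_seed = derive_seed(seed, "null", m.subject_id, round(float(s), 6))
        summary = normalized_small_world(
            t, n_random=n_random, rng_seed=null_seed, swap_factor=swap_factor
        )
        glob["cp"][gi] = summary.cp
        glob["lp"][gi] = summary.lp
        glob["gamma"][gi] = summary.gamma
        glob["lambda"][gi] = summary.lambda_
        if include_nodal:
            nodal["strength"][gi] = nodal_strength(t)
            nodal["efficiency"][gi] = nodal_efficiency(t)
            nodal["betweenness"][gi] = nodal_betweenness(t)
    curves = {
        name: MetricCurve(m.subject_id, name, grid, glob[name])
        for name in GLOBAL_METRICS
    }
    return SubjectCurves(subject_id=m.subject_id, grid=grid,
                         global_curves=curves, nodal=nodal,
                         node_labels=m.node_labels)


def auc_tables(curves: list[SubjectCurves]) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Integrate curves into per-subject AUC tables.

    Returns ``(global_auc, nodal_auc)`` where ``global_auc`` is a
    subjects x metrics frame and ``nodal_auc`` maps each nodal metric
    to a subjects x nodes frame (columns are node labels).
    """
    if not curves:
        raise ValueError("no subject curves")
    ids = [c.subject_id for c in curves]
    glob = pd.DataFrame(
        {name: [auc(c.global_curves[name]) for c in curves]
         for name in GLOBAL_METRICS},
        index=pd.Index(ids, name="subject_id"),
    )
    nodal: dict[str, pd.DataFrame] = {}
    labels = curves[0].node_labels
    for name in curves[0].nodal:
        rows = [np.trapezoid(c.nodal[name], c.grid, axis=0) for c in curves]
        nodal[name] = pd.DataFrame(
            np.vstack(rows), index=pd.Index(ids, name="subject_id"),
            columns=list(labels),
        )
    return glob, nodal


def curves_to_frame(curves: list[SubjectCurves]) -> pd.DataFrame:
    """Long-format table: subject_id, sparsity, metric, node, value."""
    records = []
    for c in curves:
        for name, curve in c.global_curves.items():
            for s, v in zip(curve.grid, curve.values):
                records.append((c.subject_id, s, name, "global", v))
        for name, arr in c.nodal.items():
            for gi, s in enumerate(c.grid):
                for ni, v in enumerate(arr[gi]):
                    label = c.node_labels[ni] if c.node_labels else str(ni + 1)
                    records.append((c.subject_id, s, name, label, v))
    return pd.DataFrame(
        records, columns=["subject_id", "sparsity", "metric", "node", "value"]
    )
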