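"""Data model, validation, and sparsity thresholding.

A subject enters the pipeline as a symmetric non-negative N x N matrix
of connection strengths (probabilistic-tractography connection
probabilities in the intended application).  Networks are analysed at a
fixed *sparsity* S -- the fraction of possible node pairs retained --
by keeping the S * N(N-1)/2 strongest edges, either with their original
weights ("weighted" mode) or set to 1 ("binary" mode).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from wmnet.atlas import aal90_labels

SYMMETRY_TOL = 1e-8

__all__ = [
    "ConnectivityMatrix",
    "ThresholdedNetwork",
    "ValidationError",
    "DisconnectedNetworkError",
    "IsolatedNodeError",
    "aal90_labels",
    "load_matrix",
    "load_phenotypes",
    "sparsity_of",
    "threshold_by_sparsity",
    "check_no_isolated_nodes",
    "is_connected",
    "n_possible_edges",
]


class ValidationError(ValueError):
    """Input matrix or table violates a structural invariant."""


class DisconnectedNetworkError(RuntimeError):
    """A metric requiring full connectivity met an infinite distance."""


class IsolatedNodeError(RuntimeError):
    """A thresholded network has a degree-zero node at the grid minimum."""


def n_possible_edges(n: int) -> int:
    return n * (n - 1) // 2


def _validate_weights(w: np.ndarray, what: str = "matrix") -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError(f"{what} must be square, got shape {w.shape}")
    n = w.shape[0]
    if n < 3:
        raise ValidationError(f"{what} must have at least 3 nodes, got {n}")
    if not np.all(np.isfinite(w)):
        raise ValidationError(f"{what} contains non-finite entries")
    if np.any(w < 0):
        raise ValidationError(f"{what} contains negative entries")
    if np.any(np.abs(w - w.T) > SYMMETRY_TOL):
        raise ValidationError(f"{what} is asymmetric beyond tolerance {SYMMETRY_TOL}")
    if np.any(np.abs(np.diag(w)) > 0):
        raise ValidationError(f"{what} has nonzero diagonal entries")
    # enforce exact symmetry after the tolerance check
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's raw weighted network.

    Invariants (checked on construction): square, symmetric within
    1e-8 (then symmetrized exactly), zero diagonal, finite, non-negative,
    N >= 3, one node label per node.
    """

    subject_id: str
    weights: np.ndarray
    node_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = _validate_weights(self.weights, f"matrix of {self.subject_id!r}")
        labels = tuple(self.node_labels) if self.node_labels else tuple(
            f"node_{i + 1}" for i in range(w.shape[0])
        )
        if len(labels) != w.shape[0]:
            raise ValidationError(
                f"{len(labels)} node labels for {w.shape[0]} nodes"
            )
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """A network thresholded at a given sparsity.

    ``sparsity`` is the achieved value k / (N(N-1)/2) where k is the
    retained edge count.  In binary mode all retained weights are 1.
    """

    weights: np.ndarray
    sparsity: float
    binary: bool = False
    subject_id: str | None = None

    def __post_init__(self) -> None:
        w = _validate_weights(self.weights, "thresholded network")
        if not (0.0 < self.sparsity <= 1.0):
            raise ValidationError(f"sparsity {self.sparsity} outside (0, 1]")
        if self.binary:
            nz = w[w > 0]
            if nz.size and not np.allclose(nz, 1.0):
                raise ValidationError("binary network has weights other than 0/1")
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def degrees(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)


def load_matrix(path: str | os.PathLike, labels_path: str | os.PathLike | None = None,
                subject_id: str | None = None) -> ConnectivityMatrix:
    """Read a whitespace- or comma-delimited numeric matrix file.

    The optional companion label file holds one region name per line.
    Raises :class:`ValidationError` for non-square, negative, NaN, or
    asymmetric input, or a label count that does not match N.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        w = np.loadtxt(io.StringIO(text.replace(",", " ")), ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"cannot parse matrix file {path}: {exc}") from exc
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    labels: tuple[str, ...] = ()
    if labels_path is not None:
        with open(labels_path) as fh:
            labels = tuple(line.strip() for line in fh if line.strip())
    return ConnectivityMatrix(subject_id=subject_id, weights=w, node_labels=labels)


REQUIRED_PHENO_COLUMNS = (
    "subject_id", "group", "mbea", "tone", "age", "sex", "iq", "brain_size",
)


def load_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read the phenotype table (delimited text with a header row).

    Required columns: subject_id, group, mbea, tone, age, sex, iq,
    brain_size.  Exactly two group labels must be present and the
    behavioural scores must lie in [0, 100].
    """
    table = pd.read_csv(path, sep=None, engine="python")
    return validate_phenotypes(table)


def validate_phenotypes(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_PHENO_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"expected exactly two group labels, got {groups}")
    for col in ("mbea", "tone"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(vals < 0) or np.any(vals > 100):
            raise ValidationError(f"{col} scores outside [0, 100]")
    return table.reset_index(drop=True)


def sparsity_of(m: ConnectivityMatrix | ThresholdedNetwork) -> float:
    """Fraction of possible node pairs with a nonzero weight."""
    w = m.weights
    n = w.shape[0]
    iu = np.triu_indices(n, 1)
    return float(np.count_nonzero(w[iu])) / n_possible_edges(n)


def threshold_by_sparsity(m: ConnectivityMatrix | ThresholdedNetwork,
                          sparsity: float, binary: bool = False) -> ThresholdedNetwork:
    """Retain the k = rint(S * N(N-1)/2) strongest edges.

    Rounding is half-to-even.  Ties at the cut are broken by
    lexicographic (i, j) node-pair order, so thresholding is
    deterministic even with duplicated weights.  Retained edges keep
    their original weights unless ``binary`` is set, in which case they
    become 1.
    """
    w = np.asarray(m.weights, dtype=float)
    n = w.shape[0]
    npairs = n_possible_edges(n)
    if not (0.0 < sparsity <= 1.0):
        raise ValueError(f"sparsity {sparsity} outside (0, 1]")
    raw = sparsity_of(m)
    if sparsity > raw + 1e-12:
        raise ValueError(
            f"requested sparsity {sparsity:.4f} exceeds raw sparsity {raw:.4f}"
        )
    k = int(np.rint(sparsity * npairs))
    if k == 0:
        raise ValueError(f"sparsity {sparsity} retains zero edges for N={n}")
    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    order = np.lexsort((ju, iu, -vals))[:k]
    out = np.zeros_like(w)
    kept = vals[order]
    out[iu[order], ju[order]] = 1.0 if binary else kept
    out = out + out.T
    subject_id = getattr(m, "subject_id", None)
    return ThresholdedNetwork(
        weights=out, sparsity=k / npairs, binary=binary, subject_id=subject_id
    )


def check_no_isolated_nodes(t: ThresholdedNetwork) -> bool:
    """True iff every node has degree >= 1."""
    return bool(np.all(t.degrees() >= 1))


def is_connected(t: ThresholdedNetwork) -> bool:
    """True iff the network forms a single connected component."""
    ncomp, _ = connected_components(csr_matrix(t.weights), directed=False)
    return ncomp == 1
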