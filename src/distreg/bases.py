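"""Design matrices, penalty matrices and identifiability constraints.

Every smooth term of the structured additive predictor is represented by a
design matrix ``B``, a positive semi-definite penalty matrix ``K`` and a
variance parameter.  This module builds those pieces for the term types the
model supports:

* one-dimensional penalised B-splines (P-splines) with random-walk
  (difference) penalties,
* tensor-product surfaces of two marginal B-spline bases with a
  Kronecker-sum penalty,
* intrinsic Markov-random-field (MRF) terms over a district adjacency
  graph, whose penalty is the graph Laplacian ``diag(N_s) - A`` so that the
  full conditional of a district effect is Normal with mean equal to the
  average of its neighbours and variance ``tau^2 / N_s``,
* effect-coded categorical covariates (+1/-1/0 contrasts).

Smooth terms are made identifiable within the additive decomposition by a
sum-to-zero constraint on the fitted values, implemented as an orthonormal
reparameterisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "SplineBasisDef",
    "PenaltyMatrix",
    "DistrictGraph",
    "spline_def_for",
    "build_bspline_basis",
    "build_difference_penalty",
    "build_tensor_basis",
    "build_mrf_penalty",
    "apply_sum_to_zero_constraint",
    "effect_code",
    "read_district_graph",
    "write_district_graph",
]


@dataclass(frozen=True)
class SplineBasisDef:
    """Definition of a univariate B-spline basis.

    Parameters
    ----------
    covariate : str
        Label of the covariate the basis applies to (used in error
        messages and output files).
    degree : int
        Polynomial degree of the B-spline pieces (cubic by default).
    n_intervals : int
        Number of equidistant interior intervals between the boundary
        knots; the basis has ``n_intervals + degree`` functions.
    boundary : tuple[float, float]
        Lower and upper boundary knots; observations must lie inside.
    penalty_order : int
        Order of the random-walk (difference) penalty on the coefficients.
    """

    covariate: str
    degree: int = 3
    n_intervals: int = 20
    boundary: tuple[float, float] = (0.0, 1.0)
    penalty_order: int = 2

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.n_intervals < self.penalty_order + 1:
            raise ValueError(
                "n_intervals must be >= penalty_order + 1 "
                f"(got {self.n_intervals} vs order {self.penalty_order})"
            )
        lo, hi = self.boundary
        if not lo < hi:
            raise ValueError(f"boundary low must be < high, got {self.boundary}")

    @property
    def n_basis(self) -> int:
        return self.n_intervals + self.degree

    def knots(self) -> np.ndarray:
        """Full knot vector: equidistant interior knots extended by
        ``degree`` equally spaced knots beyond each boundary."""
        lo, hi = self.boundary
        h = (hi - lo) / self.n_intervals
        return lo + h * np.arange(-self.degree, self.n_intervals + self.degree + 1)


@dataclass(frozen=True)
class PenaltyMatrix:
    """A symmetric positive semi-definite penalty with known null-space
    dimension (``rank_deficiency``)."""

    matrix: np.ndarray
    rank_deficiency: int

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("penalty must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("penalty must be symmetric")
        object.__setattr__(self, "matrix", K)

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    @property
    def rank(self) -> int:
        return self.dim - self.rank_deficiency


@dataclass
class DistrictGraph:
    """District adjacency: ordered node labels and undirected edges.

    Nodes with no incident edge ("islands") are allowed; they get a zero
    row in the MRF penalty and are then informed only by the sum-to-zero
    constraint and the variance parameter.
    """

    nodes: list
    edges: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate node labels")
        norm = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop at node {a!r}")
            if a not in node_set or b not in node_set:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            norm.add((a, b) if self.nodes.index(a) < self.nodes.index(b) else (b, a))
        self.edges = norm
        self._index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, node) -> int:
        return self._index[node]

    def neighbours(self, node) -> list:
        out = []
        for a, b in self.edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out

    def degree(self, node) -> int:
        return len(self.neighbours(node))

    @property
    def islands(self) -> list:
        degs = self.degrees()
        return [n for n, d in zip(self.nodes, degs) if d == 0]

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            d[self._index[a]] += 1
            d[self._index[b]] += 1
        return d

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        for a, b in self.edges:
            i, j = self._index[a], self._index[b]
            A[i, j] = A[j, i] = 1.0
        return A


def spline_def_for(
    x: np.ndarray,
    covariate: str,
    degree: int = 3,
    n_intervals: int = 20,
    penalty_order: int = 2,
) -> SplineBasisDef:
    """Default basis definition for an observed covariate.

    Boundary knots are the observed min/max.  Covariates with few distinct
    values (counts such as number of vaccinations) get their interval count
    reduced to ``n_distinct - 1`` to avoid rank pathologies.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise ValueError(f"covariate {covariate!r} is constant")
    n_iv = min(n_intervals, n_distinct - 1)
    n_iv = max(n_iv, penalty_order + 1)
    if hi - lo <= 0:
        raise ValueError(f"covariate {covariate!r} has zero range")
    return SplineBasisDef(
        covariate=covariate,
        degree=degree,
        n_intervals=n_iv,
        boundary=(lo, hi),
        penalty_order=penalty_order,
    )


def build_bspline_basis(x: np.ndarray, basis: SplineBasisDef) -> np.ndarray:
    """Evaluate the B-spline design matrix (one row per observation).

    Rows form a partition of unity; raises if any value of ``x`` falls
    outside the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = basis.boundary
    if np.any(x < lo) or np.any(x > hi):
        bad = x[(x < lo) | (x > hi)]
        raise ValueError(
            f"covariate {basis.covariate!r}: {bad.size} value(s) outside "
            f"boundary [{lo}, {hi}], e.g. {bad[:3]}"
        )
    t = basis.knots()
    # The right boundary point belongs to the last interval; nudge it
    # inside so the de Boor recursion assigns it there.
    eps = (hi - lo) * 1e-12
    xc = np.clip(x, lo, hi - eps) if np.any(x == hi) else x
    design = BSpline.design_matrix(xc, t, basis.degree).toarray()
    assert design.shape[1] == basis.n_basis
    return design


def build_difference_penalty(n_basis: int, order: int) -> PenaltyMatrix:
    """Random-walk penalty ``K = D'D`` for order-``order`` differences.

    ``K`` has rank ``n_basis - order``; its null space is spanned by
    polynomial sequences of degree < ``order``.
    """
    if order < 1:
        raise ValueError("penalty order must be >= 1")
    if order >= n_basis:
        raise ValueError(f"order ({order}) must be < n_basis ({n_basis})")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return PenaltyMatrix(matrix=D.T @ D, rank_deficiency=order)


def build_tensor_basis(
    x1: np.ndarray,
    x2: np.ndarray,
    def1: SplineBasisDef,
    def2: SplineBasisDef,
) -> tuple[np.ndarray, PenaltyMatrix]:
    """Tensor-product design and Kronecker-sum penalty for a 2-D surface.

    The design is the row-wise tensor (Khatri-Rao) product of the two
    marginal bases, so each row again sums to one.  The penalty
    ``K1 (x) I + I (x) K2`` shares a single variance parameter
    (isotropic smoothing).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError(f"length mismatch: {x1.shape} vs {x2.shape}")
    B1 = build_bspline_basis(x1, def1)
    B2 = build_bspline_basis(x2, def2)
    n, p1 = B1.shape
    p2 = B2.shape[1]
    design = (B1[:, :, None] * B2[:, None, :]).reshape(n, p1 * p2)
    K1 = build_difference_penalty(p1, def1.penalty_order).matrix
    K2 = build_difference_penalty(p2, def2.penalty_order).matrix
    K = np.kron(K1, np.eye(p2)) + np.kron(np.eye(p1), K2)
    # Null space of the Kronecker sum = tensor of the marginal null
    # spaces: dimension order1 * order2.
    rank_def = def1.penalty_order * def2.penalty_order
    return design, PenaltyMatrix(matrix=K, rank_deficiency=rank_def)


def build_mrf_penalty(graph: DistrictGraph) -> PenaltyMatrix:
    """Graph-Laplacian penalty ``K = diag(N_s) - A`` of the intrinsic MRF.

    Under the Gaussian MRF prior with precision ``K / tau^2`` the full
    conditional of each district effect is Normal with mean the average of
    its neighbours and variance ``tau^2 / N_s``.  Islands contribute a zero
    row and increase the rank deficiency.
    """
    degs = graph.degrees().astype(float)
    K = np.diag(degs) - graph.adjacency()
    islands = graph.islands
    if islands:
        logger.warning(
            "district graph has %d island(s) with no neighbours: %s",
            len(islands), islands,
        )
    # rank deficiency = number of connected components of the graph
    # (each component contributes one constant null vector).
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    n_comp = nx.number_connected_components(g)
    return PenaltyMatrix(matrix=K, rank_deficiency=n_comp)


def apply_sum_to_zero_constraint(
    design: np.ndarray, penalty: PenaltyMatrix
) -> tuple[np.ndarray, PenaltyMatrix, np.ndarray]:
    """Reparameterise so fitted values sum to zero over the sample.

    The constraint ``1'B beta = 0`` is absorbed by an orthonormal basis
    ``Z`` of the null space of the column-sum vector; returns the
    constrained design ``B Z``, the constrained penalty ``Z'K Z`` and the
    back-transform ``Z`` (original coefficients = ``Z @ constrained``).
    """
    B = np.asarray(design, dtype=float)
    if B.shape[1] != penalty.dim:
        raise ValueError("design/penalty dimension mismatch")
    c = B.sum(axis=0)
    nc = np.linalg.norm(c)
    if nc < 1e-12:
        # already sums to zero for every coefficient vector
        return B, penalty, np.eye(B.shape[1])
    # Householder-style orthonormal complement of c
    q, _ = np.linalg.qr(np.column_stack([c / nc, np.eye(B.shape[1])]))
    Z = q[:, 1:B.shape[1]]
    Kc = Z.T @ penalty.matrix @ Z
    Kc = 0.5 * (Kc + Kc.T)
    # the constrained-out direction reduces the null space iff it
    # intersects it; compute the new rank deficiency numerically
    if Z.shape[1] == 0 or penalty.rank_deficiency == 0:
        new_def = 0
    else:
        eig = np.linalg.eigvalsh(Kc)
        scale = max(np.max(np.abs(eig)), 1.0)
        new_def = int(np.sum(eig < 1e-9 * scale))
    return B @ Z, PenaltyMatrix(matrix=Kc, rank_deficiency=new_def), Z


def effect_code(factor, reference_level=None) -> tuple[np.ndarray, list]:
    """Effect coding (+1/-1/0) of a categorical vector.

    With ``L`` observed levels the design has ``L - 1`` columns, one per
    non-reference level: +1 on rows at that level, -1 on rows at the
    reference level, 0 otherwise.  The reference defaults to the last
    level in sorted order.

    Returns the coded design and the list of non-reference level labels
    (column names).
    """
    factor = np.asarray(factor)
    levels = sorted(set(factor.tolist()))
    if len(levels) < 2:
        raise ValueError(f"factor has a single observed level: {levels}")
    if reference_level is None:
        reference_level = levels[-1]
    if reference_level not in levels:
        raise ValueError(f"reference level {reference_level!r} absent from data")
    others = [lv for lv in levels if lv != reference_level]
    X = np.zeros((factor.size, len(others)))
    ref_rows = factor == reference_level
    for j, lv in enumerate(others):
        X[factor == lv, j] = 1.0
        X[ref_rows, j] = -1.0
    return X, others


def write_district_graph(graph: DistrictGraph, edge_path, node_path) -> None:
    """Persist a graph as a two-column edge list plus a node-universe file
    (so islands survive a round trip)."""
    with open(edge_path, "w") as fh:
        fh.write("from\tto\n")
        for a, b in sorted(graph.edges, key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{a}\t{b}\n")
    with open(node_path, "w") as fh:
        fh.write("node\n")
        for n in graph.nodes:
            fh.write(f"{n}\n")


def read_district_graph(edge_path, node_path) -> DistrictGraph:
    with open(node_path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    nodes = lines[1:]  # skip header
    edges = set()
    with open(edge_path) as fh:
        rows = [ln.split() for ln in fh if ln.strip()]
    for a, b in rows[1:]:
        edges.add((a, b))
    return DistrictGraph(nodes=nodes, edges=edges)
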