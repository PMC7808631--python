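"""Label-ranking source identification via label propagation.

The idea: a propagation source infects its surroundings first, so it tends
to sit in the centre of the infection subgraph and far from the uninfected
frontier. Encode the observed status of every node as an initial label
vector y (infected -> +1, uninfected -> -1, unknown -> 0 by default) and
diffuse it over the network,

    f(k+1) = alpha * M f(k) + (1 - alpha) * y,        0 < alpha < 1,

where M is a degree-normalised adjacency matrix. The iteration converges to

    f* = (1 - alpha) (I - alpha * M)^(-1) y,

and f*_i measures the relative mass of infected versus uninfected labels
around node i: the node ranked highest is the inferred source. alpha
balances the smoothness of f over edges against fidelity to y.

Three normalisations are supported:

* SYM — S = D^(-1/2) W D^(-1/2), the symmetric normalisation whose fixed
  point minimises the degree-unbiased quadratic smoothness cost (default);
* ROW — P = D^(-1) W, the random-walk transition matrix;
* COL — P^T, its transpose (column-stochastic).

Two identifiers are built on the same kernel:

* :func:`blrsi` (basic) — complete observation; argmax of f* restricted to
  the observed-infected candidate set, since the source must be infected.
* :func:`vlrsi` (vanilla) — partial snapshot; the labels no longer reflect
  the true status of every node, so the argmax runs over all nodes.

:func:`closed_form_scores` solves the linear system directly and serves as
the independent oracle for the iterative kernel in the test-suite.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .epidemic import Observation, ObservationMode, ObservedState
from .exceptions import InfeasibleObservationError
from .graphs import ContactNetwork

__all__ = [
    "LabelWeights",
    "MatrixKind",
    "RankingScores",
    "labels_from_observation",
    "build_matrix",
    "propagate_labels",
    "closed_form_scores",
    "blrsi",
    "vlrsi",
    "write_scores",
]

#: Eq-style stop rule: ||f(k+1) - f(k)||_2 <= DEFAULT_TOL_SCALE * n
DEFAULT_TOL_SCALE = 1e-4
DEFAULT_MAX_ITER = 1000


@dataclass(frozen=True)
class LabelWeights:
    """Initial label values: (uninfected a, infected b); unknown is 0."""

    uninfected: float = -1.0
    infected: float = 1.0

    def __post_init__(self):
        if self.uninfected == 0.0 and self.infected == 0.0:
            raise ValueError("label weights (0, 0) carry no information")


class MatrixKind(enum.Enum):
    SYM = "sym"
    ROW = "row"
    COL = "col"


@dataclass(frozen=True)
class RankingScores:
    """Converged (or truncated) label-ranking vector with its provenance."""

    f: np.ndarray
    y: np.ndarray
    alpha: float
    iterations: int
    converged: bool

    def argmax(self, candidates: np.ndarray | None = None) -> int:
        """Highest-scoring node; ties broken to the lowest node id.

        ``candidates`` restricts the argmax to a subset of node ids.
        """
        if candidates is None:
            return int(np.argmax(self.f))
        candidates = np.asarray(candidates)
        if candidates.size == 0:
            raise ValueError("empty candidate set")
        # np.argmax takes the first maximum; candidates are sorted ids
        candidates = np.sort(candidates)
        return int(candidates[np.argmax(self.f[candidates])])


def labels_from_observation(
    obs: Observation, weights: LabelWeights = LabelWeights()
) -> np.ndarray:
    """Initial label vector y: infected -> b, uninfected -> a, unknown -> 0."""
    y = np.zeros(obs.n, dtype=np.float64)
    y[obs.values == ObservedState.INFECTED] = weights.infected
    y[obs.values == ObservedState.UNINFECTED] = weights.uninfected
    return y


def build_matrix(network: ContactNetwork, kind: MatrixKind = MatrixKind.SYM) -> sp.csr_array:
    """Degree-normalised adjacency of the requested kind (sparse CSR)."""
    kind = MatrixKind(kind)
    w = network.adjacency()
    deg = network.degrees().astype(np.float64)
    if np.any(deg == 0):
        raise ValueError("zero-degree node: normalisation undefined")
    if kind is MatrixKind.SYM:
        d_inv_sqrt = sp.diags_array(1.0 / np.sqrt(deg))
        mat = d_inv_sqrt @ w @ d_inv_sqrt
    else:
        row = sp.diags_array(1.0 / deg) @ w
        mat = row if kind is MatrixKind.ROW else row.T
    return sp.csr_array(mat)


def propagate_labels(
    matrix: sp.csr_array,
    y: np.ndarray,
    alpha: float,
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> RankingScores:
    """Iterate f <- alpha*M f + (1-alpha)*y until the update norm is small.

    Stops when ``||f(k+1) - f(k)||_2 <= tol_scale * n``. Non-convergence
    within ``max_iter`` returns the last iterate flagged
    ``converged=False`` rather than raising: the downstream consumer is an
    argmax, for which a loose fixed point is typically sufficient.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    y = np.asarray(y, dtype=np.float64)
    n = y.shape[0]
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} incompatible with y ({n})")
    threshold = tol_scale * n
    f = y.copy()
    for k in range(1, max_iter + 1):
        f_next = alpha * (matrix @ f) + (1.0 - alpha) * y
        delta = float(np.linalg.norm(f_next - f))
        f = f_next
        if delta <= threshold:
            return RankingScores(f=f, y=y, alpha=alpha, iterations=k, converged=True)
    return RankingScores(f=f, y=y, alpha=alpha, iterations=max_iter, converged=False)


def closed_form_scores(
    network: ContactNetwork,
    y: np.ndarray,
    alpha: float,
    kind: MatrixKind = MatrixKind.SYM,
) -> RankingScores:
    """Exact fixed point f* = (1-alpha) (I - alpha*M)^(-1) y by direct solve.

    The spectral radius of every supported normalisation is 1, so
    I - alpha*M is nonsingular for alpha < 1. Kept as the independent
    oracle for :func:`propagate_labels`.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    y = np.asarray(y, dtype=np.float64)
    m = build_matrix(network, kind)
    n = network.n
    system = sp.csc_array(sp.eye_array(n) - alpha * m)
    f = spla.spsolve(system, (1.0 - alpha) * y)
    return RankingScores(f=np.asarray(f), y=y, alpha=alpha, iterations=0, converged=True)


def _scores_for(
    network: ContactNetwork,
    obs: Observation,
    alpha: float,
    kind: MatrixKind,
    weights: LabelWeights,
    tol_scale: float,
    max_iter: int,
) -> RankingScores:
    y = labels_from_observation(obs, weights)
    return propagate_labels(build_matrix(network, kind), y, alpha, tol_scale, max_iter)


def blrsi(
    network: ContactNetwork,
    obs: Observation,
    alpha: float = 0.5,
    kind: MatrixKind = MatrixKind.SYM,
    weights: LabelWeights = LabelWeights(),
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
    return_scores: bool = False,
):
    """Basic label-ranking identifier for a complete observation.

    Returns the observed-infected node with the highest ranking score
    (candidate restriction: the source must itself be infected). With
    ``return_scores=True`` returns ``(source, RankingScores)``.
    """
    if obs.mode is not ObservationMode.COMPLETE:
        raise ValueError("blrsi requires a COMPLETE observation; see vlrsi/tssi")
    candidates = obs.infected_nodes()
    if candidates.size == 0:
        raise InfeasibleObservationError("no infected nodes: nothing to rank")
    scores = _scores_for(network, obs, alpha, kind, weights, tol_scale, max_iter)
    source = scores.argmax(candidates)
    return (source, scores) if return_scores else source


def vlrsi(
    network: ContactNetwork,
    obs: Observation,
    alpha: float = 0.5,
    kind: MatrixKind = MatrixKind.SYM,
    weights: LabelWeights = LabelWeights(),
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
    return_scores: bool = False,
):
    """Vanilla label-ranking identifier for a (partial) snapshot.

    The initial labels no longer reflect every node's true status, so the
    argmax runs over all nodes, observed or not.
    """
    if not np.any(obs.values == ObservedState.INFECTED):
        raise InfeasibleObservationError("snapshot contains no infected label")
    scores = _scores_for(network, obs, alpha, kind, weights, tol_scale, max_iter)
    source = scores.argmax()
    return (source, scores) if return_scores else source


def write_scores(scores: RankingScores, path) -> None:
    """Export as two-column CSV: node_id,score."""
    with open(path, "w") as fh:
        fh.write("node_id,score\n")
        for i, v in enumerate(scores.f):
            fh.write(f"{i},{v:.10g}\n")
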