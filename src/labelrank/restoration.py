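"""Semi-supervised restoration of the full network status from a snapshot.

Stage one of the two-stage identifier: given a partial observation, infer
every node's infected/uninfected status by graph-based semi-supervised
binary classification. The soft-label matrix F is n x 2 — column 0 scores
the uninfected class, column 1 the infected class — initialised from the
one-hot matrix Y (observed nodes one-hot, unobserved nodes zero rows) and
iterated to a fixed point; the restored status of node i is the argmax of
row i.

Two classical propagation schemes are provided:

* GFHF (Gaussian fields / harmonic functions): F <- P F with P = D^(-1) W,
  re-clamping observed rows to Y after every sweep. The hard clamp means
  observed nodes keep their reported status exactly; unobserved scores are
  harmonic (neighbour averages), hence each row stays a convex combination
  of the observed one-hot rows.
* LGC (local and global consistency): F <- alpha * S F + (1 - alpha) * Y
  with the symmetric normalisation S and no clamping, so the restoration
  can override a reported status — which is what makes it tolerant to
  observation noise.

Restoring from a snapshot with only one observed class is refused: every
unlabelled node would trivially collapse onto that class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epidemic import Observation, ObservationMode, ObservedState
from .exceptions import DegenerateLabelsError, InfeasibleObservationError
from .graphs import ContactNetwork
from .ranking import DEFAULT_MAX_ITER, DEFAULT_TOL_SCALE, MatrixKind, build_matrix

__all__ = ["SoftLabels", "one_hot_matrix", "gfhf", "lgc", "gfhf_soft", "lgc_soft"]

#: column indices of the soft-label matrix
COL_UNINFECTED, COL_INFECTED = 0, 1


@dataclass(frozen=True)
class SoftLabels:
    """Converged n x 2 class-score matrix with iteration provenance."""

    F: np.ndarray
    iterations: int
    converged: bool


def one_hot_matrix(obs: Observation) -> np.ndarray:
    """Initial state matrix Y: uninfected -> (1,0), infected -> (0,1),
    unknown -> (0,0)."""
    y = np.zeros((obs.n, 2), dtype=np.float64)
    y[obs.values == ObservedState.UNINFECTED, COL_UNINFECTED] = 1.0
    y[obs.values == ObservedState.INFECTED, COL_INFECTED] = 1.0
    return y


def _check_restorable(obs: Observation) -> None:
    has_inf = bool(np.any(obs.values == ObservedState.INFECTED))
    has_uninf = bool(np.any(obs.values == ObservedState.UNINFECTED))
    if not (has_inf or has_uninf):
        raise InfeasibleObservationError("empty observed set: nothing to restore from")
    if not (has_inf and has_uninf):
        raise DegenerateLabelsError(
            "restoration needs both observed classes; with one class every "
            "unlabelled node would collapse onto it"
        )


def _classify(
    F: np.ndarray, obs: Observation, clamp: bool, tie_break: str
) -> Observation:
    if tie_break not in ("uninfected", "infected"):
        raise ValueError(f"tie_break must be 'uninfected' or 'infected', got {tie_break!r}")
    if tie_break == "uninfected":
        infected = F[:, COL_INFECTED] > F[:, COL_UNINFECTED]
    else:
        infected = F[:, COL_INFECTED] >= F[:, COL_UNINFECTED]
    values = np.where(infected, ObservedState.INFECTED, ObservedState.UNINFECTED).astype(
        np.int8
    )
    if clamp:
        observed = obs.observed_mask()
        values[observed] = obs.values[observed]
    return Observation(values=values, mode=ObservationMode.COMPLETE)


def gfhf_soft(
    network: ContactNetwork,
    obs: Observation,
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SoftLabels:
    """Harmonic soft labels: iterate F <- P F, re-clamping observed rows.

    Stops when ``||F(k+1) - F(k)||_F <= tol_scale * n``.
    """
    _check_restorable(obs)
    p = build_matrix(network, MatrixKind.ROW)
    y = one_hot_matrix(obs)
    observed = obs.observed_mask()
    threshold = tol_scale * obs.n
    F = y.copy()
    for k in range(1, max_iter + 1):
        F_next = p @ F
        F_next[observed] = y[observed]
        delta = float(np.linalg.norm(F_next - F))
        F = F_next
        if delta <= threshold:
            return SoftLabels(F=F, iterations=k, converged=True)
    return SoftLabels(F=F, iterations=max_iter, converged=False)


def lgc_soft(
    network: ContactNetwork,
    obs: Observation,
    alpha: float = 0.5,
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SoftLabels:
    """Local-and-global-consistency soft labels (no clamping).

    Iterates ``F <- alpha * S F + (1 - alpha) * Y`` with the symmetric
    normalisation; converges to (1-alpha)(I - alpha*S)^(-1) Y column-wise.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    _check_restorable(obs)
    s = build_matrix(network, MatrixKind.SYM)
    y = one_hot_matrix(obs)
    threshold = tol_scale * obs.n
    F = y.copy()
    for k in range(1, max_iter + 1):
        F_next = alpha * (s @ F) + (1.0 - alpha) * y
        delta = float(np.linalg.norm(F_next - F))
        F = F_next
        if delta <= threshold:
            return SoftLabels(F=F, iterations=k, converged=True)
    return SoftLabels(F=F, iterations=max_iter, converged=False)


def gfhf(
    network: ContactNetwork,
    obs: Observation,
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
    tie_break: str = "uninfected",
) -> Observation:
    """Restore a complete observation via GFHF.

    Observed nodes keep their reported status exactly (hard clamp); an
    unobserved node with a tied soft label is classified by ``tie_break``
    (default uninfected — conservative for source candidacy).
    """
    soft = gfhf_soft(network, obs, tol_scale, max_iter)
    return _classify(soft.F, obs, clamp=True, tie_break=tie_break)


def lgc(
    network: ContactNetwork,
    obs: Observation,
    alpha: float = 0.5,
    tol_scale: float = DEFAULT_TOL_SCALE,
    max_iter: int = DEFAULT_MAX_ITER,
    tie_break: str = "uninfected",
) -> Observation:
    """Restore a complete observation via LGC (noise tolerant: observed
    nodes are classified from F like everyone else, not clamped)."""
    soft = lgc_soft(network, obs, alpha, tol_scale, max_iter)
    return _classify(soft.F, obs, clamp=False, tie_break=tie_break)
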