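"""Discrete-time SI/SIR propagation and observation construction.

The spread starts from a single source node infected at t = 0 while every
other node is susceptible. Updates are synchronous (generation based): at
each step, a susceptible node with j neighbours that entered the step
infectious becomes infected with probability 1 - (1 - beta)^j — each
infectious neighbour is an independent Bernoulli(beta) exposure — and,
under SIR, every node that entered the step infectious recovers with
probability gamma. A node infected within a step can neither transmit nor
recover until the next step, and R is absorbing.

The simulation stops at the first step where the ever-infected fraction
|I ∪ R| / n reaches ``stop_fraction`` — recovered nodes still count as
infected for this purpose, which is also how every observation below
exposes them (the SIR model is folded into SI by treating R as I).

Three observation regimes are produced from a finished outcome:

* complete — every node's infected/uninfected status is known;
* uniform snapshot — a uniformly sampled fraction r of nodes reveal their
  status, the rest are unknown (both statuses guaranteed present);
* infected-only snapshot — exactly the ever-infected nodes are reported,
  everything else is unknown (no uninfected labels at all).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .exceptions import InfeasibleObservationError, SimulationError
from .graphs import ContactNetwork

__all__ = [
    "NodeState",
    "ObservedState",
    "ObservationMode",
    "PropagationOutcome",
    "Observation",
    "simulate",
    "complete_observation",
    "snapshot_uniform",
    "snapshot_infected_only",
    "read_observation",
    "write_observation",
]


class NodeState(enum.IntEnum):
    S = 0
    I = 1
    R = 2


class ObservedState(enum.IntEnum):
    UNINFECTED = 0
    INFECTED = 1
    UNKNOWN = 2


class ObservationMode(enum.Enum):
    COMPLETE = "complete"
    SNAPSHOT_UNIFORM = "snapshot_uniform"
    SNAPSHOT_INFECTED_ONLY = "snapshot_infected_only"


@dataclass(frozen=True)
class PropagationOutcome:
    """Result of one simulated spread: per-node S/I/R plus provenance."""

    source: int
    states: np.ndarray  # int8 NodeState codes, length n
    steps: int
    model: str  # "SI" | "SIR"
    beta: float
    gamma: float

    def ever_infected(self) -> np.ndarray:
        """Boolean mask of nodes that are or were infected (I or R)."""
        return self.states != NodeState.S

    def infected_fraction(self) -> float:
        return float(self.ever_infected().mean())


@dataclass(frozen=True)
class Observation:
    """Per-node observed status; L = observed nodes, U = unknown nodes."""

    values: np.ndarray  # int8 ObservedState codes, length n
    mode: ObservationMode

    def __post_init__(self):
        if self.mode is ObservationMode.COMPLETE and np.any(
            self.values == ObservedState.UNKNOWN
        ):
            raise ValueError("a complete observation cannot contain UNKNOWN")

    @property
    def n(self) -> int:
        return len(self.values)

    def observed_mask(self) -> np.ndarray:
        return self.values != ObservedState.UNKNOWN

    def observed_set(self) -> np.ndarray:
        """The node ids of L in increasing order."""
        return np.flatnonzero(self.observed_mask())

    def unobserved_set(self) -> np.ndarray:
        return np.flatnonzero(~self.observed_mask())

    def infected_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.values == ObservedState.INFECTED)


def simulate(
    network: ContactNetwork,
    model: str,
    source: int,
    beta: float,
    gamma: float = 0.0,
    stop_fraction: float = 0.3,
    max_steps: int | None = None,
    seed=None,
) -> PropagationOutcome:
    """Run one synchronous SI/SIR spread until ``stop_fraction`` is reached.

    Raises :class:`SimulationError` (carrying the partial outcome) if the
    threshold is not reached within ``max_steps`` — e.g. beta = 0, or an
    SIR die-out where every infectious node recovers first.
    """
    model = model.upper()
    if model not in ("SI", "SIR"):
        raise ValueError(f"model must be 'SI' or 'SIR', got {model!r}")
    if not (0.0 <= beta <= 1.0 and 0.0 <= gamma <= 1.0):
        raise ValueError("beta and gamma must lie in [0, 1]")
    if not (0.0 < stop_fraction <= 1.0):
        raise ValueError(f"stop_fraction must be in (0, 1], got {stop_fraction}")
    network.validate_node(source)
    n = network.n
    if max_steps is None:
        max_steps = 10 * n
    rng = np.random.default_rng(seed)
    adj = network.adjacency()

    states = np.zeros(n, dtype=np.int8)
    states[source] = NodeState.I

    def outcome(steps):
        return PropagationOutcome(
            source=source,
            states=states.copy(),
            steps=steps,
            model=model,
            beta=beta,
            gamma=float(gamma) if model == "SIR" else 0.0,
        )

    for step in range(max_steps + 1):
        if (states != NodeState.S).sum() / n >= stop_fraction:
            return outcome(step)
        if step == max_steps:
            break
        infectious = (states == NodeState.I).astype(np.float64)
        if not infectious.any():
            raise SimulationError(
                f"die-out at step {step}: no infectious nodes left "
                f"({(states != NodeState.S).sum()}/{n} ever infected)",
                partial_outcome=outcome(step),
            )
        # j infectious neighbours -> infection prob 1 - (1-beta)^j
        exposures = adj @ infectious
        susceptible = states == NodeState.S
        p_infect = 1.0 - (1.0 - beta) ** exposures
        newly_infected = susceptible & (rng.random(n) < p_infect)
        if model == "SIR" and gamma > 0.0:
            recovering = (states == NodeState.I) & (rng.random(n) < gamma)
            states[recovering] = NodeState.R
        states[newly_infected] = NodeState.I
    raise SimulationError(
        f"stop fraction {stop_fraction} not reached within {max_steps} steps",
        partial_outcome=outcome(max_steps),
    )


def complete_observation(outcome: PropagationOutcome) -> Observation:
    """Full status report: I and R observed as infected, S as uninfected."""
    values = np.where(
        outcome.ever_infected(), ObservedState.INFECTED, ObservedState.UNINFECTED
    ).astype(np.int8)
    return Observation(values=values, mode=ObservationMode.COMPLETE)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def snapshot_uniform(
    outcome: PropagationOutcome, r: float, seed=None, max_attempts: int = 1000
) -> Observation:
    """Reveal a uniform sample of round(r*n) nodes; redraw until both
    statuses appear among the revealed nodes (guaranteed by construction)."""
    if not (0.0 < r <= 1.0):
        raise ValueError(f"snapshot fraction r must be in (0, 1], got {r}")
    full = complete_observation(outcome)
    n = len(full.values)
    size = min(_round_half_away(r * n), n)
    if size >= n:
        return full
    infected = full.values == ObservedState.INFECTED
    if infected.all() or not infected.any():
        raise InfeasibleObservationError(
            "snapshot with r < 1 needs both infected and uninfected nodes present"
        )
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        chosen = rng.choice(n, size=size, replace=False)
        if infected[chosen].any() and (~infected[chosen]).any():
            values = np.full(n, ObservedState.UNKNOWN, dtype=np.int8)
            values[chosen] = full.values[chosen]
            return Observation(values=values, mode=ObservationMode.SNAPSHOT_UNIFORM)
    raise InfeasibleObservationError(
        f"could not draw a two-status snapshot in {max_attempts} attempts"
    )


def snapshot_infected_only(outcome: PropagationOutcome) -> Observation:
    """Reveal exactly the ever-infected nodes (R included); the rest unknown."""
    ever = outcome.ever_infected()
    if not ever.any():
        raise InfeasibleObservationError("outcome has no infected nodes to observe")
    values = np.where(ever, ObservedState.INFECTED, ObservedState.UNKNOWN).astype(
        np.int8
    )
    return Observation(values=values, mode=ObservationMode.SNAPSHOT_INFECTED_ONLY)


def assert_infection_subgraph_connected(
    network: ContactNetwork, outcome: PropagationOutcome
) -> bool:
    """Check the single-source invariant: ever-infected nodes induce a
    connected subgraph containing the source."""
    ever = np.flatnonzero(outcome.ever_infected())
    if outcome.source not in ever:
        return False
    sub = network.graph.subgraph(ever.tolist())
    return nx.is_connected(sub)


_STATE_TO_CHAR = {
    ObservedState.UNINFECTED: "S",
    ObservedState.INFECTED: "I",
    ObservedState.UNKNOWN: "U",
}
_CHAR_TO_STATE = {v: k for k, v in _STATE_TO_CHAR.items()}


def write_observation(obs: Observation, path) -> None:
    """Two-column text format: ``node_id state`` with state in {I, S, U}."""
    with open(path, "w") as fh:
        fh.write(f"# mode: {obs.mode.value}\n")
        for i, code in enumerate(obs.values):
            fh.write(f"{i} {_STATE_TO_CHAR[ObservedState(code)]}\n")


def read_observation(path) -> Observation:
    mode = None
    entries: dict[int, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# mode:"):
                mode = ObservationMode(line.split(":", 1)[1].strip())
                continue
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2 or parts[1] not in _CHAR_TO_STATE:
                raise ValueError(f"{path}:{lineno}: expected 'node_id I|S|U'")
            entries[int(parts[0])] = int(_CHAR_TO_STATE[parts[1]])
    if not entries:
        raise ValueError(f"{path}: empty observation file")
    n = max(entries) + 1
    if sorted(entries) != list(range(n)):
        raise ValueError(f"{path}: node ids must cover 0..{n - 1} exactly")
    values = np.array([entries[i] for i in range(n)], dtype=np.int8)
    if mode is None:
        has_unknown = bool(np.any(values == ObservedState.UNKNOWN))
        mode = (
            ObservationMode.SNAPSHOT_UNIFORM if has_unknown else ObservationMode.COMPLETE
        )
    return Observation(values=values, mode=mode)
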