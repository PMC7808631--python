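"""Two-stage identification, evaluation metrics and the experiment harness.

The two-stage identifier (:func:`tssi`) handles a partial snapshot by first
restoring the full network status with GFHF or LGC (stage one) and then
running the basic label-ranking identifier on the restoration (stage two).

The harness (:func:`run_experiment`) reproduces the benchmark protocol:
per run a source is drawn uniformly, a spread is simulated until the
ever-infected fraction crosses the stop threshold, the configured
observation is built, the configured identifier is applied, and detection
and geodesic error are recorded; results are averaged over ``n_runs``
independent runs. Per-run random streams are derived deterministically
from the master seed keyed by (run index, attempt), so a report is
reproducible bit-for-bit and :func:`sweep` can share identical propagation
outcomes across the swept parameter values (paired comparison).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import f1_score

from . import epidemic, ranking, restoration
from .epidemic import Observation, ObservationMode, PropagationOutcome
from .exceptions import SimulationError, UndefinedMetricError
from .graphs import ContactNetwork, generate_ba, generate_er, generate_ws, geodesic_distance

__all__ = [
    "ExperimentConfig",
    "MetricsReport",
    "tssi",
    "detection_rate",
    "average_error_distance",
    "restoration_f1",
    "build_network",
    "run_experiment",
    "sweep",
]

METHODS = ("blrsi", "vlrsi", "tssi-gfhf", "tssi-lgc")
OBSERVATIONS = ("complete", "uniform", "infected_only")

#: attempts per run before giving up on die-outs
MAX_REDRAWS_PER_RUN = 100


def tssi(
    network: ContactNetwork,
    obs: Observation,
    method: str = "lgc",
    alpha1: float = 0.5,
    alpha2: float = 0.5,
    weights: ranking.LabelWeights = ranking.LabelWeights(),
    return_restored: bool = False,
):
    """Two-stage source identification from a snapshot.

    Stage one restores a complete observation (``method``: 'gfhf' or
    'lgc', the latter taking ``alpha1``); stage two runs the basic
    identifier on the restoration with ``alpha2``, default weights and the
    symmetric normalisation. ``return_restored=True`` additionally returns
    the stage-one observation for restoration-quality scoring.
    """
    method = method.lower()
    if method == "gfhf":
        restored = restoration.gfhf(network, obs)
    elif method == "lgc":
        restored = restoration.lgc(network, obs, alpha=alpha1)
    else:
        raise ValueError(f"unknown restoration method {method!r} (gfhf|lgc)")
    source = ranking.blrsi(network, restored, alpha=alpha2, weights=weights)
    return (source, restored) if return_restored else source


def detection_rate(inferred, truth) -> float:
    """Fraction of runs whose inferred source equals the true source."""
    inferred, truth = np.asarray(inferred), np.asarray(truth)
    if inferred.shape != truth.shape or inferred.size == 0:
        raise ValueError("inferred and truth must be equal-length, non-empty")
    return float(np.mean(inferred == truth))


def average_error_distance(network: ContactNetwork, inferred, truth) -> float:
    """Mean geodesic (hop) distance between inferred and true sources."""
    inferred, truth = np.asarray(inferred), np.asarray(truth)
    if inferred.shape != truth.shape or inferred.size == 0:
        raise ValueError("inferred and truth must be equal-length, non-empty")
    return float(
        np.mean([geodesic_distance(network, int(a), int(b)) for a, b in zip(inferred, truth)])
    )


def restoration_f1(
    restored: Observation, truth: PropagationOutcome, eval_set: str = "unobserved",
    observed_in: Observation | None = None,
) -> float:
    """F1 of the restored status against the simulation truth.

    Positive class is infected. ``eval_set`` is 'all' or 'unobserved'; the
    latter (default) needs the pre-restoration snapshot ``observed_in`` to
    know which nodes were revealed — observed nodes are excluded because a
    clamping restorer gets them right by construction.
    """
    if restored.mode is not ObservationMode.COMPLETE:
        raise ValueError("restored observation must be COMPLETE")
    true_inf = truth.ever_infected()
    pred_inf = restored.values == epidemic.ObservedState.INFECTED
    if eval_set == "unobserved":
        if observed_in is None:
            raise ValueError("eval_set='unobserved' requires observed_in")
        mask = ~observed_in.observed_mask()
    elif eval_set == "all":
        mask = np.ones(restored.n, dtype=bool)
    else:
        raise ValueError(f"eval_set must be 'all' or 'unobserved', got {eval_set!r}")
    if not true_inf[mask].any():
        raise UndefinedMetricError("no infected nodes in truth over the eval set")
    return float(f1_score(true_inf[mask], pred_inf[mask], zero_division=0.0))


@dataclass
class ExperimentConfig:
    """Full description of one Monte-Carlo benchmark experiment."""

    network: ContactNetwork | dict
    method: str = "blrsi"
    model: str = "SI"
    beta: float = 0.3
    gamma: float = 0.1
    stop_fraction: float = 0.3
    n_runs: int = 1000
    seed: int = 0
    alpha: float = 0.5  # ranking alpha (alpha2 for two-stage)
    alpha1: float = 0.5  # LGC restoration alpha (two-stage only)
    kind: ranking.MatrixKind = ranking.MatrixKind.SYM
    weights: ranking.LabelWeights = field(default_factory=ranking.LabelWeights)
    observation: str = "complete"
    r: float = 0.5  # snapshot fraction (uniform snapshots only)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.observation not in OBSERVATIONS:
            raise ValueError(
                f"observation must be one of {OBSERVATIONS}, got {self.observation!r}"
            )
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.method == "blrsi" and self.observation != "complete":
            raise ValueError("blrsi requires complete observation (use vlrsi/tssi-*)")
        if self.method.startswith("tssi") and self.observation != "uniform":
            raise ValueError("two-stage identifiers require a uniform snapshot")


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate benchmark result over the completed runs."""

    detection_rate: float
    average_error_distance: float
    error_histogram: dict[int, int]
    restoration_f1: float | None
    runs: int
    redraws: int
    wall_clock_seconds: float  # informational only
    warning: str | None = None

    def to_dict(self) -> dict:
        d = {
            "detection_rate": self.detection_rate,
            "average_error_distance": self.average_error_distance,
            "error_histogram": {str(k): v for k, v in sorted(self.error_histogram.items())},
            "restoration_f1": self.restoration_f1,
            "runs": self.runs,
            "redraws": self.redraws,
            "wall_clock_seconds": self.wall_clock_seconds,
        }
        if self.warning:
            d["warning"] = self.warning
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_network(spec: ContactNetwork | dict, seed: int = 0) -> ContactNetwork:
    """Materialise a network from a ContactNetwork or a generator spec dict.

    Spec dicts: ``{"family": "er", "n":, "m":}``, ``{"family": "ba", "n":,
    "m_attach":}``, ``{"family": "ws", "n":, "k":, "p_rewire":}`` or
    ``{"family": "edgelist", "path":}``.
    """
    if isinstance(spec, ContactNetwork):
        return spec
    family = spec["family"].lower()
    if family == "er":
        return generate_er(spec["n"], spec["m"], seed=spec.get("seed", seed))
    if family == "ba":
        return generate_ba(spec["n"], spec["m_attach"], seed=spec.get("seed", seed))
    if family == "ws":
        return generate_ws(
            spec["n"], spec["k"], spec.get("p_rewire", 0.2), seed=spec.get("seed", seed)
        )
    if family == "edgelist":
        from .graphs import read_edgelist

        return read_edgelist(spec["path"])
    raise ValueError(f"unknown network family {spec['family']!r}")


def _run_rngs(master_seed: int, run_index: int, attempt: int):
    """Independent (simulation, snapshot) streams for one run attempt."""
    seq = np.random.SeedSequence((int(master_seed), int(run_index), int(attempt)))
    sim_seq, snap_seq = seq.spawn(2)
    return np.random.default_rng(sim_seq), np.random.default_rng(snap_seq)


def _one_run(network: ContactNetwork, config: ExperimentConfig, run_index: int):
    """Simulate, observe and identify once; returns (true, inferred, f1|None, attempts)."""
    for attempt in range(MAX_REDRAWS_PER_RUN):
        sim_rng, snap_rng = _run_rngs(config.seed, run_index, attempt)
        source = int(sim_rng.integers(network.n))
        try:
            outcome = epidemic.simulate(
                network,
                config.model,
                source,
                beta=config.beta,
                gamma=config.gamma if config.model.upper() == "SIR" else 0.0,
                stop_fraction=config.stop_fraction,
                seed=sim_rng,
            )
        except SimulationError:
            continue  # die-out: redraw source and trajectory on the next substream
        if config.observation == "complete":
            obs = epidemic.complete_observation(outcome)
        elif config.observation == "uniform":
            obs = epidemic.snapshot_uniform(outcome, config.r, seed=snap_rng)
        else:
            obs = epidemic.snapshot_infected_only(outcome)

        f1 = None
        if config.method == "blrsi":
            inferred = ranking.blrsi(
                network, obs, alpha=config.alpha, kind=config.kind, weights=config.weights
            )
        elif config.method == "vlrsi":
            inferred = ranking.vlrsi(
                network, obs, alpha=config.alpha, kind=config.kind, weights=config.weights
            )
        else:
            inferred, restored = tssi(
                network,
                obs,
                method=config.method.split("-", 1)[1],
                alpha1=config.alpha1,
                alpha2=config.alpha,
                weights=config.weights,
                return_restored=True,
            )
            if (~obs.observed_mask()).any():
                try:
                    f1 = restoration_f1(restored, outcome, "unobserved", observed_in=obs)
                except UndefinedMetricError:
                    f1 = None  # no infected truth among the unobserved nodes
        return source, int(inferred), f1, attempt
    raise SimulationError(
        f"run {run_index}: no viable trajectory in {MAX_REDRAWS_PER_RUN} attempts"
    )


def run_experiment(config: ExperimentConfig) -> MetricsReport:
    """Execute the configured Monte-Carlo benchmark and aggregate metrics."""
    t0 = time.perf_counter()
    network = build_network(config.network, seed=config.seed)
    truths, inferreds, f1s = [], [], []
    redraws = 0
    for i in range(config.n_runs):
        true_source, inferred, f1, attempt = _one_run(network, config, i)
        truths.append(true_source)
        inferreds.append(inferred)
        redraws += attempt
        if f1 is not None:
            f1s.append(f1)
    distances = [geodesic_distance(network, a, b) for a, b in zip(inferreds, truths)]
    hist: dict[int, int] = {}
    for d in distances:
        hist[d] = hist.get(d, 0) + 1
    warning = None
    if redraws > 0.1 * config.n_runs:
        warning = f"high die-out redraw rate: {redraws} redraws over {config.n_runs} runs"
    return MetricsReport(
        detection_rate=detection_rate(inferreds, truths),
        average_error_distance=float(np.mean(distances)),
        error_histogram=hist,
        restoration_f1=float(np.mean(f1s)) if f1s else None,
        runs=config.n_runs,
        redraws=redraws,
        wall_clock_seconds=time.perf_counter() - t0,
        warning=warning,
    )


_SWEEPABLE = {"alpha": "alpha", "r": "r", "weights": "weights"}


def sweep(config: ExperimentConfig, parameter: str, values) -> list[MetricsReport]:
    """One report per value of the swept parameter, with paired per-run seeds.

    The master seed is shared across values, so every report sees the same
    propagation outcomes and differences isolate the parameter effect.
    """
    parameter = parameter.lower()
    if parameter not in _SWEEPABLE:
        raise ValueError(f"parameter must be one of {sorted(_SWEEPABLE)}, got {parameter!r}")
    if parameter == "r" and config.observation != "uniform":
        raise ValueError("r sweep only applies to uniform-snapshot experiments")
    reports = []
    for value in values:
        if parameter == "weights" and not isinstance(value, ranking.LabelWeights):
            value = ranking.LabelWeights(*value)
        cfg = replace(config, **{_SWEEPABLE[parameter]: value})
        reports.append(run_experiment(cfg))
    return reports
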