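"""Typed errors raised across the package."""

from __future__ import annotations


class LabelRankError(Exception):
    """Base class for all package errors."""


class GraphGenerationError(LabelRankError):
    """A synthetic generator could not produce a connected graph."""


class EdgeListFormatError(LabelRankError):
    """An edge-list file violates the two-integer-columns contract."""


class SimulationError(LabelRankError):
    """Propagation failed to reach the stop fraction within max_steps.

    Carries the partial outcome so callers can inspect the die-out.
    """

    def __init__(self, message: str, partial_outcome=None):
        super().__init__(message)
        self.partial_outcome = partial_outcome


class InfeasibleObservationError(LabelRankError):
    """The requested observation cannot be built from this outcome."""


class DegenerateLabelsError(LabelRankError):
    """Restoration refused: a single observed class would swallow all nodes."""


class UndefinedMetricError(LabelRankError):
    """A metric is undefined for the given inputs (e.g. F1 with no positives)."""
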