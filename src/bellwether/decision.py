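"""Allocate-or-wait decision rule for a multi-year survey budget.

At the start of each field season the observed bellwether detectability
``q`` is converted to the probability that the current year is the best
one left in the study window::

    p_best = F(q; alpha, beta) ** (y - 1)

where ``F`` is the calibrated beta CDF of annual detectability and
``y`` counts the remaining years *including* the current one.  In the
final year ``p_best`` is 1 by construction, so the budget is always
released.  The default rule allocates the entire remaining budget when
``p_best`` strictly exceeds a threshold (0.4); a two-threshold variant
releases only a fraction of the budget in an intermediate band.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .calibration import DetectabilityDistribution, beta_cdf

__all__ = [
    "DecisionState",
    "Decision",
    "SingleThresholdRule",
    "TwoThresholdRule",
    "p_best",
    "decide",
]

DEFAULT_THRESHOLD = 0.4


class Decision(Enum):
    ALLOCATE = "allocate"
    WAIT = "wait"


@dataclass(frozen=True)
class DecisionState:
    """Inputs to one annual decision.

    years_remaining counts the current year, so the last season of a
    study has ``years_remaining == 1``.
    """

    years_remaining: int
    observed_output: float
    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.years_remaining < 1:
            raise ValueError(f"years_remaining must be >= 1, got {self.years_remaining}")
        if not (0.0 <= self.observed_output <= 1.0):
            raise ValueError(
                f"observed_output must be in [0, 1], got {self.observed_output}"
            )
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


def p_best(dist: DetectabilityDistribution, state: DecisionState) -> float:
    """Probability that no remaining year beats the current one.

    Equals ``F(q)**(y-1)``: each of the ``y - 1`` future years
    independently draws its detectability from the calibrated beta, and
    all of them must fall below the currently observed ``q``.  Always 1
    in the final year.
    """
    return float(beta_cdf(dist, state.observed_output) ** (state.years_remaining - 1))


def decide(dist: DetectabilityDistribution, state: DecisionState) -> Decision:
    """ALLOCATE iff ``p_best`` strictly exceeds the state's threshold."""
    return (
        Decision.ALLOCATE
        if p_best(dist, state) > state.threshold
        else Decision.WAIT
    )


@dataclass(frozen=True)
class SingleThresholdRule:
    """All-or-nothing rule: release the full remaining budget when
    p_best > threshold, otherwise conduct no new surveys this year."""

    threshold: float = DEFAULT_THRESHOLD

    def allocation_fraction(self, pb: float) -> float:
        return 1.0 if pb > self.threshold else 0.0


@dataclass(frozen=True)
class TwoThresholdRule:
    """Partial-allocation variant: the full budget above ``upper``, a
    fixed ``fraction`` of it in the (lower, upper] band, nothing below.

    The band fraction is a free parameter; outcomes are insensitive to
    it in the campaign simulations, as they are to the threshold itself.
    """

    lower: float = 0.4
    upper: float = 0.5
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.lower < self.upper < 1.0):
            raise ValueError("need 0 < lower < upper < 1")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")

    def allocation_fraction(self, pb: float) -> float:
        if pb > self.upper:
            return 1.0
        if pb > self.lower:
            return self.fraction
        return 0.0
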