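"""Monte-Carlo simulation of multi-year survey campaigns.

A campaign has a fixed budget of single-visit pond surveys to spend
within a fixed horizon of years.  Annual detectability at each pond is a
weighted average of a *global* component g (one beta draw per year,
shared by every pond) and a *local* component l_i (an independent beta
draw per pond per year)::

    p_i = c * g + (1 - c) * l_i

with the correlation weight c in [0, 1].  When c = 1 every occupied
pond in a year shares the global detectability; when c = 0 ponds
fluctuate independently.

In the adaptive design, a handful of *bellwether* ponds — long-term
monitoring sites with known populations — are surveyed at the start of
each year (their cost is deducted from the budget) to observe the
year's detectability level q; the allocate-or-wait rule then either
releases the remaining budget into the current season or holds it for a
better year.  The non-adaptive comparison splits the budget equally
across the years.  Candidate ponds form an unbounded pool: every survey
visits a fresh pond, occupied with a fixed probability, and detection
is a single Bernoulli trial at that pond's p_i.

Two equivalent execution paths are provided.  :func:`simulate_campaign`
runs one replicate with explicit per-pond draws (the literal mechanics
above).  :func:`simulate_campaigns` and :func:`run_grid` vectorise over
replicates using an exact marginalisation: conditional on g, the
detection count in a block of b surveys is Binomial(b, occupancy *
(c*g + (1-c)*mu)) with mu the beta mean, because the local draws are
i.i.d. given g.  The two paths agree in distribution, not just in
expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import DetectabilityDistribution, beta_cdf
from .decision import DEFAULT_THRESHOLD, SingleThresholdRule, TwoThresholdRule

__all__ = [
    "CampaignConfig",
    "YearWorld",
    "CampaignResult",
    "CampaignEnsemble",
    "GridResult",
    "draw_year_world",
    "observe_bellwethers",
    "simulate_campaign",
    "simulate_campaigns",
    "run_grid",
    "DEFAULT_CORRELATIONS",
    "DEFAULT_BELLWETHER_COUNTS",
]

#: Grid axes used throughout: correlation 0 to 1 in steps of 0.05,
#: bellwether count 0 to 10.
DEFAULT_CORRELATIONS: np.ndarray = np.round(np.arange(0.0, 1.0001, 0.05), 2)
DEFAULT_BELLWETHER_COUNTS: np.ndarray = np.arange(0, 11)


@dataclass(frozen=True)
class CampaignConfig:
    """Parameters of one simulated survey campaign.

    Defaults are the reference scenario: 400 total surveys (bellwether
    visits included) over 5 years, 20% of candidate ponds occupied,
    decision threshold 0.4.
    """

    total_budget: int = 400
    horizon_years: int = 5
    occupancy: float = 0.2
    n_bellwether: int = 0
    correlation: float = 0.0
    threshold: float = DEFAULT_THRESHOLD
    reps: int = 10_000
    seed: int | None = None
    rule: SingleThresholdRule | TwoThresholdRule | None = None

    def __post_init__(self) -> None:
        if self.total_budget <= 0 or self.horizon_years <= 0:
            raise ValueError("total_budget and horizon_years must be positive")
        if self.n_bellwether < 0:
            raise ValueError("n_bellwether must be >= 0")
        for name in ("occupancy", "correlation"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.n_bellwether > 0 and self.total_budget <= self.n_bellwether * self.horizon_years:
            raise ValueError(
                "total_budget must exceed n_bellwether * horizon_years so the "
                "bellwether overhead cannot consume the whole budget"
            )

    def decision_rule(self) -> SingleThresholdRule | TwoThresholdRule:
        return self.rule if self.rule is not None else SingleThresholdRule(self.threshold)


@dataclass(frozen=True)
class YearWorld:
    """Realised detectability state of one simulated year."""

    global_component: float
    local_components: np.ndarray
    correlation: float
    detection_probs: np.ndarray  # c*g + (1-c)*l_i, one per pond


@dataclass(frozen=True)
class CampaignResult:
    """Outcome of a single campaign replicate."""

    detections: int
    surveys_used: int
    allocation_year: int | None  # 1-based year of full budget release


@dataclass(frozen=True)
class CampaignEnsemble:
    """Outcome arrays for a block of replicates of one configuration."""

    detections: np.ndarray
    surveys_used: np.ndarray
    allocation_year: np.ndarray  # 0 where the budget was never fully released
    config: CampaignConfig

    @property
    def mean(self) -> float:
        return float(self.detections.mean())

    @property
    def sd(self) -> float:
        return float(self.detections.std(ddof=1))

    @property
    def mc_se(self) -> float:
        """Monte-Carlo standard error of the mean detection count."""
        return self.sd / np.sqrt(len(self.detections))


@dataclass(frozen=True)
class GridResult:
    """Mean/sd detection counts over a correlation x bellwether grid.

    ``mean`` and ``sd`` are indexed [bellwether_count, correlation].
    """

    correlations: np.ndarray
    bellwether_counts: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    reps: int
    seed: int | None = None

    def __post_init__(self) -> None:
        shape = (len(self.bellwether_counts), len(self.correlations))
        if self.mean.shape != shape or self.sd.shape != shape:
            raise ValueError(f"grid arrays must have shape {shape}")

    def cell(self, n_bellwether: int, correlation: float) -> tuple[float, float]:
        i = int(np.flatnonzero(self.bellwether_counts == n_bellwether)[0])
        j = int(np.argmin(np.abs(self.correlations - correlation)))
        return float(self.mean[i, j]), float(self.sd[i, j])


def draw_year_world(
    dist: DetectabilityDistribution,
    n_ponds: int,
    correlation: float,
    rng: np.random.Generator,
) -> YearWorld:
    """Draw one year's global component and per-pond detectabilities."""
    if n_ponds < 0:
        raise ValueError("n_ponds must be >= 0")
    g = float(dist.sample(rng))
    local = dist.sample(rng, n_ponds)
    probs = correlation * g + (1.0 - correlation) * local
    return YearWorld(
        global_component=g,
        local_components=local,
        correlation=correlation,
        detection_probs=probs,
    )


def observe_bellwethers(
    world: YearWorld, n_bellwether: int, rng: np.random.Generator,
    dist: DetectabilityDistribution,
) -> float:
    """Mean realised detectability over ``n_bellwether`` monitoring ponds.

    Bellwether ponds are known-occupied and disjoint from the candidate
    pool; each receives its own local draw through the same global/local
    mixture as the survey ponds.  The survey cost (one visit per
    bellwether pond) is charged to the budget by the campaign loop, not
    here.
    """
    if n_bellwether < 1:
        raise ValueError("observe_bellwethers requires n_bellwether >= 1")
    local = dist.sample(rng, n_bellwether)
    vals = world.correlation * world.global_component + (1.0 - world.correlation) * local
    return float(np.mean(vals))


def _survey_block(
    world_g: float,
    n_surveys: int,
    config: CampaignConfig,
    dist: DetectabilityDistribution,
    rng: np.random.Generator,
) -> int:
    """Survey ``n_surveys`` fresh ponds in a year with global draw g."""
    if n_surveys <= 0:
        return 0
    occupied = rng.random(n_surveys) < config.occupancy
    n_occ = int(occupied.sum())
    local = dist.sample(rng, n_occ)
    p = config.correlation * world_g + (1.0 - config.correlation) * local
    return int((rng.random(n_occ) < p).sum())


def _yearly_split(total: int, years: int) -> np.ndarray:
    """Equal split with the remainder assigned to the earliest years."""
    per = np.full(years, total // years, dtype=int)
    per[: total % years] += 1
    return per


def simulate_campaign(
    config: CampaignConfig,
    dist: DetectabilityDistribution,
    rng: np.random.Generator,
) -> CampaignResult:
    """Run a single campaign replicate with explicit per-pond draws.

    Adaptive path (``n_bellwether >= 1``): each year costs the
    bellwether overhead, observes q, and applies the decision rule;
    a full allocation spends the whole remaining budget that year and
    ends the campaign, and the final year always releases everything.
    Non-adaptive path (``n_bellwether == 0``): the budget is split
    equally across the horizon.
    """
    nb = config.n_bellwether
    if nb == 0:
        detections = 0
        for n_year in _yearly_split(config.total_budget, config.horizon_years):
            world = draw_year_world(dist, 0, config.correlation, rng)
            detections += _survey_block(
                world.global_component, int(n_year), config, dist, rng
            )
        return CampaignResult(
            detections=detections,
            surveys_used=config.total_budget,
            allocation_year=None,
        )

    rule = config.decision_rule()
    remaining = config.total_budget
    detections = 0
    allocation_year: int | None = None
    for year in range(1, config.horizon_years + 1):
        years_left = config.horizon_years - year + 1
        cost = min(nb, remaining)
        remaining -= cost
        if remaining == 0:
            warnings.warn(
                "budget exhausted by bellwether surveys before allocation",
                stacklevel=2,
            )
            break
        world = draw_year_world(dist, 0, config.correlation, rng)
        q = observe_bellwethers(world, nb, rng, dist)
        if years_left == 1:
            frac = 1.0
        else:
            pb = beta_cdf(dist, q) ** (years_left - 1)
            frac = rule.allocation_fraction(pb)
        n_surveys = int(np.floor(frac * remaining))
        detections += _survey_block(
            world.global_component, n_surveys, config, dist, rng
        )
        remaining -= n_surveys
        if frac >= 1.0:
            allocation_year = year
            break
    return CampaignResult(
        detections=detections,
        surveys_used=config.total_budget - remaining,
        allocation_year=allocation_year,
    )


def _allocation_fractions(
    rule: SingleThresholdRule | TwoThresholdRule, pb: np.ndarray
) -> np.ndarray:
    if isinstance(rule, SingleThresholdRule):
        return (pb > rule.threshold).astype(float)
    return np.select(
        [pb > rule.upper, pb > rule.lower], [1.0, rule.fraction], default=0.0
    )


def simulate_campaigns(
    config: CampaignConfig,
    dist: DetectabilityDistribution,
    rng: np.random.Generator | None = None,
) -> CampaignEnsemble:
    """Run ``config.reps`` replicates, vectorised over replicates.

    Uses the exact conditional-binomial form of the detection count
    (see module docstring); per-replicate outcomes are exchangeable
    with those of :func:`simulate_campaign`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    reps = config.reps
    mu = dist.mean
    c = config.correlation
    occ = config.occupancy
    nb = config.n_bellwether

    detections = np.zeros(reps, dtype=np.int64)

    if nb == 0:
        for n_year in _yearly_split(config.total_budget, config.horizon_years):
            g = dist.sample(rng, reps)
            detections += rng.binomial(int(n_year), occ * (c * g + (1 - c) * mu))
        return CampaignEnsemble(
            detections=detections,
            surveys_used=np.full(reps, config.total_budget, dtype=np.int64),
            allocation_year=np.zeros(reps, dtype=np.int64),
            config=config,
        )

    rule = config.decision_rule()
    remaining = np.full(reps, config.total_budget, dtype=np.int64)
    allocation_year = np.zeros(reps, dtype=np.int64)
    active = np.ones(reps, dtype=bool)
    for year in range(1, config.horizon_years + 1):
        years_left = config.horizon_years - year + 1
        remaining[active] -= np.minimum(nb, remaining[active])
        g = dist.sample(rng, reps)
        local = dist.sample(rng, (reps, nb))
        q = (c * g[:, None] + (1 - c) * local).mean(axis=1)
        if years_left == 1:
            frac = np.ones(reps)
        else:
            pb = beta_cdf(dist, q) ** (years_left - 1)
            frac = _allocation_fractions(rule, pb)
        n_surveys = np.where(active, np.floor(frac * remaining).astype(np.int64), 0)
        detections += rng.binomial(n_surveys, occ * (c * g + (1 - c) * mu))
        remaining -= n_surveys
        full = active & (frac >= 1.0)
        allocation_year[full] = year
        active &= ~full
        active &= remaining > 0
        if not active.any():
            break
    return CampaignEnsemble(
        detections=detections,
        surveys_used=config.total_budget - remaining,
        allocation_year=allocation_year,
        config=config,
    )


def run_grid(
    config_template: CampaignConfig,
    dist: DetectabilityDistribution,
    correlations: Sequence[float] | None = None,
    bellwether_counts: Sequence[int] | None = None,
    seed: int | None = None,
) -> GridResult:
    """Sweep the correlation x bellwether grid of campaign simulations.

    Each cell runs ``config_template.reps`` replicates on its own
    deterministic RNG substream (spawned from ``seed``), so the grid is
    reproducible and cells are statistically independent.
    """
    correlations = (
        DEFAULT_CORRELATIONS if correlations is None else np.asarray(correlations, float)
    )
    bellwether_counts = (
        DEFAULT_BELLWETHER_COUNTS
        if bellwether_counts is None
        else np.asarray(bellwether_counts, int)
    )
    if len(correlations) == 0 or len(bellwether_counts) == 0:
        raise ValueError("axis lists must be non-empty")
    if seed is None:
        seed = config_template.seed

    mean = np.empty((len(bellwether_counts), len(correlations)))
    sd = np.empty_like(mean)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(mean.size)
    k = 0
    for i, nb in enumerate(bellwether_counts):
        for j, corr in enumerate(correlations):
            cfg = replace(
                config_template, n_bellwether=int(nb), correlation=float(corr)
            )
            ens = simulate_campaigns(cfg, dist, np.random.default_rng(streams[k]))
            mean[i, j] = ens.mean
            sd[i, j] = ens.sd
            k += 1
    return GridResult(
        correlations=np.asarray(correlations, float),
        bellwether_counts=np.asarray(bellwether_counts, int),
        mean=mean,
        sd=sd,
        reps=config_template.reps,
        seed=seed,
    )
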