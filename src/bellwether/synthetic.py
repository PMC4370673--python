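"""Synthetic field-survey and monitoring-series generators.

These generators emulate the structure of a two-year larval survey
study: 32 ponds, each visited once per seasonal window (early / middle
/ late spring) in each of two years with one of three methods (daytime
visual scan, dipnet sweep, nocturnal visual scan), surveys capped at 30
minutes and right-censored when nothing is found.  Method order within
a pond is random but balanced so each method appears (near-)equally
often in each window, and a pond keeps the same order in both years.

Time to detection is drawn from a Weibull accelerated failure time
model with multiplicative factors per covariate level, and a
configurable fraction of ponds is *never detectable* (always censored)
— mimicking sites whose historic population records are wrong or whose
populations have gone extinct.  A sidecar of true parameters is kept so
recovery tests can check the analysis stack end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DetectabilityDistribution

__all__ = [
    "StudyDesign",
    "GeneratorParams",
    "FIELDLIKE_PARAMS",
    "generate_field_surveys",
    "generate_bellwether_history",
]


@dataclass(frozen=True)
class StudyDesign:
    """Balanced survey layout: ponds x years x windows, one method per
    pond-window with the balancing constraint described above."""

    n_ponds: int = 32
    years: tuple[int, ...] = (2009, 2010)
    windows: tuple[str, ...] = ("early", "middle", "late")
    methods: tuple[str, ...] = ("day_visual", "dipnet", "night_visual")
    observers: tuple[str, ...] = ("obs_a", "obs_b")
    censor_minutes: float = 30.0

    @property
    def n_records(self) -> int:
        return self.n_ponds * len(self.years) * len(self.windows)


@dataclass(frozen=True)
class GeneratorParams:
    """True accelerated-failure-time parameters of the generator.

    ``baseline_mean_ttd`` is the Weibull mean (minutes) in the
    reference cell (first level of every covariate); the ``*_factors``
    multiply the time scale for the other levels, so a factor of 2
    means detection takes twice as long.  ``shape`` is the Weibull
    shape k (AFT scale sigma = 1/k).  ``frac_never_detectable`` ponds
    produce only censored records regardless of covariates.
    """

    baseline_mean_ttd: float = 14.0
    year_factors: dict = field(default_factory=lambda: {"2009": 2.8, "2010": 1.0})
    method_factors: dict = field(
        default_factory=lambda: {"day_visual": 1.7, "dipnet": 1.4, "night_visual": 1.0}
    )
    window_factors: dict = field(
        default_factory=lambda: {"early": 1.3, "middle": 1.0, "late": 1.35}
    )
    observer_factors: dict = field(
        default_factory=lambda: {"obs_a": 1.0, "obs_b": 1.0}
    )
    shape: float = 1.1
    frac_never_detectable: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_mean_ttd <= 0 or self.shape <= 0:
            raise ValueError("baseline_mean_ttd and shape must be positive")
        if not (0.0 <= self.frac_never_detectable < 1.0):
            raise ValueError("frac_never_detectable must be in [0, 1)")
        for fac in (self.year_factors, self.method_factors,
                    self.window_factors, self.observer_factors):
            if any(v <= 0 for v in fac.values()):
                raise ValueError("all acceleration factors must be positive")


#: Synthetic preset whose qualitative behaviour resembles the study it
#: emulates (year effect much larger than method effect, roughly half
#: the ponds never detectable).  Entirely synthetic — not field data.
FIELDLIKE_PARAMS = GeneratorParams(
    baseline_mean_ttd=9.0,
    year_factors={"2009": 2.8, "2010": 1.0},
    method_factors={"day_visual": 1.7, "dipnet": 1.4, "night_visual": 1.0},
    window_factors={"early": 1.3, "middle": 1.0, "late": 1.35},
    observer_factors={"obs_a": 1.0, "obs_b": 1.0},
    shape=1.1,
    frac_never_detectable=0.47,
)


def _balanced_method_orders(design: StudyDesign, rng: np.random.Generator) -> list[tuple]:
    """Assign each pond a permutation of the methods, the six possible
    orders spread in near-equal counts (32 ponds -> counts 5 or 6) so
    each method appears near-equally often in each window."""
    perms = list(itertools.permutations(design.methods))
    base, extra = divmod(design.n_ponds, len(perms))
    counts = np.full(len(perms), base, dtype=int)
    counts[rng.choice(len(perms), size=extra, replace=False)] += 1
    orders = [p for p, c in zip(perms, counts) for _ in range(c)]
    rng.shuffle(orders)
    return orders


def generate_field_surveys(
    design: StudyDesign | None = None,
    params: GeneratorParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate one synthetic survey table in the canonical schema.

    Returns a DataFrame with columns ``pond, year, window, method,
    observer, time_min, detected`` and ``design.n_records`` rows.
    Detection times follow the Weibull AFT model in ``params``; times
    exceeding the 30-minute cap are emitted censored at the cap, and
    never-detectable ponds are always censored.
    """
    design = design or StudyDesign()
    params = params or GeneratorParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)

    orders = _balanced_method_orders(design, rng)
    n_never = int(round(params.frac_never_detectable * design.n_ponds))
    never = set(rng.choice(design.n_ponds, size=n_never, replace=False).tolist())

    sigma = 1.0 / params.shape
    # mean of Weibull with scale lam, shape k is lam * Gamma(1 + 1/k)
    from scipy.special import gamma as _gamma

    lam0 = params.baseline_mean_ttd / _gamma(1.0 + sigma)

    rows = []
    for pond in range(design.n_ponds):
        pond_id = f"pond_{pond + 1:02d}"
        observers = rng.choice(design.observers, size=len(design.years) * len(design.windows))
        k = 0
        for year in design.years:
            for w, window in enumerate(design.windows):
                method = orders[pond][w]
                obs = str(observers[k])
                k += 1
                if pond in never:
                    t, det = design.censor_minutes, False
                else:
                    lam = (
                        lam0
                        * params.year_factors[str(year)]
                        * params.method_factors[method]
                        * params.window_factors[window]
                        * params.observer_factors[obs]
                    )
                    # log T = log lam + sigma * Gumbel-min
                    t = float(lam * rng.weibull(params.shape))
                    det = t <= design.censor_minutes
                    if not det:
                        t = design.censor_minutes
                rows.append(
                    {
                        "pond": pond_id,
                        "year": year,
                        "window": window,
                        "method": method,
                        "observer": obs,
                        "time_min": round(max(t, 1e-3), 3),
                        "detected": det,
                    }
                )
    return pd.DataFrame(rows)


def true_log_acceleration(params: GeneratorParams) -> dict[str, float]:
    """Treatment-coded true log-acceleration coefficients implied by
    ``params`` (for parameter-recovery tests)."""
    out = {}
    for var, fac in (
        ("year", params.year_factors),
        ("method", params.method_factors),
        ("window", params.window_factors),
        ("observer", params.observer_factors),
    ):
        levels = list(fac)
        ref = fac[levels[0]]
        for lv in levels[1:]:
            out[f"{var}[{lv}]"] = float(np.log(fac[lv] / ref))
    return out


def generate_bellwether_history(
    dist: DetectabilityDistribution,
    n_years: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate an annual detectability series at a monitoring site.

    Independent draws from ``dist``, one per year — a stand-in for a
    long-term larval monitoring series from which percentile anchors
    could be read off.  Returns a DataFrame with ``year`` (1-based
    index) and ``detectability`` columns.
    """
    if n_years < 2:
        raise ValueError("n_years must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    vals = dist.sample(rng, n_years)
    return pd.DataFrame({"year": np.arange(1, n_years + 1), "detectability": vals})
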