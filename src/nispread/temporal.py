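"""Year-gap (delta-of-momenta) statistics and cumulative spread curves.

For each species i and momentum step x ≥ 1 the temporal delta
Δt_x − t_(x−1) is the year gap between two consecutive first records.
Pooled over species, each step yields a sample of non-negative integer
gaps; its empirical CDF median summarizes the typical time a species needs
to advance one step. Running sums of the per-step medians give the
cumulative curve — the inferred time from basin entry through momentum t_k.

Two scenarios are supported: (1) all species' cases, and (2) only cases
falling inside the dominant (>50% cumulative share) hotspot countries of
each momentum. The per-step percentage deviation between the scenarios'
medians quantifies how much the dominant subset distorts the timing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .momentum import MomentumSeries

Scenario = Literal["all", "dominant"]


class EmptyDistributionError(ValueError):
    """No species contributes a year gap at the requested step."""

    def __init__(self, step_index: int):
        super().__init__(f"no species possesses momenta {step_index - 1} and {step_index}")
        self.step_index = step_index


@dataclass(frozen=True)
class DeltaDistribution:
    """The pooled sample of year gaps at one momentum transition.

    ``step`` is the 1-based transition index (1 ↔ Δt₁–t₀). ``values`` keeps
    one entry per contributing species; ``low_n`` flags single-observation
    steps whose median is the lone value itself.
    """

    step: int
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise EmptyDistributionError(self.step)
        if any(v < 0 for v in self.values):
            raise ValueError(f"negative year gap at step {self.step}")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def low_n(self) -> bool:
        return self.n < 2

    @property
    def label(self) -> str:
        return f"dt{self.step}-t{self.step - 1}"

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def ecdf(self) -> Callable[[float], float]:
        return ecdf_median(self.values)[0]


def ecdf_median(values: Sequence[float]) -> tuple[Callable[[float], float], float]:
    """Empirical CDF of a sample plus its median.

    The eCDF is the usual right-continuous step function
    F(x) = (#values ≤ x)/n, evaluated through :func:`scipy.stats.ecdf`.
    The median is the standard sample median (midpoint of the two central
    order statistics for even n, hence possibly fractional).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("ecdf_median requires at least one value")
    cdf = stats.ecdf(arr).cdf

    def F(x: float) -> float:
        return float(cdf.evaluate(np.asarray(x, dtype=float)))

    return F, float(np.median(arr))


def step_deltas(
    all_series: Sequence[MomentumSeries],
    step_index: int,
    species_filter: Optional[set[str]] = None,
) -> DeltaDistribution:
    """Pool the year gaps Δt_step − t_(step−1) over species.

    Every species possessing both momenta contributes one gap; an optional
    ``species_filter`` (e.g. the dominant-hotspot subset of scenario 2)
    restricts the pool. Gaps of zero — two first records in the same year —
    are legal contributions.
    """
    if step_index < 1:
        raise ValueError("step_index must be ≥ 1")
    gaps = []
    for series in all_series:
        if species_filter is not None and series.species not in species_filter:
            continue
        if len(series.steps) > step_index:
            gaps.append(series.year_at(step_index) - series.year_at(step_index - 1))
    return DeltaDistribution(step=step_index, values=tuple(gaps))


@dataclass(frozen=True)
class CumulativeCurve:
    """Per-step eCDF medians and their running sum, for one scenario.

    ``step_medians[k]`` is the median gap of transition k+1 (Δt_(k+1)–t_k);
    ``cumulative[k]`` the summed medians through that transition, i.e. the
    inferred years from entry (t_0) to momentum t_(k+1). ``ns`` records the
    per-step sample sizes and ``low_n`` flags steps with a single
    observation.
    """

    scenario: Scenario
    step_medians: tuple[float, ...]
    ns: tuple[int, ...]

    @property
    def cumulative(self) -> tuple[float, ...]:
        return tuple(np.cumsum(self.step_medians))

    @property
    def low_n(self) -> tuple[bool, ...]:
        return tuple(n < 2 for n in self.ns)

    @property
    def n_steps(self) -> int:
        return len(self.step_medians)

    def inferred_years_at(self, momentum_index: int) -> float:
        """Cumulative median years from entry through momentum t_index."""
        if not (1 <= momentum_index <= self.n_steps):
            raise IndexError(
                f"momentum {momentum_index} beyond curve (covers t_1..t_{self.n_steps})"
            )
        return self.cumulative[momentum_index - 1]

    @property
    def mean_step_after_first(self) -> float:
        """Average per-step median excluding the (largest) first transition."""
        if self.n_steps < 2:
            raise ValueError("curve has no steps beyond the first")
        return float(np.mean(self.step_medians[1:]))


def cumulative_median_curve(
    all_series: Sequence[MomentumSeries],
    scenario: Scenario = "all",
    step_filters: Optional[Mapping[int, set[str]]] = None,
    max_momentum: int = 10,
) -> CumulativeCurve:
    """Build the cumulative median spread curve over steps 1..max_momentum.

    ``step_filters`` maps each step index to the species subset allowed to
    contribute there (scenario 2); ``None`` means all species at every
    step. The curve stops at the last step that still has data.
    """
    medians, ns = [], []
    for step in range(1, max_momentum + 1):
        flt = step_filters.get(step) if step_filters is not None else None
        try:
            dist = step_deltas(all_series, step, species_filter=flt)
        except EmptyDistributionError:
            break
        medians.append(dist.median)
        ns.append(dist.n)
    if not medians:
        raise EmptyDistributionError(1)
    return CumulativeCurve(scenario=scenario, step_medians=tuple(medians), ns=tuple(ns))


@dataclass(frozen=True)
class DeviationEntry:
    step: int
    deviation_pct: Optional[float]  # None when the reference median is 0 but the other is not

    @property
    def undefined(self) -> bool:
        return self.deviation_pct is None


def scenario_deviation(
    curve_all: CumulativeCurve, curve_dom: CumulativeCurve
) -> list[DeviationEntry]:
    """Per-step percentage deviation of scenario (2) from scenario (1).

    deviation[k] = 100·|m₁ − m₂|/m₁ with the all-cases median m₁ as the
    reference. Both medians zero → 0%; reference zero alone → flagged
    undefined rather than infinite.
    """
    if curve_all.n_steps != curve_dom.n_steps:
        raise ValueError(
            f"curves cover different steps ({curve_all.n_steps} vs {curve_dom.n_steps})"
        )
    out = []
    for k, (m1, m2) in enumerate(zip(curve_all.step_medians, curve_dom.step_medians), start=1):
        if m1 == 0.0:
            out.append(DeviationEntry(step=k, deviation_pct=0.0 if m2 == 0.0 else None))
        else:
            out.append(DeviationEntry(step=k, deviation_pct=100.0 * abs(m1 - m2) / m1))
    return out
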