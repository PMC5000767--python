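"""Running (prefix) statistics and the windowed convergence rule.

A statistic (Boltzmann-weighted average or disproportionate effect) is
re-evaluated over growing prefixes of the ensemble in sampling order, and the
series is declared converged once the step-to-step changes stay strictly
below a threshold for a full window of consecutive iterations (default: 5%
over 5 iterations).  Requiring a full window of subsequent stability guards
against declaring convergence on a value that is merely passing through a
plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .core import (
    BarrierEnsemble,
    ThermalContext,
    boltzmann_weighted_average,
    disproportionate_effect,
)

STATISTICS = ("boltzmann_average", "disproportionate_effect")
#: Prefix length at which each statistic is first defined.
_FIRST_N = {"boltzmann_average": 1, "disproportionate_effect": 2}


@dataclass(frozen=True)
class ConvergenceRule:
    """Windowed small-change convergence criterion.

    Parameters
    ----------
    threshold
        Change bound, strictly positive.  Percent for the relative metric,
        statistic units for the absolute metric.
    window
        Number of consecutive iterations whose changes must all fall strictly
        below the threshold.
    change_metric
        ``"relative"`` — percent change of each prefix value against the
        previous value; ``"absolute"`` — plain difference.  The relative
        metric divides by ``max(|previous|, denominator_floor)`` so a
        near-zero statistic cannot blow the ratio up.
    count_from
        ``"window_end"`` (default) reports the conformation count at which
        the confirming window completes — i.e. the number of conformations
        actually needed to declare convergence.  ``"window_start"`` reports
        the first index whose estimate the window then confirms.
    """

    threshold: float = 5.0
    window: int = 5
    change_metric: str = "relative"
    denominator_floor: float = 1e-8
    count_from: str = "window_end"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be > 0, got {self.threshold!r}")
        if not (isinstance(self.window, int) and self.window >= 1):
            raise ValueError(f"window must be an integer >= 1, got {self.window!r}")
        if self.change_metric not in ("relative", "absolute"):
            raise ValueError(f"unknown change metric {self.change_metric!r}")
        if not self.denominator_floor > 0:
            raise ValueError("denominator_floor must be > 0")
        if self.count_from not in ("window_end", "window_start"):
            raise ValueError(f"unknown count_from {self.count_from!r}")


@dataclass(frozen=True)
class ConvergenceTrace:
    """Running evaluation of one statistic over ensemble prefixes.

    ``points[k]`` is ``(n, value)`` with the statistic over the first ``n``
    records in sampling order; ``changes`` holds ``(n, change)`` for each
    step after the first point and has exactly one fewer entry than
    ``points``.  ``converged_after`` is filled in by :func:`converged_after`.
    """

    statistic_name: str
    points: Tuple[Tuple[int, float], ...]
    changes: Tuple[Tuple[int, float], ...]
    converged_after: Optional[int] = None

    def __post_init__(self) -> None:
        if self.statistic_name not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic_name!r}")
        if len(self.changes) != len(self.points) - 1:
            raise ValueError("changes must have exactly one fewer entry than points")


def running_statistic(
    ensemble: BarrierEnsemble,
    statistic: str,
    thermal: ThermalContext | None = None,
    rule: ConvergenceRule | None = None,
) -> ConvergenceTrace:
    """Evaluate a statistic over every prefix of the ensemble.

    The Boltzmann average starts at n = 1; the disproportionate effect at
    n = 2 (its first defined prefix).  Changes follow the rule's metric
    (default: relative percent change against the previous value).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    rule = rule or ConvergenceRule()
    thermal = thermal or ThermalContext()
    first_n = _FIRST_N[statistic]
    if len(ensemble) < first_n:
        raise ValueError(
            f"{statistic} needs at least {first_n} records, got {len(ensemble)}"
        )
    stat = (
        boltzmann_weighted_average
        if statistic == "boltzmann_average"
        else disproportionate_effect
    )
    points: List[Tuple[int, float]] = []
    for n in range(first_n, len(ensemble) + 1):
        points.append((n, stat(ensemble.prefix(n), thermal)))
    changes: List[Tuple[int, float]] = []
    for (n_prev, v_prev), (n, v) in zip(points, points[1:]):
        if rule.change_metric == "relative":
            change = abs(v - v_prev) / max(abs(v_prev), rule.denominator_floor) * 100.0
        else:
            change = abs(v - v_prev)
        changes.append((n, change))
    return ConvergenceTrace(statistic, tuple(points), tuple(changes))


def converged_after(trace: ConvergenceTrace, rule: ConvergenceRule | None = None) -> Optional[int]:
    """Smallest conformation count at which the trace is converged, or None.

    Scans for the earliest point whose next ``window`` consecutive changes
    all fall strictly below the threshold.  With ``count_from="window_end"``
    the count returned is that of the conformation completing the window
    (the number that must actually be sampled); with ``"window_start"`` it
    is the index of the confirmed point itself.  A trace too short to host a
    full window yields None, never a guess.
    """
    rule = rule or ConvergenceRule()
    w = rule.window
    change_vals = [c for _, c in trace.changes]
    for i in range(len(trace.points)):
        block = change_vals[i : i + w]
        if len(block) < w:
            return None
        if all(c < rule.threshold for c in block):
            n_start = trace.points[i][0]
            return n_start + w if rule.count_from == "window_end" else n_start
    return None


def evaluated_trace(
    ensemble: BarrierEnsemble,
    statistic: str,
    rule: ConvergenceRule | None = None,
    thermal: ThermalContext | None = None,
) -> ConvergenceTrace:
    """Running trace with its ``converged_after`` field filled in."""
    rule = rule or ConvergenceRule()
    trace = running_statistic(ensemble, statistic, thermal, rule)
    return replace(trace, converged_after=converged_after(trace, rule))


def combined_converged_after(
    ensemble: BarrierEnsemble,
    rule: ConvergenceRule | None = None,
    thermal: ThermalContext | None = None,
) -> Optional[int]:
    """Conformation count satisfying both criteria, or None.

    Both the Boltzmann-average trace and the DE trace must individually
    converge; the combined count is the larger of the two (e.g. criteria
    converging at 13 and 18 conformations give 18).  None if either trace
    never settles within the ensemble.
    """
    if len(ensemble) < 2:
        raise ValueError("combined criterion needs at least 2 records")
    counts = []
    for statistic in STATISTICS:
        trace = running_statistic(ensemble, statistic, thermal, rule)
        c = converged_after(trace, rule)
        if c is None:
            return None
        counts.append(c)
    return max(counts)


def ordering_sensitivity(
    ensemble: BarrierEnsemble,
    rule: ConvergenceRule | None = None,
    thermal: ThermalContext | None = None,
    n_permutations: int = 100,
    seed: int = 0,
) -> Tuple[Optional[int], ...]:
    """Combined convergence counts over random re-orderings of the records.

    Quantifies how strongly the declared count depends on the arbitrary MD
    sampling order.  Bit-reproducible for a given seed; None entries mark
    permutations under which the criteria never fire.
    """
    if not (isinstance(n_permutations, int) and n_permutations >= 1):
        raise ValueError(f"n_permutations must be an integer >= 1, got {n_permutations!r}")
    rng = np.random.default_rng(seed)
    out: List[Optional[int]] = []
    for _ in range(n_permutations):
        order = rng.permutation(len(ensemble)).tolist()
        out.append(combined_converged_after(ensemble.reordered(order), rule, thermal))
    return tuple(out)
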