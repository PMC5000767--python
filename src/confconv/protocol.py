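"""Ranked small-QM → big-QM screening protocol and its cost accounting.

Big-QM-region barrier calculations are accurate but expensive; small-QM
barriers for the same conformations are cheap and roughly rank-correlated
with them.  The protocol exploits this: pre-screen every conformation at the
small QM region, sort conformations by the small-QM barrier from lowest to
highest, then evaluate big-QM barriers in that order — feeding the decisive
low-barrier conformations into the Boltzmann-weighted average first — until
both convergence criteria (average and disproportionate effect) are met.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import stats

from .convergence import ConvergenceRule, combined_converged_after
from .core import (
    BarrierEnsemble,
    BarrierRecord,
    QMRegion,
    ThermalContext,
    boltzmann_weighted_average,
    disproportionate_effect,
)


@dataclass(frozen=True)
class PairedRecord:
    """Small- and big-QM-region barriers for one conformation."""

    conformation_id: str
    barrier_small: float
    barrier_big: float
    sample_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.conformation_id:
            raise ValueError("conformation_id must be a nonempty string")
        for name, b in (("barrier_small", self.barrier_small), ("barrier_big", self.barrier_big)):
            if not (math.isfinite(b) and b > 0):
                raise ValueError(
                    f"invalid barrier: {name}={b!r} for conformation "
                    f"{self.conformation_id!r} (must be finite and > 0)"
                )


@dataclass(frozen=True)
class PairedEnsemble:
    """Conformation-matched small-QM and big-QM barrier series, in MD order."""

    system_label: str
    records: Tuple[PairedRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) == 0:
            raise ValueError("empty ensemble")
        ids = [r.conformation_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate conformation_id {dup!r} in paired ensemble")

    def __len__(self) -> int:
        return len(self.records)

    def side(self, qm_region: QMRegion) -> BarrierEnsemble:
        """One side of the pairing as a plain ensemble, MD order preserved."""
        records = tuple(
            BarrierRecord(
                r.conformation_id,
                r.barrier_small if qm_region is QMRegion.SMALL else r.barrier_big,
                r.sample_time,
            )
            for r in self.records
        )
        return BarrierEnsemble(self.system_label, qm_region, records)


@dataclass(frozen=True)
class CostModel:
    """Relative cost of a small-QM evaluation and the comparison baseline.

    ``relative_cost`` is the small:big cost ratio in (0, 1] (default 0.1 — a
    small-region calculation costing a tenth of a big-region one);
    ``baseline_big_evaluations`` is the number of big-QM evaluations the
    protocol is compared against (default: the full ensemble).
    """

    relative_cost: float = 0.1
    baseline_big_evaluations: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 < self.relative_cost <= 1):
            raise ValueError(
                f"relative_cost must be in (0, 1], got {self.relative_cost!r}"
            )
        if self.baseline_big_evaluations is not None and self.baseline_big_evaluations <= 0:
            raise ValueError("baseline_big_evaluations must be positive")


@dataclass(frozen=True)
class ProtocolResult:
    """Outcome of the ranked screening protocol.

    ``evaluation_order`` lists conformation ids in the order their big-QM
    barriers were (or would be) evaluated; ``n_big_evaluated`` is the number
    of big-QM evaluations performed; ``total_cost`` is expressed in big-QM
    evaluation equivalents.
    """

    evaluation_order: Tuple[str, ...]
    n_big_evaluated: int
    converged: bool
    final_boltzmann_average: float
    final_disproportionate_effect: Optional[float]
    total_cost: float
    savings: float


def rank_by_small(paired: PairedEnsemble) -> List[str]:
    """Conformation ids sorted by small-QM barrier, lowest first.

    The sort is stable: ties keep MD sampling order, so the ranking is
    deterministic.
    """
    order = sorted(range(len(paired)), key=lambda i: paired.records[i].barrier_small)
    return [paired.records[i].conformation_id for i in order]


def spearman_correlation(paired: PairedEnsemble) -> float:
    """Spearman rank correlation between small- and big-QM barriers.

    Rank rather than linear correlation, because the protocol only relies on
    the ordering of barriers being roughly preserved between QM-region sizes;
    ties get average ranks.
    """
    if len(paired) < 3:
        raise ValueError(f"correlation needs at least 3 pairs, got {len(paired)}")
    small = np.array([r.barrier_small for r in paired.records])
    big = np.array([r.barrier_big for r in paired.records])
    if np.ptp(small) == 0 or np.ptp(big) == 0:
        raise ValueError("undefined correlation: zero variance on one side")
    rho = stats.spearmanr(small, big).statistic
    return float(rho)


def pearson_correlation(paired: PairedEnsemble) -> float:
    """Linear (Pearson) correlation between the paired barriers."""
    if len(paired) < 3:
        raise ValueError(f"correlation needs at least 3 pairs, got {len(paired)}")
    small = np.array([r.barrier_small for r in paired.records])
    big = np.array([r.barrier_big for r in paired.records])
    if np.ptp(small) == 0 or np.ptp(big) == 0:
        raise ValueError("undefined correlation: zero variance on one side")
    return float(stats.pearsonr(small, big).statistic)


def cost_savings(
    cost: CostModel, n_small_prescreened: int, n_big_evaluated: int
) -> float:
    """Percent cost saved versus evaluating the baseline at the big QM region.

    ``100 * (baseline - (n_small * relative_cost + n_big)) / baseline``; may
    be negative when pre-screening plus evaluations exceed the baseline.
    """
    if n_small_prescreened < 0 or n_big_evaluated < 0:
        raise ValueError("counts must be >= 0")
    baseline = cost.baseline_big_evaluations
    if baseline is None or baseline <= 0:
        raise ValueError("baseline must be a positive evaluation count")
    spent = n_small_prescreened * cost.relative_cost + n_big_evaluated
    return 100.0 * (baseline - spent) / baseline


def run_protocol(
    paired: PairedEnsemble,
    rule: ConvergenceRule | None = None,
    thermal: ThermalContext | None = None,
    cost: CostModel | None = None,
) -> ProtocolResult:
    """Execute the ranked screening protocol on a paired ensemble.

    Big-QM barriers are consumed in ascending small-QM-barrier order; after
    each addition both convergence criteria are re-evaluated over the big
    barriers accumulated so far (this evaluation order, not MD order, is the
    only sequence that exists as evaluations accrue).  The protocol stops at
    the first count where the combined criterion fires; if it never does, all
    conformations are evaluated and ``converged`` is False, with the final
    averages equal to the full-set values.
    """
    rule = rule or ConvergenceRule()
    thermal = thermal or ThermalContext()
    cost = cost or CostModel()
    if cost.baseline_big_evaluations is None:
        cost = CostModel(cost.relative_cost, len(paired))

    order = rank_by_small(paired)
    by_id = {r.conformation_id: r for r in paired.records}
    ranked_records = tuple(
        BarrierRecord(cid, by_id[cid].barrier_big, by_id[cid].sample_time)
        for cid in order
    )

    n = len(paired)
    converged = False
    n_big = n
    # Re-check from scratch after each evaluation; the first success yields
    # the earliest count the full sequence would also report.
    for k in range(2, n + 1):
        prefix = BarrierEnsemble(paired.system_label, QMRegion.BIG, ranked_records[:k])
        c = combined_converged_after(prefix, rule, thermal)
        if c is not None:
            converged = True
            n_big = c
            break

    final_ens = BarrierEnsemble(paired.system_label, QMRegion.BIG, ranked_records[:n_big])
    final_avg = boltzmann_weighted_average(final_ens, thermal)
    final_de = disproportionate_effect(final_ens, thermal) if n_big >= 2 else None
    total_cost = n * cost.relative_cost + n_big
    savings = cost_savings(cost, n, n_big)
    return ProtocolResult(
        evaluation_order=tuple(order),
        n_big_evaluated=n_big,
        converged=converged,
        final_boltzmann_average=final_avg,
        final_disproportionate_effect=final_de,
        total_cost=total_cost,
        savings=savings,
    )
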