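"""Domain types and averaging statistics for conformational barrier ensembles.

The central quantity is the Boltzmann-weighted (exponential) average of
activation barriers obtained from adiabatic QM/MM calculations on multiple
MD-sampled enzyme conformations,

    dE = -RT * ln[(1/n) * sum_i exp(-dE_i / RT)],

which is dominated by the low-barrier conformations and therefore fluctuates
strongly while those are still under-sampled.  The companion diagnostic is the
*disproportionate effect* (DE): the percent rise of the Boltzmann-weighted
average when the single lowest-barrier conformation is removed.  A large DE
flags that one outlier conformation is carrying the average, i.e. that the
ensemble is not yet converged.

All energies are in kcal·mol⁻¹; temperatures in kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

#: Molar gas constant in kcal·mol⁻¹·K⁻¹.
DEFAULT_GAS_CONSTANT = 1.987204e-3
#: Standard laboratory temperature, kelvin.
DEFAULT_TEMPERATURE = 298.15


class QMRegion(str, Enum):
    """Which QM-region size a barrier series belongs to."""

    SMALL = "small"
    BIG = "big"


@dataclass(frozen=True)
class ThermalContext:
    """Temperature and gas constant entering the Boltzmann weights.

    Parameters
    ----------
    temperature
        Absolute temperature in kelvin; strictly positive and finite.
    gas_constant
        Gas constant in kcal·mol⁻¹·K⁻¹.
    """

    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = DEFAULT_GAS_CONSTANT

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(
                f"invalid thermal context: temperature must be finite and > 0, "
                f"got {self.temperature!r}"
            )
        if not (math.isfinite(self.gas_constant) and self.gas_constant > 0):
            raise ValueError(
                f"invalid thermal context: gas constant must be finite and > 0, "
                f"got {self.gas_constant!r}"
            )

    @property
    def rt(self) -> float:
        """Thermal energy R·T in kcal·mol⁻¹."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class BarrierRecord:
    """One conformation's activation barrier.

    Parameters
    ----------
    conformation_id
        Nonempty label identifying the MD snapshot.
    barrier
        Activation energy in kcal·mol⁻¹; finite and strictly positive (the
        DE statistic divides by an average barrier, so zero is disallowed).
    sample_time
        Optional trajectory time of the snapshot, nanoseconds, >= 0.
    """

    conformation_id: str
    barrier: float
    sample_time: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.conformation_id:
            raise ValueError("conformation_id must be a nonempty string")
        if not (math.isfinite(self.barrier) and self.barrier > 0):
            raise ValueError(
                f"invalid barrier: {self.barrier!r} for conformation "
                f"{self.conformation_id!r} (must be finite and > 0)"
            )
        if self.sample_time is not None and not (
            math.isfinite(self.sample_time) and self.sample_time >= 0
        ):
            raise ValueError(
                f"invalid sample_time {self.sample_time!r} for conformation "
                f"{self.conformation_id!r}"
            )


@dataclass(frozen=True)
class BarrierEnsemble:
    """Ordered series of barriers for one system and QM-region size.

    Record order is the MD sampling (chronological) order and is preserved
    by all I/O round-trips; the running convergence statistics depend on it.
    """

    system_label: str
    qm_region: QMRegion
    records: Tuple[BarrierRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if len(self.records) == 0:
            raise ValueError("empty ensemble")
        ids = [r.conformation_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate conformation_id {dup!r} in ensemble")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def barriers(self) -> np.ndarray:
        """Barriers as a float array, in sampling order."""
        return np.array([r.barrier for r in self.records], dtype=float)

    def prefix(self, n: int) -> "BarrierEnsemble":
        """The ensemble restricted to the first ``n`` records."""
        if not 1 <= n <= len(self.records):
            raise ValueError(f"prefix length {n} out of range 1..{len(self.records)}")
        return BarrierEnsemble(self.system_label, self.qm_region, self.records[:n])

    def without_index(self, index: int) -> "BarrierEnsemble":
        """The ensemble with the record at ``index`` removed."""
        recs = self.records[:index] + self.records[index + 1 :]
        return BarrierEnsemble(self.system_label, self.qm_region, recs)

    def reordered(self, order: Sequence[int]) -> "BarrierEnsemble":
        """The same records permuted by positional ``order``."""
        if sorted(order) != list(range(len(self.records))):
            raise ValueError("order must be a permutation of record positions")
        return BarrierEnsemble(
            self.system_label, self.qm_region, tuple(self.records[i] for i in order)
        )


def ensemble_from_barriers(
    barriers: Iterable[float],
    system_label: str = "ensemble",
    qm_region: QMRegion = QMRegion.SMALL,
    interval: Optional[float] = None,
) -> BarrierEnsemble:
    """Convenience constructor from bare barrier values.

    Ids are ``c01, c02, ...``; sample times are ``(i+1)*interval`` when an
    interval is given.
    """
    vals = list(barriers)
    width = max(2, len(str(len(vals))))
    records = tuple(
        BarrierRecord(
            conformation_id=f"c{i + 1:0{width}d}",
            barrier=b,
            sample_time=None if interval is None else (i + 1) * interval,
        )
        for i, b in enumerate(vals)
    )
    return BarrierEnsemble(system_label, qm_region, records)


def boltzmann_weighted_average(
    ensemble: BarrierEnsemble, thermal: ThermalContext | None = None
) -> float:
    """Boltzmann-weighted (exponential) average barrier, kcal·mol⁻¹.

    Computes ``-RT * ln[(1/n) * sum_i exp(-dE_i/RT)]`` via a log-sum-exp
    evaluation, which shifts by the minimum barrier before exponentiating so
    that barriers of several hundred kcal·mol⁻¹ do not underflow.  The result
    always lies between the minimum barrier and the arithmetic mean.
    """
    thermal = thermal or ThermalContext()
    b = ensemble.barriers
    rt = thermal.rt
    # logsumexp shifts by max(-b/rt), i.e. by the minimum barrier.
    return float(-rt * (logsumexp(-b / rt) - math.log(len(b))))


def arithmetic_average(ensemble: BarrierEnsemble) -> float:
    """Direct arithmetic mean of the barriers, kcal·mol⁻¹."""
    return float(np.mean(ensemble.barriers))


def min_barrier(ensemble: BarrierEnsemble) -> Tuple[str, float]:
    """The record with the smallest barrier; ties go to the earliest sample."""
    idx = int(np.argmin(ensemble.barriers))  # argmin returns the first minimum
    rec = ensemble.records[idx]
    return rec.conformation_id, rec.barrier


def disproportionate_effect(
    ensemble: BarrierEnsemble, thermal: ThermalContext | None = None
) -> float:
    """Disproportionate effect of the lowest-barrier conformation, percent.

    ``100 * (dE_without_lowest - dE_all) / dE_all`` where exactly one record
    holding the minimum barrier (the earliest, on ties) is dropped from the
    Boltzmann-weighted average.  Nonnegative for all valid inputs; large
    values indicate the average is dominated by a single outlier conformation
    and more sampling is needed.
    """
    if len(ensemble) < 2:
        raise ValueError("DE undefined for n < 2")
    thermal = thermal or ThermalContext()
    full = boltzmann_weighted_average(ensemble, thermal)
    idx = int(np.argmin(ensemble.barriers))
    reduced = boltzmann_weighted_average(ensemble.without_index(idx), thermal)
    return 100.0 * (reduced - full) / full
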