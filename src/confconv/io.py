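"""Delimited-text barrier tables and JSON/TSV reports.

Tables are header-first TSV/CSV with named columns — ``conformation_id`` and
``barrier`` for a single-region series, or ``conformation_id``,
``barrier_small`` and ``barrier_big`` for a conformation-matched pair; an
optional ``time_ns`` column carries snapshot times.  Column names rather than
positions are matched, so transcribed tables with extra columns load
unchanged.  Row order in the file is the MD sampling order and is preserved.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd

from .convergence import ConvergenceTrace
from .core import BarrierEnsemble, BarrierRecord, QMRegion
from .protocol import PairedEnsemble, PairedRecord, ProtocolResult

SINGLE_COLUMNS = ("conformation_id", "barrier")
PAIRED_COLUMNS = ("conformation_id", "barrier_small", "barrier_big")
TIME_COLUMN = "time_ns"


@dataclass(frozen=True)
class BarrierTableFormat:
    """Delimiter and schema expectations for a barrier table."""

    delimiter: str = "\t"

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise ValueError("delimiter must be a single character")


def _parse_float(raw: str, row: int, column: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValueError(
            f"unparsable numeric value {raw!r} at row {row}, column {column!r}"
        ) from None
    if not math.isfinite(value):
        raise ValueError(f"non-finite value {raw!r} at row {row}, column {column!r}")
    return value


def read_barriers(
    path: Union[str, Path],
    fmt: BarrierTableFormat | None = None,
    system_label: Optional[str] = None,
    qm_region: QMRegion = QMRegion.SMALL,
) -> Union[BarrierEnsemble, PairedEnsemble]:
    """Read a barrier table, auto-detecting the single or paired schema.

    Rows are returned in file order; duplicate conformation ids, missing
    columns, unparsable numerics and empty tables each raise a ValueError
    naming the offending row and column.
    """
    fmt = fmt or BarrierTableFormat()
    path = Path(path)
    df = pd.read_csv(path, sep=fmt.delimiter, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"empty table: {path}")
    cols = set(df.columns)
    label = system_label or path.stem
    if set(PAIRED_COLUMNS) <= cols:
        return _build_paired(df, label)
    if set(SINGLE_COLUMNS) <= cols:
        return _build_single(df, label, qm_region)
    missing_single = sorted(set(SINGLE_COLUMNS) - cols)
    missing_paired = sorted(set(PAIRED_COLUMNS) - cols)
    raise ValueError(
        f"unrecognised header {sorted(cols)}: needs columns {missing_single} for a "
        f"single-region table or {missing_paired} for a paired table"
    )


def _times(df: pd.DataFrame) -> List[Optional[float]]:
    if TIME_COLUMN not in df.columns:
        return [None] * len(df)
    return [
        _parse_float(v, row=i + 1, column=TIME_COLUMN) if v != "" else None
        for i, v in enumerate(df[TIME_COLUMN])
    ]


def _check_ids(ids: List[str]) -> None:
    seen: Dict[str, int] = {}
    for i, cid in enumerate(ids, start=1):
        if cid == "":
            raise ValueError(f"empty conformation_id at row {i}")
        if cid in seen:
            raise ValueError(
                f"duplicate conformation_id {cid!r} at rows {seen[cid]} and {i}"
            )
        seen[cid] = i


def _build_single(df: pd.DataFrame, label: str, qm_region: QMRegion) -> BarrierEnsemble:
    ids = list(df["conformation_id"])
    _check_ids(ids)
    times = _times(df)
    records = tuple(
        BarrierRecord(
            conformation_id=cid,
            barrier=_parse_float(raw, row=i + 1, column="barrier"),
            sample_time=times[i],
        )
        for i, (cid, raw) in enumerate(zip(ids, df["barrier"]))
    )
    return BarrierEnsemble(label, qm_region, records)


def _build_paired(df: pd.DataFrame, label: str) -> PairedEnsemble:
    ids = list(df["conformation_id"])
    _check_ids(ids)
    times = _times(df)
    records = tuple(
        PairedRecord(
            conformation_id=cid,
            barrier_small=_parse_float(s, row=i + 1, column="barrier_small"),
            barrier_big=_parse_float(b, row=i + 1, column="barrier_big"),
            sample_time=times[i],
        )
        for i, (cid, s, b) in enumerate(
            zip(ids, df["barrier_small"], df["barrier_big"])
        )
    )
    return PairedEnsemble(label, records)


def _fmt(value: Optional[float]) -> str:
    # repr of a float is the shortest digit string that round-trips exactly
    return "" if value is None else repr(float(value))


def write_barriers(
    ensemble: Union[BarrierEnsemble, PairedEnsemble],
    path: Union[str, Path],
    fmt: BarrierTableFormat | None = None,
) -> None:
    """Write an ensemble back to a delimited table, preserving row order."""
    fmt = fmt or BarrierTableFormat()
    path = Path(path)
    has_time = any(r.sample_time is not None for r in ensemble.records)
    if isinstance(ensemble, PairedEnsemble):
        header = list(PAIRED_COLUMNS)
        rows = [
            [r.conformation_id, _fmt(r.barrier_small), _fmt(r.barrier_big)]
            for r in ensemble.records
        ]
    else:
        header = list(SINGLE_COLUMNS)
        rows = [[r.conformation_id, _fmt(r.barrier)] for r in ensemble.records]
    if has_time:
        header.append(TIME_COLUMN)
        for row, rec in zip(rows, ensemble.records):
            row.append(_fmt(rec.sample_time))
    lines = [fmt.delimiter.join(header)]
    lines += [fmt.delimiter.join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def report_payload(result: object) -> dict:
    """Normalise a module result into a JSON-serialisable mapping.

    Convergence traces serialise their points, changes and converged_after
    (an explicit null when undecided); protocol results include the
    evaluation order, costs and savings.  Keys are stable across releases.
    """
    if isinstance(result, ConvergenceTrace):
        return {
            "kind": "convergence_trace",
            "statistic": result.statistic_name,
            "points": [{"n": n, "value": v} for n, v in result.points],
            "changes": [{"n": n, "change": c} for n, c in result.changes],
            "converged_after": result.converged_after,
        }
    if isinstance(result, ProtocolResult):
        return {
            "kind": "protocol_result",
            "evaluation_order": list(result.evaluation_order),
            "n_big_evaluated": result.n_big_evaluated,
            "converged": result.converged,
            "final_boltzmann_average": result.final_boltzmann_average,
            "final_disproportionate_effect": result.final_disproportionate_effect,
            "total_cost": result.total_cost,
            "savings": result.savings,
        }
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        return {"kind": type(result).__name__, **dataclasses.asdict(result)}
    if isinstance(result, dict):
        return result
    return {"value": result}


def _tsv_lines(payload: dict) -> List[str]:
    lines: List[str] = []
    tabular_key = None
    for key in ("points", "changes"):
        if key in payload:
            tabular_key = "points"
            break
    scalar = {
        k: v
        for k, v in payload.items()
        if not isinstance(v, (list, dict)) or k == "evaluation_order"
    }
    for k, v in scalar.items():
        if k == "evaluation_order":
            v = ",".join(v)
        lines.append(f"# {k}\t{v if v is not None else 'null'}")
    if tabular_key:
        changes = {n: c for n, c in ((d["n"], d["change"]) for d in payload["changes"])}
        lines.append("n\tvalue\tchange")
        for d in payload["points"]:
            chg = changes.get(d["n"])
            lines.append(
                f"{d['n']}\t{_fmt(d['value'])}\t{'' if chg is None else _fmt(chg)}"
            )
    return lines


def write_report(
    result: object, path: Union[str, Path], format: str = "json"
) -> None:
    """Serialise a result to ``path`` as JSON (default) or TSV.

    JSON output is byte-identical for identical inputs: key order is fixed by
    construction and floats use exact shortest-round-trip formatting.
    """
    payload = report_payload(result)
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "tsv":
        path.write_text("\n".join(_tsv_lines(payload)) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
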