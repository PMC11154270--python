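"""Benchmark error statistics against coupled-cluster reference energies.

Per (method, basis) cell: root-mean-square deviation, mean absolute error,
average signed error (method minus reference; positive means the method is
less attractive than the reference), and the largest percentage error
relative to the reference.  Errors can be stratified by interaction mode.
Also provides per-mode energy summaries and a Pareto front over
(accuracy, CPU cost) points for method selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .motifs import MotifError

__all__ = [
    "ErrorSummary",
    "ModeSummary",
    "CostPoint",
    "error_metrics",
    "stratified_errors",
    "mode_summary",
    "pareto_front",
    "round_half_up",
]

MODES = ("CH-pi", "pi-pi", "cation-pi", "H-bond", "salt-bridge")


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Printed-table rounding: halves go away from zero, not to even."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ErrorSummary:
    method_label: str
    basis_label: str
    stratum: str  # a mode name or "overall"
    rmsd: float
    mae: float
    avg: float
    max_pct: float
    n: int


@dataclass(frozen=True)
class ModeSummary:
    mode: str
    phase: str  # gas | dehydration | aqueous
    mean: float
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class CostPoint:
    method_label: str
    basis_label: str
    rmsd: float
    cpu_minutes: float

    def __post_init__(self):
        if self.cpu_minutes <= 0:
            raise MotifError("invalid-cost", "cpu_minutes must be > 0")


def error_metrics(calc, ref) -> tuple[float, float, float, float]:
    """(rmsd, mae, avg, max_pct) of calc against ref.

    avg is signed (calc - ref); max_pct is max |error| / |reference| * 100.
    """
    calc = np.asarray(calc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if calc.shape != ref.shape or calc.ndim != 1 or calc.size == 0:
        raise MotifError("shape-mismatch", f"{calc.shape} vs {ref.shape}")
    if np.any(ref == 0):
        raise MotifError("undefined-percentage", "reference value of exactly 0")
    err = calc - ref
    rmsd = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    avg = float(np.mean(err))
    max_pct = float(np.max(100.0 * np.abs(err) / np.abs(ref)))
    return rmsd, mae, avg, max_pct


def stratified_errors(
    table: pd.DataFrame,
    calc_col: str,
    ref_col: str = "reference",
    mode_col: str = "mode",
    method_label: str = "",
    basis_label: str = "",
) -> list[ErrorSummary]:
    """Per-mode error summaries plus an "overall" row over every motif."""
    unknown = set(table[mode_col]) - set(MODES)
    if unknown:
        raise MotifError("unknown-mode", str(sorted(unknown)))
    out = []
    for mode in MODES:
        sub = table[table[mode_col] == mode]
        if len(sub) == 0:
            continue
        rmsd, mae, avg, max_pct = error_metrics(sub[calc_col], sub[ref_col])
        out.append(
            ErrorSummary(method_label, basis_label, mode, rmsd, mae, avg, max_pct, len(sub))
        )
    rmsd, mae, avg, max_pct = error_metrics(table[calc_col], table[ref_col])
    out.append(
        ErrorSummary(method_label, basis_label, "overall", rmsd, mae, avg, max_pct, len(table))
    )
    return out


_PHASE_COLS = {"gas": "dE_gas", "dehydration": "dE_deh", "aqueous": "dE_aq"}


def mode_summary(reference_table: pd.DataFrame) -> list[ModeSummary]:
    """Mean/min/max interaction energy per mode and phase.

    Expects columns mode, dE_gas, dE_deh, dE_aq; means are rounded to one
    decimal for reporting parity with printed tables (raw min/max kept)."""
    out = []
    for mode in MODES:
        sub = reference_table[reference_table["mode"] == mode]
        if len(sub) == 0:
            continue
        for phase, col in _PHASE_COLS.items():
            vals = sub[col].to_numpy(dtype=float)
            out.append(
                ModeSummary(
                    mode=mode,
                    phase=phase,
                    mean=round_half_up(float(vals.mean()), 1),
                    min=float(vals.min()),
                    max=float(vals.max()),
                    n=len(vals),
                )
            )
    return out


def pareto_front(points: list[CostPoint]) -> list[CostPoint]:
    """Non-dominated subset in (rmsd, cpu_minutes), cheapest first.

    A point dominates another if it is <= in both coordinates and < in at
    least one."""
    if not points:
        raise MotifError("shape-mismatch", "need at least one point")
    front = []
    for p in points:
        dominated = any(
            (q.rmsd <= p.rmsd and q.cpu_minutes <= p.cpu_minutes)
            and (q.rmsd < p.rmsd or q.cpu_minutes < p.cpu_minutes)
            for q in points
        )
        if not dominated:
            front.append(p)
    # drop duplicates while preserving one representative
    seen = set()
    unique = []
    for p in sorted(front, key=lambda p: (p.cpu_minutes, p.rmsd)):
        key = (p.rmsd, p.cpu_minutes, p.method_label, p.basis_label)
        if key not in seen:
            seen.add(key)
            unique.append(p)
    return unique
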