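"""Complete-basis-set extrapolation and the composite coupled-cluster energy.

Correlation energies computed with correlation-consistent basis sets of
cardinal number X converge to the basis-set limit as X^-3.  The two-point
extrapolation

    E_lim = [X^3 E_X - (X-1)^3 E_{X-1}] / [X^3 - (X-1)^3]

annihilates the A X^-3 term exactly, so any series of the form
E(X) = E_inf + A X^-3 is extrapolated to E_inf identically.

The composite interaction energy combines an MP2/CBS value with a
small-basis "coupled cluster correction":

    dE_CCSD(T)/CBS = dE_MP2/CBS + (dE_CCSD(T) - dE_MP2) | small basis
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import MotifError

__all__ = [
    "CorrelationSeries",
    "CompositeComponents",
    "extrapolate_two_point",
    "mp2_cbs_total",
    "ccsdt_cbs",
]


@dataclass
class CorrelationSeries:
    """Correlation energies indexed by basis-set cardinal number."""

    entries: list[tuple[int, float]]  # (cardinal X >= 2, E_corr)
    label: str = "cc-pVXZ"

    def __post_init__(self):
        cards = [x for x, _ in self.entries]
        if any(x < 2 for x in cards):
            raise MotifError("invalid-cardinal", "cardinals must be >= 2")
        if cards != sorted(set(cards)):
            raise MotifError("invalid-cardinal", "cardinals must strictly increase")


@dataclass
class CompositeComponents:
    mp2_cbs: float  # kcal/mol (or any consistent unit)
    ccsdt_small: float
    mp2_small: float
    small_basis_label: str = "aug-cc-pVDZ"
    ccsdt_basis_label: str | None = None  # defaults to small_basis_label

    def __post_init__(self):
        if self.ccsdt_basis_label is None:
            self.ccsdt_basis_label = self.small_basis_label
        if self.ccsdt_basis_label != self.small_basis_label:
            raise MotifError(
                "basis-mismatch",
                f"{self.ccsdt_basis_label} != {self.small_basis_label}",
            )


def extrapolate_two_point(e_x: float, e_xm1: float, x: int) -> float:
    """Basis-set-limit correlation energy from cardinals X and X-1 (X >= 3)."""
    if x < 3:
        raise MotifError("invalid-cardinal", f"X={x}; need X >= 3")
    x3 = float(x) ** 3
    xm13 = float(x - 1) ** 3
    return (x3 * e_x - xm13 * e_xm1) / (x3 - xm13)


def extrapolate_series(series: CorrelationSeries) -> float:
    """Extrapolate from the two largest cardinals of a series."""
    if len(series.entries) < 2:
        raise MotifError("invalid-cardinal", "need at least two cardinals")
    (xm1, e_xm1), (x, e_x) = series.entries[-2], series.entries[-1]
    if x != xm1 + 1:
        raise MotifError("invalid-cardinal", "cardinals must be consecutive")
    return extrapolate_two_point(e_x, e_xm1, x)


def mp2_cbs_total(hf_large: float, corr_t: float, corr_q: float) -> float:
    """MP2/CBS total: unextrapolated HF at the larger basis plus the
    triple/quadruple-zeta extrapolated correlation energy."""
    return hf_large + extrapolate_two_point(corr_q, corr_t, 4)


def ccsdt_cbs(c: CompositeComponents) -> float:
    """Composite coupled-cluster/CBS interaction energy."""
    return c.mp2_cbs + (c.ccsdt_small - c.mp2_small)
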