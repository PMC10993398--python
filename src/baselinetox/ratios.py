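"""Toxic ratios, specificity ratios, and their classification bands.

TR = predicted baseline IC10 / experimental IC10 (same basis, nominal or
free). SR = predicted nominal baseline IC10 / observed effect concentration
(EC10 or EC_SPR20). TR within 0.1-10 marks baseline-like cytotoxicity;
SR > 10 marks a specific, receptor-like effect.

Boundary convention (the source prose mixes strict and loose inequalities):
TR = 10 -> "specific", TR = 0.1 -> "baseline"; SR = 1 -> "moderate",
SR = 10 -> "specific".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .errors import DomainError, ValidationError

__all__ = [
    "RatioKind",
    "Basis",
    "RatioResult",
    "toxic_ratio",
    "specificity_ratio",
    "classify_tr",
    "classify_sr",
]


class RatioKind(str, Enum):
    TR_nom = "TR_nom"
    TR_free = "TR_free"
    SR_nom = "SR_nom"


class Basis(str, Enum):
    nominal = "nominal"
    free = "free"


@dataclass(frozen=True)
class RatioResult:
    kind: RatioKind
    value: float
    baseline_concentration: float
    observed_concentration: float
    label: str

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValidationError(f"ratio must be > 0, got {self.value}")

    def summary_value(self) -> float:
        """Ratio rounded to the 2-decimal reporting precision."""
        return round(self.value, 2)


def _check_positive(**named: float) -> None:
    for name, v in named.items():
        if not (v > 0 and math.isfinite(v)):
            raise DomainError(f"{name} must be positive and finite, got {v}")


def classify_tr(value: float) -> str:
    """Label a toxic ratio: below_baseline_band (<0.1), baseline ([0.1, 10)),
    or specific (>=10)."""
    _check_positive(tr=value)
    if value < 0.1:
        return "below_baseline_band"
    if value < 10.0:
        return "baseline"
    return "specific"


def classify_sr(value: float) -> str:
    """Label a specificity ratio: nonspecific (<1), moderate ([1, 10)),
    or specific (>=10)."""
    _check_positive(sr=value)
    if value < 1.0:
        return "nonspecific"
    if value < 10.0:
        return "moderate"
    return "specific"


def toxic_ratio(
    ic10_baseline: float,
    ic10_experimental: float,
    basis: Basis | str = Basis.nominal,
) -> RatioResult:
    """TR = predicted baseline IC10 / experimental IC10 [dimensionless].

    Both concentrations must share the stated basis; the ratio itself is
    scale-invariant.
    """
    basis = Basis(basis)
    _check_positive(ic10_baseline=ic10_baseline, ic10_experimental=ic10_experimental)
    value = ic10_baseline / ic10_experimental
    kind = RatioKind.TR_nom if basis == Basis.nominal else RatioKind.TR_free
    return RatioResult(
        kind=kind,
        value=value,
        baseline_concentration=ic10_baseline,
        observed_concentration=ic10_experimental,
        label=classify_tr(value),
    )


def specificity_ratio(
    ic10_nom_baseline: float, effect_concentration: float
) -> RatioResult:
    """SR = predicted nominal baseline IC10 / effect concentration.

    The effect concentration is an EC10 (10% of maximal effect) or EC_SPR20
    (20% suppression of a reference agonist signal), on the nominal basis.
    """
    _check_positive(
        ic10_nom_baseline=ic10_nom_baseline,
        effect_concentration=effect_concentration,
    )
    value = ic10_nom_baseline / effect_concentration
    return RatioResult(
        kind=RatioKind.SR_nom,
        value=value,
        baseline_concentration=ic10_nom_baseline,
        observed_concentration=effect_concentration,
        label=classify_sr(value),
    )
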