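"""Effect-concentration derivation from concentration-response data.

Two routes to an IC10/EC10:

* a four-parameter log-logistic (4PL) fit inverted at the requested effect
  level — the default when the response range brackets the level;
* the linear-portion method: OLS of response on concentration over the
  low-effect points (response <= 30%), solved at 10% — preferred when the
  observed effects stay well below 50%, where a 4PL midpoint is poorly
  constrained.

Cytotoxicity from confluency imaging is 100 * (1 - exposed/control),
clipped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    DomainError,
    FitError,
    InsufficientDataError,
    NoEffectError,
    ValidationError,
)

__all__ = [
    "Endpoint",
    "EffectKind",
    "DoseResponseDataset",
    "LogLogisticFit",
    "DerivedEffectConcentration",
    "fit_log_logistic",
    "derive_effect_concentration",
    "derive_ec10_linear",
    "cytotoxicity_from_confluency",
    "LINEAR_PORTION_MAX_RESPONSE",
]

#: Upper response bound (percent) for points entering the linear-portion fit.
LINEAR_PORTION_MAX_RESPONSE = 30.0


class Endpoint(str, Enum):
    cytotoxicity = "cytotoxicity"
    agonism = "agonism"
    antagonism = "antagonism"
    neurite_outgrowth = "neurite_outgrowth"


class EffectKind(str, Enum):
    IC10 = "IC10"
    EC10 = "EC10"
    EC_SPR20 = "EC_SPR20"


#: Effect level (percent) conventionally attached to each kind.
DEFAULT_LEVELS = {
    EffectKind.IC10: 10.0,
    EffectKind.EC10: 10.0,
    EffectKind.EC_SPR20: 20.0,
}


@dataclass(frozen=True)
class DoseResponseDataset:
    """Concentration-response measurements for one chemical and endpoint.

    Concentrations in mol/L; responses in percent (of maximum effect, of
    cytotoxicity, or of suppression). Needs >= 4 points for logistic
    fitting, >= 3 for the linear method.
    """

    chemical: str
    endpoint: Endpoint
    points: tuple[tuple[float, float], ...]
    basis: str = "nominal"
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "endpoint", Endpoint(self.endpoint))
        object.__setattr__(
            self, "points", tuple((float(c), float(r)) for c, r in self.points)
        )
        for c, r in self.points:
            if not (c > 0 and math.isfinite(c)):
                raise ValidationError(f"concentrations must be > 0, got {c}")
            if not math.isfinite(r):
                raise ValidationError(f"responses must be finite, got {r}")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def responses(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


@dataclass(frozen=True)
class LogLogisticFit:
    """Fitted 4PL curve: response = floor + (ceiling - floor) /
    (1 + (ec50 / c)**hill)."""

    floor: float
    ceiling: float
    ec50: float
    hill: float
    rms_residual: float
    observed_response_range: tuple[float, float]

    def predict(self, conc: float | np.ndarray) -> float | np.ndarray:
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + (self.ec50 / np.asarray(conc, dtype=float)) ** self.hill
        )


@dataclass(frozen=True)
class DerivedEffectConcentration:
    kind: EffectKind
    value: float
    method: str  # "log_logistic" or "linear_portion"
    level: float
    extrapolated: bool = False
    diagnostics: dict = field(default_factory=dict)


def _4pl(log_c: np.ndarray, floor: float, ceiling: float, log_ec50: float, hill: float) -> np.ndarray:
    return floor + (ceiling - floor) / (1.0 + 10.0 ** (hill * (log_ec50 - log_c)))


def fit_log_logistic(data: DoseResponseDataset) -> LogLogisticFit:
    """Least-squares 4PL fit in log10-concentration space.

    Deterministic: initial guesses come from data quantiles (floor = min
    response, ceiling = max, midpoint = concentration nearest half-range,
    slope = 1) followed by a single local optimisation. Flat or severely
    non-monotone data raise :class:`FitError` rather than returning a
    spurious EC.
    """
    conc = data.concentrations
    resp = data.responses
    if len(np.unique(conc)) < 4:
        raise InsufficientDataError(
            f"log-logistic fit needs >= 4 distinct concentrations, "
            f"got {len(np.unique(conc))}"
        )
    span = float(np.ptp(resp))
    if span < 5.0:
        raise FitError(
            f"response span {span:.2f}% too flat to constrain a log-logistic fit"
        )
    log_c = np.log10(conc)
    half = float(np.min(resp) + span / 2.0)
    mid_idx = int(np.argmin(np.abs(resp - half)))
    p0 = [float(np.min(resp)), float(np.max(resp)), float(log_c[mid_idx]), 1.0]
    lo = [-50.0, float(np.min(resp)), float(np.min(log_c) - 3), 0.05]
    hi = [float(np.max(resp)), 200.0, float(np.max(log_c) + 3), 20.0]
    p0 = np.clip(p0, lo, hi)
    try:
        popt, _ = curve_fit(
            _4pl, log_c, resp, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"log-logistic fit did not converge: {exc}") from exc
    floor, ceiling, log_ec50, hill = popt
    pred = _4pl(log_c, *popt)
    rms = float(np.sqrt(np.mean((pred - resp) ** 2)))
    if ceiling - floor < 5.0:
        raise FitError("fitted response amplitude < 5%: no interpretable curve")
    return LogLogisticFit(
        floor=float(floor),
        ceiling=float(ceiling),
        ec50=float(10.0**log_ec50),
        hill=float(hill),
        rms_residual=rms,
        observed_response_range=(float(np.min(resp)), float(np.max(resp))),
    )


def derive_effect_concentration(
    fit: LogLogisticFit,
    level: float,
    kind: EffectKind | str,
    allow_extrapolation: bool = True,
) -> DerivedEffectConcentration:
    """Invert a fitted 4PL curve at ``level`` percent effect.

    Exact closed-form inverse of the fitted curve. The result is flagged
    extrapolated when the level lies outside the observed response range;
    with ``allow_extrapolation=False`` that raises instead.
    """
    kind = EffectKind(kind)
    if not 0.0 < level < 100.0:
        raise DomainError(f"effect level must be in (0, 100), got {level}")
    if not fit.floor < level < fit.ceiling:
        raise DomainError(
            f"level {level}% outside the fitted response window "
            f"({fit.floor:.1f}, {fit.ceiling:.1f})%"
        )
    lo_obs, hi_obs = fit.observed_response_range
    extrapolated = not (lo_obs <= level <= hi_obs)
    if extrapolated and not allow_extrapolation:
        raise DomainError(
            f"level {level}% not bracketed by observed responses "
            f"[{lo_obs:.1f}, {hi_obs:.1f}]% and extrapolation is disallowed"
        )
    frac = (fit.ceiling - fit.floor) / (level - fit.floor) - 1.0
    value = fit.ec50 * frac ** (-1.0 / fit.hill)
    return DerivedEffectConcentration(
        kind=kind,
        value=float(value),
        method="log_logistic",
        level=level,
        extrapolated=extrapolated,
        diagnostics={
            "rms_residual": fit.rms_residual,
            "ec50": fit.ec50,
            "hill": fit.hill,
            "floor": fit.floor,
            "ceiling": fit.ceiling,
        },
    )


def derive_ec10_linear(
    data: DoseResponseDataset, level: float = 10.0
) -> DerivedEffectConcentration:
    """EC10 from the linear portion of a low-effect curve.

    OLS of response on concentration over points with response <=
    30%; EC10 = (level - intercept) / slope. A nonpositive slope means no
    concentration-dependent effect and raises :class:`NoEffectError`.
    """
    if not 0.0 < level < 100.0:
        raise DomainError(f"effect level must be in (0, 100), got {level}")
    mask = data.responses <= LINEAR_PORTION_MAX_RESPONSE
    if int(np.sum(mask)) < 3:
        raise InsufficientDataError(
            f"linear-portion method needs >= 3 points with response <= "
            f"{LINEAR_PORTION_MAX_RESPONSE}%, got {int(np.sum(mask))}"
        )
    x = data.concentrations[mask]
    y = data.responses[mask]
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise NoEffectError(
            f"{data.chemical}: nonpositive concentration-response slope "
            f"({slope:.3g}); no effect concentration derivable"
        )
    value = (level - intercept) / slope
    if not (value > 0 and math.isfinite(value)):
        raise NoEffectError(
            f"{data.chemical}: linear EC{level:g} is nonpositive "
            f"({value:.3g} mol/L); responses already exceed the level at c -> 0"
        )
    resid = y - (slope * x + intercept)
    extrapolated = not (float(np.min(x)) <= value <= float(np.max(x)))
    kind = EffectKind.IC10 if data.endpoint == Endpoint.cytotoxicity else EffectKind.EC10
    return DerivedEffectConcentration(
        kind=kind,
        value=float(value),
        method="linear_portion",
        level=level,
        extrapolated=extrapolated,
        diagnostics={
            "slope": float(slope),
            "intercept": float(intercept),
            "rms_residual": float(np.sqrt(np.mean(resid**2))),
            "n_points": int(np.sum(mask)),
        },
    )


def cytotoxicity_from_confluency(
    confluency_exposed: float, confluency_control: float
) -> tuple[float, bool]:
    """Percent cytotoxicity from confluency imaging.

    ``100 * (1 - exposed/control)`` clipped to [0, 100]. Returns the value
    and a growth-stimulation flag that is set when exposed wells are more
    confluent than controls (clipped to 0 rather than reported negative).
    """
    if confluency_control <= 0:
        raise DomainError(
            f"control confluency must be > 0, got {confluency_control}"
        )
    if confluency_exposed < 0:
        raise DomainError(
            f"exposed confluency must be >= 0, got {confluency_exposed}"
        )
    raw = 100.0 * (1.0 - confluency_exposed / confluency_control)
    stimulated = raw < 0.0
    return float(np.clip(raw, 0.0, 100.0)), stimulated
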