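"""Baseline-toxicity (narcosis) prediction models.

Baseline toxicity occurs at a constant critical membrane burden: 69 mmol of
chemical per liter of membrane lipid causes 10% cytotoxicity regardless of
cell line or chemical. Dividing by the liposome-water distribution ratio
gives the freely dissolved concentration at that burden::

    IC10_free_baseline = 0.069 / D_lip/w          [mol/L]

Converting through the bioassay mass balance — with the protein
distribution ratios predicted from ``log D_lip/w`` by the charge-class
regressions — yields the *mechanistic* nominal prediction, a function of
``log D_lip/w`` and the system composition alone. The mechanistic curve is
well approximated by a three-parameter exponential (the *empirical* model)::

    log10 IC10_nom_baseline = -(a + b * (1 - exp(-c * log10 D_lip/w)))

whose fitted (a, b, c) for four experimental bioassays and a generic
384-well system ship as packaged constants. For hydrophilic chemicals
(log D_lip/w < ~2) sorption is negligible and both models collapse to the
free-concentration limit, which holds for neutral, anionic and cationic
organics alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .chemistry import (
    ChargeClass,
    ChemicalRecord,
    LinearPartitionRegression,
    ProteinKind,
    load_partition_regressions,
    protein_partition_from_lipid,
)
from .errors import (
    FitError,
    InsufficientDataError,
    MissingDescriptorError,
    UnsupportedChargeClassError,
    ValidationError,
)
from .massbalance import (
    AssaySystem,
    PartitioningContext,
    composite_d_cell_w,
    composite_d_medium_w,
    nominal_from_free,
)

__all__ = [
    "IC10_MEMBRANE_BASELINE",
    "EmpiricalFitParams",
    "ic10_free_baseline",
    "hydrophilic_limit",
    "ic10_nom_baseline_mechanistic",
    "ic10_nom_baseline_empirical",
    "empirical_log10_ic10",
    "fit_empirical_model",
    "mechanistic_curve",
]

#: Critical membrane burden for 10% cytotoxicity [mol per L membrane lipid].
IC10_MEMBRANE_BASELINE = 0.069


@dataclass(frozen=True)
class EmpiricalFitParams:
    """(a, b, c) of the empirical exponential baseline model for one
    assay x charge class, optionally with the fit residual RMS."""

    assay: str
    charge_class: ChargeClass
    a: float
    b: float
    c: float
    medium: str | None = None
    rms_residual: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "charge_class", ChargeClass(self.charge_class))
        for attr in ("a", "b", "c"):
            if not math.isfinite(getattr(self, attr)):
                raise ValidationError(f"parameter {attr} must be finite")


def ic10_free_baseline(log_dlip_w: float) -> float:
    """Freely dissolved concentration at the critical membrane burden
    [mol/L]: ``0.069 / 10**log_dlip_w``."""
    if not math.isfinite(log_dlip_w):
        raise ValidationError(f"log_dlip_w must be finite, got {log_dlip_w}")
    return IC10_MEMBRANE_BASELINE / 10.0**log_dlip_w


def hydrophilic_limit(log_dlip_w: float) -> float:
    """Simplified nominal baseline prediction for hydrophilic chemicals.

    For weakly sorbing chemicals the nominal and free baseline
    concentrations coincide, so the prediction reduces to the
    free-concentration form and applies to neutral, anionic and cationic
    organics alike.
    """
    return ic10_free_baseline(log_dlip_w)


def _model_charge_class(
    charge_class: ChargeClass, override: ChargeClass | None = None
) -> ChargeClass:
    """Map a chemical's charge class onto a baseline model class.

    Partially charged chemicals are grouped with the neutral model (the
    grouping used for PFOSA-like sulfonamides), overridable per chemical.
    Cationic chemicals have no model here.
    """
    cc = override if override is not None else charge_class
    if cc == ChargeClass.partially_charged:
        cc = ChargeClass.neutral
    if cc not in (ChargeClass.anionic, ChargeClass.neutral):
        raise UnsupportedChargeClassError(
            f"unsupported charge class for baseline prediction: {charge_class.value}"
        )
    return cc


def ic10_nom_baseline_mechanistic(
    chemical: ChemicalRecord,
    system: AssaySystem,
    regression_set: Iterable[LinearPartitionRegression] | None = None,
    charge_class_override: ChargeClass | str | None = None,
) -> float:
    """Mechanistic nominal baseline prediction [mol/L].

    Predicts ``D_BSA/w`` and ``D_SP/w`` from ``log D_lip/w`` with the
    charge-class regressions, composes the medium and cell distribution
    ratios, and converts the free baseline concentration through the mass
    balance. ``log D_lip/w`` is the sole chemical descriptor.
    """
    if chemical.log_dlip_w is None:
        raise MissingDescriptorError(
            f"{chemical.name}: log_dlip_w required for baseline prediction "
            "(predict it from n_fluorinated_carbons first if needed)"
        )
    cc = _model_charge_class(
        chemical.charge_class,
        ChargeClass(charge_class_override) if charge_class_override else None,
    )
    if regression_set is None:
        regression_set = load_partition_regressions()
    logd = chemical.log_dlip_w
    d_lip = 10.0**logd
    d_bsa = 10.0 ** protein_partition_from_lipid(
        logd, cc, ProteinKind.BSA, regression_set
    )
    d_sp = 10.0 ** protein_partition_from_lipid(
        logd, cc, ProteinKind.structural_protein, regression_set
    )
    c_free = ic10_free_baseline(logd)

    has_medium_sorption = system.vf_protein_medium + system.vf_lipid_medium > 0
    has_cell_sorption = (
        system.v_cell > 0 and system.vf_protein_cell + system.vf_lipid_cell > 0
    )
    d_medium = (
        composite_d_medium_w(
            d_bsa, d_lip, system.vf_protein_medium, system.vf_lipid_medium
        )
        if has_medium_sorption
        else 0.0
    )
    d_cell = (
        composite_d_cell_w(d_sp, d_lip, system.vf_protein_cell, system.vf_lipid_cell)
        if has_cell_sorption
        else 0.0
    )
    ctx = PartitioningContext(d_medium_w=d_medium, d_cell_w=d_cell)
    return nominal_from_free(c_free, system, ctx)


def empirical_log10_ic10(log_dlip_w: float, a: float, b: float, c: float) -> float:
    """log10 of the empirical nominal baseline prediction."""
    return -(a + b * (1.0 - math.exp(-c * log_dlip_w)))


def ic10_nom_baseline_empirical(
    log_dlip_w: float, params: EmpiricalFitParams
) -> float:
    """Empirical three-parameter nominal baseline prediction [mol/L]."""
    if not math.isfinite(log_dlip_w):
        raise ValidationError(f"log_dlip_w must be finite, got {log_dlip_w}")
    return 10.0 ** empirical_log10_ic10(log_dlip_w, params.a, params.b, params.c)


def mechanistic_curve(
    system: AssaySystem,
    charge_class: ChargeClass | str,
    log_dlip_grid: Sequence[float] | None = None,
    regression_set: Iterable[LinearPartitionRegression] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the mechanistic model on a ``log D_lip/w`` grid.

    Default grid: [0, 7] in steps of 0.05, the span over which the
    empirical constants were calibrated.
    """
    if log_dlip_grid is None:
        log_dlip_grid = np.arange(0.0, 7.0 + 1e-12, 0.05)
    grid = np.asarray(log_dlip_grid, dtype=float)
    cc = ChargeClass(charge_class)
    if regression_set is None:
        regression_set = load_partition_regressions()
    vals = np.array(
        [
            ic10_nom_baseline_mechanistic(
                ChemicalRecord(name=f"grid_{x:.2f}", charge_class=cc, log_dlip_w=float(x)),
                system,
                regression_set,
            )
            for x in grid
        ]
    )
    return grid, vals


def fit_empirical_model(
    curve: Sequence[tuple[float, float]],
    assay: str = "user fit",
    charge_class: ChargeClass | str = ChargeClass.anionic,
    medium: str | None = None,
) -> EmpiricalFitParams:
    """Fit the empirical exponential model to (log D_lip/w, IC10_nom) points.

    Unweighted least squares in log10(IC10) space. Requires >= 10 points
    spanning >= 3 log units of ``log D_lip/w``. Three restarts from fixed
    seeds (42, 43, 44) perturb the initial guess to guard against local
    minima; the best residual wins, so the fit is deterministic.
    """
    if len(curve) < 10:
        raise InsufficientDataError(
            f"empirical fit needs >= 10 curve points, got {len(curve)}"
        )
    pts = sorted((float(x), float(y)) for x, y in curve)
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) < 3.0:
        raise InsufficientDataError(
            f"curve must span >= 3 log units of log D_lip/w, spans {np.ptp(x):.2f}"
        )
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValidationError("IC10 values must be positive and finite")
    logy = np.log10(y)

    def resid(p: np.ndarray) -> np.ndarray:
        a, b, c = p
        return -(a + b * (1.0 - np.exp(-c * x))) - logy

    # data-driven base guess: a from the y-intercept region, a+b from the
    # hydrophobic plateau, c from the curvature scale
    a0 = -float(np.max(logy))
    b0 = max(float(np.max(logy) - np.min(logy)), 0.5)
    base = np.array([a0, b0, 0.3])
    best = None
    for seed in (42, 43, 44):
        rng = np.random.default_rng(seed)
        p0 = base * (1.0 + 0.2 * rng.standard_normal(3))
        try:
            sol = least_squares(resid, p0, max_nfev=10000)
        except Exception:  # pragma: no cover - scipy raises only on bad input
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise FitError("empirical exponential fit did not converge")
    a, b, c = best.x
    rms = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    return EmpiricalFitParams(
        assay=assay,
        charge_class=charge_class,
        a=float(a),
        b=float(b),
        c=float(c),
        medium=medium,
        rms_residual=rms,
    )
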