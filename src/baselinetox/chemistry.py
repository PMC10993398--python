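"""Chemical records and partition-coefficient relationships.

All partitioning quantities are dimensionless, volume-normalised
distribution ratios (liters of water per liter of sorbing phase) and are
handled in log10 space; aqueous concentrations are mol/L.

Three families of linear log-log relationships live here:

* protein-lipid regressions ``log D_protein/w = slope * log D_lip/w +
  intercept`` that predict binding to serum albumin (medium surrogate) or
  structural protein (cell surrogate) from the liposome-water distribution
  ratio, with separate coefficients for anionic and neutral chemicals
  (anionic chemicals bind proteins considerably more strongly);
* Freundlich-type concentration-dependent binding ``log D = slope *
  log C_w + intercept``, which captures the saturable, nonlinear medium
  binding observed for several perfluoroalkyl acids;
* a fluorinated-carbon calibration that predicts ``log D_lip/w`` for PFAS
  lacking an experimental value from the homologous-series trend.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    ExtrapolationWarning,
    UnsupportedChargeClassError,
    ValidationError,
)

__all__ = [
    "ChargeClass",
    "ProteinKind",
    "ChemicalRecord",
    "LinearPartitionRegression",
    "FreundlichBinding",
    "protein_partition_from_lipid",
    "fit_protein_lipid_regression",
    "freundlich_log_d",
    "log_dlip_from_n_fluorocarbons",
    "mass_to_volume_fraction",
    "load_partition_regressions",
    "PROTEIN_DENSITY_KG_L",
    "LIPID_DENSITY_KG_L",
]

#: Densities used to convert measured mass concentrations (mg/L) of protein
#: and lipid into the volume fractions the mass balance needs (mL/L).
PROTEIN_DENSITY_KG_L = 1.36
LIPID_DENSITY_KG_L = 1.0


class ChargeClass(str, Enum):
    """Dominant speciation of a chemical at assay pH 7.4.

    Assigned by inspection of the structure; no pKa computation is done.
    """

    anionic = "anionic"
    neutral = "neutral"
    partially_charged = "partially_charged"
    cationic = "cationic"


class ProteinKind(str, Enum):
    BSA = "BSA"
    structural_protein = "structural_protein"


def _check_finite(name: str, value: float | None) -> None:
    if value is not None and not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical's identity, charge class, and partition descriptors.

    ``log_dlip_w`` is the liposome-water distribution ratio at pH 7.4,
    the sole descriptor of the baseline-toxicity models. The protein
    descriptors are optional: when absent they are predicted from
    ``log_dlip_w`` through the charge-class regressions.
    """

    name: str
    charge_class: ChargeClass
    dtxsid: str | None = None
    log_dlip_w: float | None = None
    log_dbsa_w: float | None = None
    log_dsp_w: float | None = None
    n_fluorinated_carbons: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "charge_class", ChargeClass(self.charge_class))
        for attr in ("log_dlip_w", "log_dbsa_w", "log_dsp_w"):
            _check_finite(attr, getattr(self, attr))
        n = self.n_fluorinated_carbons
        if n is not None and (int(n) != n or n < 0):
            raise ValidationError(
                f"n_fluorinated_carbons must be a nonnegative integer, got {n!r}"
            )


@dataclass(frozen=True)
class LinearPartitionRegression:
    """``log D_protein/w = slope * log D_lip/w + intercept`` for one
    (charge class, protein kind) pair."""

    slope: float
    intercept: float
    charge_class: ChargeClass
    protein_kind: ProteinKind
    source: str = "user fit"

    def __post_init__(self) -> None:
        object.__setattr__(self, "charge_class", ChargeClass(self.charge_class))
        object.__setattr__(self, "protein_kind", ProteinKind(self.protein_kind))
        _check_finite("slope", self.slope)
        _check_finite("intercept", self.intercept)

    def predict(self, log_dlip_w: float) -> float:
        _check_finite("log_dlip_w", log_dlip_w)
        return self.slope * log_dlip_w + self.intercept


@dataclass(frozen=True)
class FreundlichBinding:
    """Concentration-dependent distribution ratio, linear in log-log space.

    ``log10 D = slope * log10 C_w + intercept`` with ``C_w`` the freely
    dissolved concentration in mol/L. ``valid_log_cw_range`` is the
    concentration window the regression was derived on; evaluation outside
    it warns (extrapolation) but proceeds, since effect concentrations
    routinely sit near the edge of the measured range.
    """

    slope: float
    intercept: float
    valid_log_cw_range: tuple[float, float] = (-12.0, 0.0)

    def __post_init__(self) -> None:
        _check_finite("slope", self.slope)
        _check_finite("intercept", self.intercept)
        lo, hi = self.valid_log_cw_range
        if not lo < hi:
            raise ValidationError(
                f"valid_log_cw_range must be increasing, got ({lo}, {hi})"
            )


def freundlich_log_d(binding: FreundlichBinding, log_cw: float) -> float:
    """Evaluate a Freundlich-type binding model at ``log_cw`` [log10 mol/L].

    Warns with :class:`ExtrapolationWarning` outside the validity range.
    A slope of 0 recovers a concentration-independent distribution ratio.
    """
    _check_finite("log_cw", log_cw)
    lo, hi = binding.valid_log_cw_range
    if not lo <= log_cw <= hi:
        warnings.warn(
            f"log C_w = {log_cw:.3g} outside Freundlich validity range "
            f"[{lo:.3g}, {hi:.3g}]; extrapolating",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return binding.slope * log_cw + binding.intercept


def fit_protein_lipid_regression(
    pairs: Sequence[tuple[float, float]],
    charge_class: ChargeClass | str = ChargeClass.anionic,
    protein_kind: ProteinKind | str = ProteinKind.BSA,
    source: str = "user fit",
) -> LinearPartitionRegression:
    """Ordinary least squares of ``log D_protein/w`` on ``log D_lip/w``.

    Unweighted OLS in log10 space. Requires at least three pairs and
    nonzero variance in the predictor.
    """
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"protein-lipid regression needs >= 3 pairs, got {len(pairs)}"
        )
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite value in regression pairs")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("zero variance in log D_lip/w values")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearPartitionRegression(
        slope=float(slope),
        intercept=float(intercept),
        charge_class=charge_class,
        protein_kind=protein_kind,
        source=source,
    )


def protein_partition_from_lipid(
    log_dlip_w: float,
    charge_class: ChargeClass | str,
    protein_kind: ProteinKind | str,
    regression_set: Iterable[LinearPartitionRegression] | None = None,
) -> float:
    """Predict ``log D_protein/w`` from ``log D_lip/w``.

    Looks up the regression matching (charge class, protein kind) in
    ``regression_set`` (the packaged set when None). No regression exists
    for cationic chemicals; asking for one raises
    :class:`UnsupportedChargeClassError` rather than silently falling back.
    """
    _check_finite("log_dlip_w", log_dlip_w)
    charge_class = ChargeClass(charge_class)
    protein_kind = ProteinKind(protein_kind)
    if regression_set is None:
        regression_set = load_partition_regressions()
    for reg in regression_set:
        if reg.charge_class == charge_class and reg.protein_kind == protein_kind:
            return reg.predict(log_dlip_w)
    raise UnsupportedChargeClassError(
        f"unsupported charge class: no {protein_kind.value} regression for "
        f"{charge_class.value} chemicals"
    )


def log_dlip_from_n_fluorocarbons(
    records: Sequence[ChemicalRecord], n_query: int
) -> float:
    """Predict ``log D_lip/w`` from the number of fluorinated carbons.

    OLS of known ``log_dlip_w`` on ``n_fluorinated_carbons`` over the
    calibration records (>= 3 required), evaluated at ``n_query``. Used for
    PFAS without experimental liposome-water data.
    """
    usable = [
        r
        for r in records
        if r.log_dlip_w is not None and r.n_fluorinated_carbons is not None
    ]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"fluorocarbon calibration needs >= 3 records with both "
            f"log_dlip_w and n_fluorinated_carbons, got {len(usable)}"
        )
    x = np.asarray([r.n_fluorinated_carbons for r in usable], dtype=float)
    y = np.asarray([r.log_dlip_w for r in usable], dtype=float)
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("all calibration records share one carbon count")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope * n_query + intercept)


def mass_to_volume_fraction(mass_conc: float, phase: str) -> float:
    """Convert a measured mass concentration (mg/L) to mL/L.

    Uses a protein density of 1.36 kg/L and a lipid density of 1 kg/L.
    """
    if mass_conc < 0:
        raise DomainError(f"mass concentration must be >= 0, got {mass_conc}")
    if phase == "protein":
        return mass_conc / PROTEIN_DENSITY_KG_L
    if phase == "lipid":
        return mass_conc / LIPID_DENSITY_KG_L
    raise ValidationError(f"phase must be 'protein' or 'lipid', got {phase!r}")


def load_partition_regressions(
    path: str | None = None,
) -> tuple[LinearPartitionRegression, ...]:
    """Load the packaged protein-lipid regression coefficients.

    The coefficients are data, not code: they live in
    ``data/partition_regressions.yaml`` with provenance strings.
    """
    if path is None:
        text = (
            resources.files("baselinetox.data")
            .joinpath("partition_regressions.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return tuple(
        LinearPartitionRegression(
            slope=entry["slope"],
            intercept=entry["intercept"],
            charge_class=entry["charge_class"],
            protein_kind=entry["protein_kind"],
            source=entry.get("source", "packaged"),
        )
        for entry in raw["regressions"]
    )
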