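"""In vitro mass balance between nominal and freely dissolved concentrations.

A dosed (nominal) concentration ``C_nom = n_tot / V_tot`` distributes over
the aqueous phase and the protein and lipid of medium and cells. At steady
state the free concentration is the same in medium water and cytosol, so a
single balance links the two dose metrics::

    C_nom * V_tot = C_free * (V_w
                              + D_medium/w * V_protein+lipid,medium
                              + D_cell/w   * V_protein+lipid,cell)

``D_medium/w`` and ``D_cell/w`` are composite distribution ratios of the
protein+lipid phases (L water per L protein+lipid), predicted from the
surrogate ratios (BSA for medium protein, structural protein for cell
protein, liposomes for lipid) as volume-weighted means. With constant
ratios the balance inverts in closed form; with Freundlich-type
concentration-dependent ratios the free concentration is found by a damped
fixed-point iteration on ``log10 C_free``.

``V_w`` is the total volume minus the sorptive protein and lipid volumes.
Because the volume fractions are far below 1, ``V_w ~= V_medium``; the
exact form is used internally and agrees with the approximation to <1% for
any valid system.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import yaml

from .chemistry import FreundlichBinding, freundlich_log_d
from .errors import (
    ConvergenceError,
    DegenerateInputError,
    DomainError,
    ValidationError,
)

__all__ = [
    "AssaySystem",
    "PartitioningContext",
    "composite_d_medium_w",
    "composite_d_cell_w",
    "free_from_nominal",
    "nominal_from_free",
    "load_assay_systems",
]


@dataclass(frozen=True)
class AssaySystem:
    """Geometry and sorptive composition of one bioassay.

    Volumes in liters, volume fractions in L phase per L compartment.
    Default well geometry elsewhere in the package is the 384-well format
    (40 uL medium, ~30 nL cells).
    """

    name: str
    v_medium: float
    v_cell: float
    vf_protein_medium: float
    vf_lipid_medium: float
    vf_protein_cell: float
    vf_lipid_cell: float

    def __post_init__(self) -> None:
        if self.v_medium <= 0:
            raise ValidationError(f"v_medium must be > 0, got {self.v_medium}")
        if self.v_cell < 0:
            raise ValidationError(f"v_cell must be >= 0, got {self.v_cell}")
        for attr in (
            "vf_protein_medium",
            "vf_lipid_medium",
            "vf_protein_cell",
            "vf_lipid_cell",
        ):
            v = getattr(self, attr)
            if not 0 <= v < 1:
                raise ValidationError(f"{attr} must be in [0, 1), got {v}")
        if self.vf_protein_medium + self.vf_lipid_medium >= 1:
            raise ValidationError("medium protein+lipid volume fractions >= 1")
        if self.vf_protein_cell + self.vf_lipid_cell >= 1:
            raise ValidationError("cell protein+lipid volume fractions >= 1")

    @property
    def v_tot(self) -> float:
        return self.v_medium + self.v_cell

    @property
    def v_sorptive_medium(self) -> float:
        """Protein+lipid volume in the medium compartment [L]."""
        return (self.vf_protein_medium + self.vf_lipid_medium) * self.v_medium

    @property
    def v_sorptive_cell(self) -> float:
        return (self.vf_protein_cell + self.vf_lipid_cell) * self.v_cell

    @property
    def v_water(self) -> float:
        """Aqueous volume: total minus sorptive protein and lipid volumes."""
        return self.v_tot - self.v_sorptive_medium - self.v_sorptive_cell


@dataclass(frozen=True)
class PartitioningContext:
    """Medium and cell distribution ratios, constant or Freundlich-type.

    Constant ratios are plain nonnegative floats [L_w/L_protein+lipid];
    concentration-dependent ratios are :class:`FreundlichBinding` models
    evaluated at the free concentration.
    """

    d_medium_w: float | FreundlichBinding
    d_cell_w: float | FreundlichBinding

    def __post_init__(self) -> None:
        for attr in ("d_medium_w", "d_cell_w"):
            v = getattr(self, attr)
            if isinstance(v, FreundlichBinding):
                if v.slope <= -1:
                    warnings.warn(
                        f"Freundlich slope {v.slope} <= -1: the mass balance "
                        "may not have a unique solution",
                        UserWarning,
                        stacklevel=2,
                    )
            elif v < 0:
                raise ValidationError(f"{attr} must be >= 0, got {v}")

    @property
    def is_constant(self) -> bool:
        return not (
            isinstance(self.d_medium_w, FreundlichBinding)
            or isinstance(self.d_cell_w, FreundlichBinding)
        )

    def d_at(self, which: str, c_free: float) -> float:
        d = getattr(self, which)
        if isinstance(d, FreundlichBinding):
            # clamp at 0 after back-transformation (10**x is already > 0)
            return max(10.0 ** freundlich_log_d(d, math.log10(c_free)), 0.0)
        return float(d)


def _composite(d_protein: float, d_lipid: float, vf_protein: float, vf_lipid: float) -> float:
    if d_protein < 0 or d_lipid < 0 or vf_protein < 0 or vf_lipid < 0:
        raise DomainError("distribution ratios and volume fractions must be >= 0")
    vf_total = vf_protein + vf_lipid
    if vf_total == 0:
        raise DegenerateInputError("zero combined protein+lipid volume")
    return (vf_protein * d_protein + vf_lipid * d_lipid) / vf_total


def composite_d_medium_w(
    d_bsa_w: float, d_lip_w: float, vf_protein_medium: float, vf_lipid_medium: float
) -> float:
    """Composite medium-water distribution ratio [L_w/L_protein+lipid].

    Volume-weighted mean of the BSA (protein surrogate) and liposome
    (lipid surrogate) ratios, normalised to the combined sorptive volume.
    """
    return _composite(d_bsa_w, d_lip_w, vf_protein_medium, vf_lipid_medium)


def composite_d_cell_w(
    d_sp_w: float, d_lip_w: float, vf_protein_cell: float, vf_lipid_cell: float
) -> float:
    """Composite cell-water distribution ratio; structural protein is the
    protein surrogate for cells."""
    return _composite(d_sp_w, d_lip_w, vf_protein_cell, vf_lipid_cell)


def _balance_factor(system: AssaySystem, d_medium: float, d_cell: float) -> float:
    """(V_w + D_med*V_pl,med + D_cell*V_pl,cell) / V_tot, i.e. C_nom/C_free."""
    return (
        system.v_water
        + d_medium * system.v_sorptive_medium
        + d_cell * system.v_sorptive_cell
    ) / system.v_tot


def nominal_from_free(
    c_free: float, system: AssaySystem, ctx: PartitioningContext
) -> float:
    """Nominal concentration [mol/L] producing the given free concentration.

    Direct evaluation of the balance; no iteration is needed even for
    Freundlich contexts because the ratios are evaluated at ``c_free``.
    """
    if not (c_free > 0 and math.isfinite(c_free)):
        raise DomainError(f"c_free must be positive and finite, got {c_free}")
    d_med = ctx.d_at("d_medium_w", c_free)
    d_cell = ctx.d_at("d_cell_w", c_free)
    return c_free * _balance_factor(system, d_med, d_cell)


def free_from_nominal(
    c_nom: float,
    system: AssaySystem,
    ctx: PartitioningContext,
    tol: float = 1e-11,
    max_iter: int = 500,
    damping: float = 0.5,
) -> float:
    """Free concentration [mol/L] resulting from a nominal dose.

    Closed form for constant ratios. For Freundlich contexts the
    self-consistent solution is found by damped fixed-point iteration on
    ``log10 C_free`` (damping 0.5) to ``|delta log10| < tol``. The result is
    bounded by ``0 < C_free <= C_nom * V_tot / V_w``.
    """
    if not (c_nom > 0 and math.isfinite(c_nom)):
        raise DomainError(f"c_nom must be positive and finite, got {c_nom}")
    if ctx.is_constant:
        return c_nom / _balance_factor(system, float(ctx.d_medium_w), float(ctx.d_cell_w))

    log_c = math.log10(c_nom)  # start from the no-sorption limit
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # range warnings handled once below
        for _ in range(max_iter):
            c = 10.0**log_c
            target = math.log10(
                c_nom
                / _balance_factor(
                    system, ctx.d_at("d_medium_w", c), ctx.d_at("d_cell_w", c)
                )
            )
            step = target - log_c
            log_c += damping * step
            if abs(step) < tol:
                break
        else:
            raise ConvergenceError(
                f"mass-balance fixed point did not converge in {max_iter} "
                f"iterations (last |step| = {abs(step):.2e})",
                last_iterate=10.0**log_c,
            )
    c_free = 10.0**log_c
    # re-evaluate once outside the suppressed-warning block so genuine
    # extrapolation beyond a Freundlich validity range is surfaced
    ctx.d_at("d_medium_w", c_free)
    ctx.d_at("d_cell_w", c_free)
    return c_free


def load_assay_systems(path: str | None = None) -> dict[str, AssaySystem]:
    """Load the packaged assay-system presets (plus any user file).

    Ships the generic 384-well system in two variants wherever the source
    tables disagree (``generic`` with 0.001% medium lipid and a 6%/0.1%
    cell; ``generic_text`` with 0.007% medium lipid and a 3%/0.5% cell)
    and approximate presets for the four experimental assays.
    """
    if path is None:
        text = (
            resources.files("baselinetox.data")
            .joinpath("assay_systems.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    systems = {}
    for entry in raw["systems"]:
        systems[entry["name"]] = AssaySystem(
            name=entry["name"],
            v_medium=float(entry["v_medium_L"]),
            v_cell=float(entry["v_cell_L"]),
            vf_protein_medium=float(entry["vf_protein_medium"]),
            vf_lipid_medium=float(entry["vf_lipid_medium"]),
            vf_protein_cell=float(entry["vf_protein_cell"]),
            vf_lipid_cell=float(entry["vf_lipid_cell"]),
        )
    return systems
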