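"""End-to-end orchestration: tables in, classified ratios out.

Joins a chemicals table with long-format concentration-response data,
derives effect concentrations, predicts mechanistic and empirical nominal
baseline concentrations, and emits TR/SR values with classification
labels, one row per chemical x endpoint. Chemicals whose charge class has
no baseline model are skipped with a logged reason rather than aborting
the run.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .baseline import (
    ic10_free_baseline,
    ic10_nom_baseline_empirical,
    ic10_nom_baseline_mechanistic,
)
from .chemistry import ChargeClass, ChemicalRecord
from .datasets import table2_lookup
from .doseresponse import (
    DoseResponseDataset,
    EffectKind,
    Endpoint,
    derive_ec10_linear,
    derive_effect_concentration,
    fit_log_logistic,
)
from .errors import (
    BaselinetoxError,
    NumericalError,
    UnsupportedChargeClassError,
    ValidationError,
)
from .massbalance import AssaySystem, load_assay_systems
from .ratios import specificity_ratio, toxic_ratio

__all__ = ["run_pipeline", "RESULT_COLUMNS"]

logger = logging.getLogger("baselinetox.pipeline")

_CHEMICAL_COLUMNS = {"name", "charge_class"}
_RESPONSE_COLUMNS = {
    "chemical",
    "endpoint",
    "basis",
    "concentration_mol_L",
    "response_percent",
}

RESULT_COLUMNS = [
    "chemical",
    "assay",
    "endpoint",
    "basis",
    "method",
    "derived_kind",
    "derived_conc_mol_L",
    "baseline_conc_mol_L",
    "baseline_model",
    "ratio_kind",
    "ratio",
    "label",
]

_ENDPOINT_KIND = {
    Endpoint.cytotoxicity: (EffectKind.IC10, 10.0),
    Endpoint.agonism: (EffectKind.EC10, 10.0),
    Endpoint.neurite_outgrowth: (EffectKind.EC10, 10.0),
    Endpoint.antagonism: (EffectKind.EC_SPR20, 20.0),
}


def _validate_schema(df: pd.DataFrame, required: set[str], what: str) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{what} table missing columns: {sorted(missing)}")


def _parse_float(value) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    v = float(value)
    return v if math.isfinite(v) else None


def run_pipeline(
    chemicals: pd.DataFrame,
    responses: pd.DataFrame,
    system: AssaySystem | str = "generic",
    assay: str = "generic",
    model: str = "mechanistic",
    ec_method: str = "log_logistic",
) -> pd.DataFrame:
    """Run derivation, baseline prediction and classification.

    ``model`` selects which baseline prediction anchors the ratios
    (``mechanistic`` or ``empirical``); both are computed and reported.
    ``ec_method`` is ``log_logistic`` or ``linear``. Deterministic.
    """
    if isinstance(system, str):
        system = load_assay_systems()[system]
    if model not in ("mechanistic", "empirical"):
        raise ValidationError(f"model must be mechanistic|empirical, got {model!r}")
    if ec_method not in ("log_logistic", "linear"):
        raise ValidationError(
            f"ec_method must be log_logistic|linear, got {ec_method!r}"
        )
    _validate_schema(chemicals, _CHEMICAL_COLUMNS, "chemicals")
    if len(responses) and not _RESPONSE_COLUMNS <= set(responses.columns):
        _validate_schema(responses, _RESPONSE_COLUMNS, "responses")

    known = set(chemicals["name"])
    if len(responses):
        unknown = sorted(set(responses["chemical"]) - known)
        if unknown:
            raise ValidationError(
                f"responses reference chemicals absent from the chemicals "
                f"table: {unknown}"
            )
        bad = responses[
            ~np.isfinite(pd.to_numeric(responses["concentration_mol_L"], errors="coerce"))
            | (pd.to_numeric(responses["concentration_mol_L"], errors="coerce") <= 0)
        ]
        if len(bad):
            raise ValidationError(
                f"non-positive or non-numeric concentrations in responses "
                f"rows {bad.index.tolist()}"
            )

    rows: list[dict] = []
    for _, chem_row in chemicals.iterrows():
        name = chem_row["name"]
        try:
            record = ChemicalRecord(
                name=name,
                charge_class=ChargeClass(chem_row["charge_class"]),
                log_dlip_w=_parse_float(chem_row.get("log_dlip_w")),
                log_dbsa_w=_parse_float(chem_row.get("log_dbsa_w")),
                log_dsp_w=_parse_float(chem_row.get("log_dsp_w")),
            )
        except ValueError as exc:
            raise ValidationError(f"chemical {name!r}: {exc}") from exc

        try:
            baseline_mech = ic10_nom_baseline_mechanistic(record, system)
            model_cc = (
                ChargeClass.neutral
                if record.charge_class == ChargeClass.partially_charged
                else record.charge_class
            )
            baseline_emp = ic10_nom_baseline_empirical(
                record.log_dlip_w, table2_lookup(assay, model_cc)
            )
        except UnsupportedChargeClassError as exc:
            logger.info("skipping %s: %s", name, exc)
            continue
        except BaselinetoxError as exc:
            logger.info("skipping %s: %s", name, exc)
            continue
        baseline_nom = baseline_mech if model == "mechanistic" else baseline_emp
        logger.info(
            "%s: log_dlip_w=%.2f model=%s baseline IC10,nom=%.3e mol/L",
            name,
            record.log_dlip_w,
            model,
            baseline_nom,
        )

        if not len(responses):
            continue
        for (endpoint_name, basis), group in responses[
            responses["chemical"] == name
        ].groupby(["endpoint", "basis"], sort=True):
            endpoint = Endpoint(endpoint_name)
            kind, level = _ENDPOINT_KIND[endpoint]
            ds = DoseResponseDataset(
                chemical=name,
                endpoint=endpoint,
                basis=basis,
                points=tuple(
                    zip(
                        group["concentration_mol_L"].astype(float),
                        group["response_percent"].astype(float),
                    )
                ),
            )
            try:
                if ec_method == "log_logistic":
                    derived = derive_effect_concentration(
                        fit_log_logistic(ds), level, kind
                    )
                else:
                    derived = derive_ec10_linear(ds, level)
                    derived = type(derived)(
                        kind=kind,
                        value=derived.value,
                        method=derived.method,
                        level=derived.level,
                        extrapolated=derived.extrapolated,
                        diagnostics=derived.diagnostics,
                    )
            except NumericalError as exc:
                logger.info("%s/%s: no effect concentration (%s)", name, endpoint.value, exc)
                continue

            if endpoint == Endpoint.cytotoxicity:
                if basis == "free":
                    baseline_for_ratio = ic10_free_baseline(record.log_dlip_w)
                else:
                    baseline_for_ratio = baseline_nom
                ratio = toxic_ratio(baseline_for_ratio, derived.value, basis)
            else:
                if basis == "free":
                    raise ValidationError(
                        f"{name}/{endpoint.value}: specificity ratios are "
                        "defined on the nominal basis"
                    )
                baseline_for_ratio = baseline_nom
                ratio = specificity_ratio(baseline_nom, derived.value)
            rows.append(
                {
                    "chemical": name,
                    "assay": assay,
                    "endpoint": endpoint.value,
                    "basis": basis,
                    "method": derived.method,
                    "derived_kind": derived.kind.value,
                    "derived_conc_mol_L": derived.value,
                    "baseline_conc_mol_L": baseline_for_ratio,
                    "baseline_model": model,
                    "ratio_kind": ratio.kind.value,
                    "ratio": ratio.value,
                    "label": ratio.label,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
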