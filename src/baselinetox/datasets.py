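"""Packaged reference datasets.

``table1``: cytotoxicity and distribution ratios of 11 PFAS measured in the
PPARgamma-GeneBLAzer assay (96-well format) — nominal and free IC10,
composite medium/cell ratios, surrogate-phase ratios, liposome-water
ratios, and the printed toxic ratios.

``table2``: the (a, b, c) parameters of the empirical baseline model for
four bioassays plus the generic 384-well system, for anionic and neutral
chemicals (10 parameter triples).

Files are verified against embedded SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
import unicodedata
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .baseline import EmpiricalFitParams
from .chemistry import ChargeClass, ChemicalRecord
from .errors import ValidationError

__all__ = ["PackagedDataset", "load_packaged", "table2_lookup", "table1_records"]

_CHECKSUMS = {
    "table1": "c4efcca5dae7709fdb55876abd28927097b1fc9488b40fba32d700b2cc8b90a2",
    "table2": "a7e30c03a668c2b1fdb6c23a333ca499186a10126f2ef6ddf0c5b880397569fe",
}

_PROVENANCE = "doi:10.1021/acs.est.3c09950"


@dataclass(frozen=True)
class PackagedDataset:
    name: str
    table: pd.DataFrame
    provenance: str


def _normalise_assay(name: str) -> str:
    """Fold unicode (e.g. the Greek gamma) so both spellings look up."""
    name = unicodedata.normalize("NFKC", name)
    return name.replace("γ", "gamma").replace("α", "alpha").strip().lower()


def load_packaged(name: str) -> PackagedDataset:
    """Load a packaged dataset (``table1`` or ``table2``) with validation."""
    if name not in _CHECKSUMS:
        raise ValidationError(
            f"unknown packaged dataset {name!r}; available: {sorted(_CHECKSUMS)}"
        )
    raw = resources.files("baselinetox.data").joinpath(f"{name}.csv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValidationError(
            f"packaged dataset {name} failed checksum verification ({digest})"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw))
    if name == "table1":
        if len(df) != 11:
            raise ValidationError(f"table1 must hold 11 chemicals, got {len(df)}")
        df = df.set_index("name", drop=False)
    else:
        if len(df) != 10:
            raise ValidationError(f"table2 must hold 10 parameter triples, got {len(df)}")
    return PackagedDataset(name=name, table=df, provenance=_PROVENANCE)


def table1_records() -> tuple[ChemicalRecord, ...]:
    """Table 1 chemicals as :class:`ChemicalRecord` objects."""
    df = load_packaged("table1").table
    return tuple(
        ChemicalRecord(
            name=row["name"],
            dtxsid=row["dtxsid"],
            charge_class=ChargeClass(row["charge_class"]),
            log_dlip_w=float(row["log_dlip_w"]),
            log_dbsa_w=float(row["log_dbsa_w"]),
            log_dsp_w=float(row["log_dsp_w"]),
            n_fluorinated_carbons=int(row["n_fluorinated_carbons"]),
        )
        for _, row in df.iterrows()
    )


def table2_lookup(
    assay: str, charge_class: ChargeClass | str
) -> EmpiricalFitParams:
    """Fetch the empirical (a, b, c) for one assay x charge class.

    Assay matching is unicode-folded and case-insensitive; ``generic``
    matches the generic-cell row.
    """
    cc = ChargeClass(charge_class)
    if cc not in (ChargeClass.anionic, ChargeClass.neutral):
        raise ValidationError(
            f"empirical parameters exist only for anionic/neutral, got {cc.value}"
        )
    df = load_packaged("table2").table
    key = _normalise_assay(assay)
    for _, row in df.iterrows():
        row_key = _normalise_assay(str(row["assay"]))
        if (row_key == key or row_key.startswith(key)) and row["charge_class"] == cc.value:
            return EmpiricalFitParams(
                assay=str(row["assay"]),
                charge_class=cc,
                a=float(row["a"]),
                b=float(row["b"]),
                c=float(row["c"]),
                medium=str(row["medium"]),
            )
    raise ValidationError(
        f"no empirical parameters for assay {assay!r} / {cc.value}"
    )
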