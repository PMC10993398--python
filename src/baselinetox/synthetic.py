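"""Synthetic data generation for pipeline validation.

The generator emulates the screening study design: chemicals with
liposome-water distribution ratios spread over the PFAS range, 10-point
2-fold serial-dilution concentration-response curves, percent responses
with additive Gaussian noise (3% by default, the replicate scatter typical
of imaging-based cytotoxicity readouts), and Freundlich-type medium
binding with shallow negative slopes.

Cytotoxic potencies are placed exactly on the baseline model (TR = 1 by
construction); effect endpoints are offset below baseline by a
per-chemical specificity factor, so the ground-truth SR is known. All
randomness flows from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .baseline import ic10_nom_baseline_mechanistic
from .chemistry import ChargeClass, ChemicalRecord
from .errors import ValidationError
from .doseresponse import DoseResponseDataset, Endpoint
from .massbalance import AssaySystem, load_assay_systems

__all__ = ["SyntheticScenario", "SyntheticData", "generate_synthetic", "synthetic_4pl_dataset"]


def synthetic_4pl_dataset(
    chemical: str,
    ec10_true: float,
    rng: np.random.Generator,
    endpoint: Endpoint | str = Endpoint.cytotoxicity,
    n_concentrations: int = 10,
    dilution_factor: float = 2.0,
    hill: float = 1.0,
    noise_sd_response: float = 3.0,
    max_response: float | None = None,
) -> DoseResponseDataset:
    """One noisy 4PL concentration-response curve with a known EC10.

    The curve has floor 0, ceiling 100 and the given Hill slope; its EC50
    is placed so the noise-free EC10 equals ``ec10_true``. ``max_response``
    caps the top tested concentration at the concentration producing that
    noise-free response (used to emulate low-effect curves); otherwise the
    design brackets the EC50 comfortably.
    """
    ec50 = ec10_true * 9.0 ** (1.0 / hill)
    if max_response is not None:
        top = ec50 * ((100.0 - max_response) / max_response) ** (-1.0 / hill)
    else:
        top = 16.0 * ec50
    conc = top / dilution_factor ** np.arange(n_concentrations)
    true_resp = 100.0 / (1.0 + (ec50 / conc) ** hill)
    resp = true_resp + rng.normal(0.0, noise_sd_response, size=conc.size)
    return DoseResponseDataset(
        chemical=chemical,
        endpoint=Endpoint(endpoint),
        points=tuple(zip(conc.tolist(), resp.tolist())),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for one synthetic dataset.

    ``specificity_factors`` maps chemical index -> factor; chemicals not
    listed get factor 1 (pure baseline). A factor f places the effect
    EC10 at baseline/f, so the recovered SR should be ~f.
    """

    seed: int
    n_chemicals: int = 20
    log_dlip_range: tuple[float, float] = (1.0, 6.0)
    noise_sd_response: float = 3.0
    freundlich_slope_range: tuple[float, float] = (-0.3, 0.0)
    n_concentrations: int = 10
    dilution_factor: float = 2.0
    hill: float = 1.0
    charge_class: ChargeClass = ChargeClass.anionic
    specificity_factors: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "charge_class", ChargeClass(self.charge_class))
        if self.n_chemicals < 1:
            raise ValidationError("n_chemicals must be >= 1")
        lo, hi = self.log_dlip_range
        if not lo < hi:
            raise ValidationError("log_dlip_range must be increasing")
        for idx, f in self.specificity_factors:
            if not 0 <= idx < self.n_chemicals:
                raise ValidationError(f"specificity factor index {idx} out of range")
            if f <= 0:
                raise ValidationError(f"specificity factor must be > 0, got {f}")


@dataclass(frozen=True)
class SyntheticData:
    chemicals: pd.DataFrame
    responses: pd.DataFrame
    ground_truth: pd.DataFrame

    def write(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("chemicals", "responses", "ground_truth"):
            path = directory / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, float_format="%.10E")
            paths[name] = path
        return paths


def generate_synthetic(
    scenario: SyntheticScenario, system: AssaySystem | None = None
) -> SyntheticData:
    """Draw a chemicals table, response curves, and ground truth.

    Identical scenarios (same seed) produce identical output frames.
    """
    if system is None:
        system = load_assay_systems()["generic"]
    rng = np.random.default_rng(scenario.seed)
    factors = dict(scenario.specificity_factors)
    lo, hi = scenario.log_dlip_range

    chem_rows, truth_rows, resp_frames = [], [], []
    for i in range(scenario.n_chemicals):
        name = f"SYN-{i:03d}"
        logd = float(rng.uniform(lo, hi))
        record = ChemicalRecord(
            name=name, charge_class=scenario.charge_class, log_dlip_w=logd
        )
        baseline_nom = ic10_nom_baseline_mechanistic(record, system)
        factor = factors.get(i, 1.0)
        ec10_effect = baseline_nom / factor
        f_slope = float(rng.uniform(*scenario.freundlich_slope_range))
        # anchor the concentration-dependent medium binding at the baseline
        # concentration so constant and Freundlich contexts agree there
        log_d_medium_ref = 2.5 + 0.3 * logd  # plausible magnitude, grows with hydrophobicity
        f_intercept = float(log_d_medium_ref - f_slope * np.log10(baseline_nom))

        chem_rows.append(
            {
                "name": name,
                "dtxsid": "",
                "charge_class": scenario.charge_class.value,
                "log_dlip_w": logd,
                "log_dbsa_w": "",
                "log_dsp_w": "",
                "n_fluorinated_carbons": "",
                "freundlich_slope_medium": f_slope,
                "freundlich_intercept_medium": f_intercept,
            }
        )
        truth_rows.append(
            {
                "name": name,
                "log_dlip_w": logd,
                "ic10_nom_baseline_true": baseline_nom,
                "specificity_factor": factor,
                "ic10_cytotoxicity_true": baseline_nom,
                "ec10_agonism_true": ec10_effect,
            }
        )
        for endpoint, ec_true in (
            (Endpoint.cytotoxicity, baseline_nom),
            (Endpoint.agonism, ec10_effect),
        ):
            ds = synthetic_4pl_dataset(
                chemical=name,
                ec10_true=ec_true,
                rng=rng,
                endpoint=endpoint,
                n_concentrations=scenario.n_concentrations,
                dilution_factor=scenario.dilution_factor,
                hill=scenario.hill,
                noise_sd_response=scenario.noise_sd_response,
            )
            resp_frames.append(
                pd.DataFrame(
                    {
                        "chemical": name,
                        "endpoint": endpoint.value,
                        "basis": "nominal",
                        "concentration_mol_L": ds.concentrations,
                        "response_percent": ds.responses,
                        "replicate": 1,
                    }
                )
            )

    return SyntheticData(
        chemicals=pd.DataFrame(chem_rows),
        responses=pd.concat(resp_frames, ignore_index=True),
        ground_truth=pd.DataFrame(truth_rows),
    )
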