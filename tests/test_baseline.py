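"""Baseline-toxicity prediction models: free, mechanistic and empirical."""

import dataclasses

import numpy as np
import pytest

from baselinetox import (
    ChargeClass,
    ChemicalRecord,
    EmpiricalFitParams,
    fit_empirical_model,
    hydrophilic_limit,
    ic10_free_baseline,
    ic10_nom_baseline_empirical,
    ic10_nom_baseline_mechanistic,
    mechanistic_curve,
    table2_lookup,
)
from baselinetox.errors import (
    InsufficientDataError,
    MissingDescriptorError,
    UnsupportedChargeClassError,
    ValidationError,
)
from baselinetox.massbalance import AssaySystem


def record(logd, charge_class="anionic"):
    return ChemicalRecord(name=f"x{logd}", charge_class=charge_class, log_dlip_w=logd)


class TestFreeBaseline:
    def test_unit_distribution_ratio_gives_membrane_burden(self):
        assert ic10_free_baseline(0.0) == pytest.approx(0.069)

    def test_pfba_value(self):
        assert ic10_free_baseline(1.00) == pytest.approx(6.9e-3)

    def test_strictly_decreasing_in_hydrophobicity(self):
        grid = np.linspace(-1, 7, 50)
        vals = [ic10_free_baseline(g) for g in grid]
        assert np.all(np.diff(vals) < 0)

    def test_hydrophilic_limit_equals_free_baseline(self):
        for logd in (0.0, 1.0, 3.5, 6.0):
            assert hydrophilic_limit(logd) == pytest.approx(
                ic10_free_baseline(logd), rel=1e-12
            )

    def test_hydrophilic_limit_close_to_mechanistic_for_hydrophilics(
        self, generic_system
    ):
        for cc in ("anionic", "neutral"):
            mech = ic10_nom_baseline_mechanistic(record(1.0, cc), generic_system)
            assert mech / hydrophilic_limit(1.0) < 1.5


class TestMechanisticModel:
    def test_zero_sorption_system_reduces_to_free_baseline(self):
        bare = AssaySystem(
            name="bare",
            v_medium=40e-6,
            v_cell=30e-9,
            vf_protein_medium=0.0,
            vf_lipid_medium=0.0,
            vf_protein_cell=0.0,
            vf_lipid_cell=0.0,
        )
        assert ic10_nom_baseline_mechanistic(record(3.0), bare) == pytest.approx(
            ic10_free_baseline(3.0), rel=1e-12
        )

    def test_binding_only_raises_nominal_dose(self, systems):
        grid = np.arange(0.0, 7.01, 0.5)
        for system in systems.values():
            for cc in ("anionic", "neutral"):
                for logd in grid:
                    assert ic10_nom_baseline_mechanistic(
                        record(logd, cc), system
                    ) >= ic10_free_baseline(logd) * (1 - 1e-12)

    def test_anionic_and_neutral_agree_when_hydrophilic_then_diverge(
        self, generic_system
    ):
        """The anionic and neutral models coincide within 25% at
        log D_lip/w = 1 and separate increasingly above 2, the anionic
        staying higher (stronger protein binding)."""
        def ratio(logd):
            return ic10_nom_baseline_mechanistic(
                record(logd, "anionic"), generic_system
            ) / ic10_nom_baseline_mechanistic(record(logd, "neutral"), generic_system)

        assert ratio(1.0) == pytest.approx(1.0, abs=0.25)
        ratios = [ratio(x) for x in (2.0, 3.0, 4.0, 5.0, 6.0)]
        assert ratios[0] > 1.25
        assert np.all(np.diff(ratios) > 0)
        assert ratios[-1] > 5

    def test_partially_charged_uses_neutral_model_with_override(self, generic_system):
        pfosa_like = record(4.94, "partially_charged")
        neutral = ic10_nom_baseline_mechanistic(record(4.94, "neutral"), generic_system)
        assert ic10_nom_baseline_mechanistic(
            pfosa_like, generic_system
        ) == pytest.approx(neutral, rel=1e-12)
        anionic = ic10_nom_baseline_mechanistic(
            pfosa_like, generic_system, charge_class_override="anionic"
        )
        assert anionic != pytest.approx(neutral, rel=0.01)

    def test_cationic_rejected(self, generic_system):
        with pytest.raises(UnsupportedChargeClassError):
            ic10_nom_baseline_mechanistic(record(3.0, "cationic"), generic_system)

    def test_missing_descriptor_rejected(self, generic_system):
        bare = ChemicalRecord(name="nodesc", charge_class="anionic")
        with pytest.raises(MissingDescriptorError):
            ic10_nom_baseline_mechanistic(bare, generic_system)


class TestEmpiricalModel:
    def test_shared_medium_assays_have_identical_curves(self):
        """AREc32 and AhR-CALUX used the same medium; their anionic
        empirical curves coincide."""
        p1 = table2_lookup("AREc32 (MCF7)", "anionic")
        p2 = table2_lookup("AhR (H4IIe)", "anionic")
        assert (p1.a, p1.b, p1.c) == (p2.a, p2.b, p2.c)
        grid = np.linspace(0, 7, 30)
        np.testing.assert_allclose(
            [ic10_nom_baseline_empirical(x, p1) for x in grid],
            [ic10_nom_baseline_empirical(x, p2) for x in grid],
        )

    def test_generic_empirical_tracks_mechanistic_within_factor_two(
        self, generic_system
    ):
        params = table2_lookup("generic", "anionic")
        grid, mech = mechanistic_curve(
            generic_system, "anionic", np.arange(1.0, 6.0001, 0.05)
        )
        emp = np.array([ic10_nom_baseline_empirical(x, params) for x in grid])
        factor = np.maximum(emp / mech, mech / emp)
        assert factor.max() < 2.0

    def test_generic_curves_collapse_to_hydrophilic_limit(self):
        """At log D_lip/w = 1 both generic empirical curves sit within a
        factor 2 of the sorption-free prediction, the common limit of the
        anionic and neutral models."""
        limit = hydrophilic_limit(1.0)
        for cc in ("anionic", "neutral"):
            value = ic10_nom_baseline_empirical(1.0, table2_lookup("generic", cc))
            assert 0.5 < value / limit < 2.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            EmpiricalFitParams(assay="x", charge_class="anionic", a=float("inf"), b=1, c=1)


class TestEmpiricalFit:
    @staticmethod
    def curve_from_params(a, b, c, grid):
        return [(x, 10 ** -(a + b * (1 - np.exp(-c * x)))) for x in grid]

    def test_self_consistent_recovery(self):
        grid = np.arange(0, 7.01, 0.25)
        fit = fit_empirical_model(self.curve_from_params(1.25, 4.76, 0.251, grid))
        assert fit.a == pytest.approx(1.25, rel=1e-6)
        assert fit.b == pytest.approx(4.76, rel=1e-6)
        assert fit.c == pytest.approx(0.251, rel=1e-6)
        assert fit.rms_residual < 1e-9

    def test_point_order_irrelevant(self, rng):
        grid = np.arange(0, 7.01, 0.25)
        pts = self.curve_from_params(1.2, 3.8, 0.26, grid)
        shuffled = list(pts)
        rng.shuffle(shuffled)
        f1 = fit_empirical_model(pts)
        f2 = fit_empirical_model(shuffled)
        assert (f1.a, f1.b, f1.c) == (f2.a, f2.b, f2.c)

    def test_refit_of_mechanistic_curve_matches_packaged_generic_row(
        self, generic_system
    ):
        """Fitting the exponential to the mechanistic generic-anionic curve
        reproduces the packaged generic empirical curve within a factor 2
        over the PFAS hydrophobicity range."""
        grid, mech = mechanistic_curve(generic_system, "anionic")
        fit = fit_empirical_model(list(zip(grid, mech)))
        assert fit.rms_residual < 0.1  # log10 units
        packaged = table2_lookup("generic", "anionic")
        eval_grid = np.arange(1.0, 6.0001, 0.1)
        fitted = np.array([ic10_nom_baseline_empirical(x, fit) for x in eval_grid])
        ref = np.array([ic10_nom_baseline_empirical(x, packaged) for x in eval_grid])
        assert np.maximum(fitted / ref, ref / fitted).max() < 2.0

    def test_insufficient_span_rejected(self):
        grid = np.arange(0, 2.01, 0.2)
        with pytest.raises(InsufficientDataError):
            fit_empirical_model(self.curve_from_params(1.2, 3.8, 0.26, grid))

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_empirical_model(self.curve_from_params(1.2, 3.8, 0.26, [0, 2, 4, 6]))


class TestSensitivity:
    def test_cell_compartment_negligible(self, generic_system):
        """Removing the cell compartment shifts generic predictions by <1%
        across the hydrophobicity range, for both charge classes."""
        no_cells = dataclasses.replace(generic_system, v_cell=0.0)
        grid = np.arange(0.0, 6.01, 0.2)
        for cc in ("anionic", "neutral"):
            _, with_cells = mechanistic_curve(generic_system, cc, grid)
            _, without = mechanistic_curve(no_cells, cc, grid)
            assert np.max(np.abs(with_cells - without) / with_cells) < 0.01

    def test_medium_lipid_matters_for_neutral_not_anionic(self, systems):
        """Zeroing the medium lipid fraction barely moves the anionic curve
        (protein binding dominates) but shifts the neutral curve by >10%
        at high hydrophobicity."""
        base = systems["generic_text"]  # 0.07 mL lipid per L medium
        no_lipid = dataclasses.replace(base, vf_lipid_medium=0.0)
        grid = np.arange(0.0, 6.01, 0.2)
        _, an = mechanistic_curve(base, "anionic", grid)
        _, an0 = mechanistic_curve(no_lipid, "anionic", grid)
        assert np.max(np.abs(an - an0) / an) < 0.10
        _, ne = mechanistic_curve(base, "neutral", grid)
        _, ne0 = mechanistic_curve(no_lipid, "neutral", grid)
        change = np.abs(ne - ne0) / ne
        assert change[grid > 4.0].max() > 0.10
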