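"""ODE assembly, Hill kinetics, simulation and steady-state checks."""

from __future__ import annotations

import numpy as np
import pytest

from memgrow import fixtures as fx
from memgrow.dynamics import (
    DoseSpec, RHSAssemblyError, build_rhs, hill, simulate, steady_state_check,
    transcription_flux,
)
from memgrow.model import RateLaw, TARInteraction

HOURS = 3600.0


class TestHill:
    @pytest.mark.parametrize("n", [1.0, 2.0, 4.0, 8.0])
    def test_half_maximal_at_K(self, n):
        assert hill(3.0, 3.0, n) == pytest.approx(0.5, rel=1e-12)

    def test_zero_at_zero(self):
        assert hill(0.0, 1.0, 4.0) == 0.0

    def test_two_K_n4(self):
        assert hill(2.0, 1.0, 4.0) == pytest.approx(16.0 / 17.0, rel=1e-12)

    def test_monotone_and_bounded(self):
        xs = np.linspace(0, 100, 500)
        hs = [hill(float(x), 5.0, 4.0) for x in xs]
        assert all(b >= a for a, b in zip(hs, hs[1:]))
        assert all(0 <= h < 1 for h in hs)

    def test_extreme_ratios_do_not_overflow(self):
        assert hill(1e200, 1e-100, 8.0) == pytest.approx(1.0)
        assert hill(1e-200, 1e100, 8.0) == pytest.approx(0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hill(1.0, 0.0, 4.0)
        with pytest.raises(ValueError):
            hill(1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            hill(-1.0, 1.0, 4.0)


class TestTranscriptionFlux:
    def test_no_tars_is_basal(self, base_model):
        g = base_model.genes["MYC"]
        flux = transcription_flux(g, [], {})
        assert flux == pytest.approx(
            g.copy_number * g.active_fraction * g.kTC_basal, rel=1e-12
        )

    def test_single_activator_at_half_max_is_1p5(self, base_model):
        g = base_model.genes["MYC"]
        tar = TARInteraction("STAT1_act", "MYC", "activator", K_A=2.0, n_A=4.0)
        flux = transcription_flux(g, [tar], {"STAT1_act": 2.0})
        assert flux == pytest.approx(
            1.5 * g.copy_number * g.active_fraction * g.kTC_basal, rel=1e-12
        )

    def test_saturating_repressor_kills_flux(self, base_model):
        g = base_model.genes["MYC"]
        tar = TARInteraction("STAT1_act", "MYC", "repressor", K_A=1.0, n_A=4.0)
        flux = transcription_flux(g, [tar], {"STAT1_act": 1e12})
        assert flux < 1e-12 * g.kTC_basal * g.copy_number

    def test_negative_concentration_rejected(self, base_model):
        g = base_model.genes["MYC"]
        tar = TARInteraction("STAT1_act", "MYC", "activator", K_A=1.0)
        with pytest.raises(ValueError):
            transcription_flux(g, [tar], {"STAT1_act": -0.1})


class TestBuildRHS:
    def test_unresolved_symbol_names_ratelaw(self, base_model):
        m = base_model.copy()
        m.ratelaws["vBAD"] = RateLaw("vBAD", "STAT1 -> ", "k_ghost*STAT1", {})
        with pytest.raises(RHSAssemblyError, match="vBAD"):
            build_rhs(m)

    def test_base_model_initial_state_is_fixed_point(self, base_model):
        rhs, y0, genes, species = build_rhs(base_model)
        dy = rhs(0.0, y0)
        assert float(np.max(np.abs(dy) / np.maximum(np.abs(y0), 1e-9))) < 1e-12


class TestSimulate:
    def test_no_ligand_steady_state_48h(self, expanded_candidate):
        """A consistently initialized expanded model drifts < 1% over 48 h
        without ligand — numerically confirming the analytic fixed point."""
        model, _ = expanded_candidate
        tc = simulate(model, 48 * HOURS)
        targets = []
        for g in model.genes:
            targets += [model.mrna_species(g), model.protein_species(g)]
        checks = steady_state_check(tc, targets, rel_tol=0.01)
        assert all(checks.values()), [k for k, v in checks.items() if not v]

    def test_ifng_dose_gives_transient_tf_activation(self, base_model):
        """IFNG stimulation: active TF rises from zero then decays under
        delayed negative feedback, and the induced mRNA follows."""
        tc = simulate(base_model, 48 * HOURS,
                      doses=[DoseSpec("IFNG", fx.IFNG_DOSE_NM)])
        for species in ("STAT1_act", "mRNA_SOCS1"):
            v = tc.get(species)
            assert v.max() > v[0]
            assert v[-1] < v.max()

    def test_output_resolution_does_not_change_solution(self, base_model):
        doses = [DoseSpec("IFNG", fx.IFNG_DOSE_NM)]
        coarse = simulate(base_model, 8 * HOURS, doses=doses, n_points=41)
        fine = simulate(base_model, 8 * HOURS, doses=doses, n_points=81)
        shared = np.isin(fine.times, coarse.times)
        ratio = fine.values[:, shared] / np.where(
            np.abs(coarse.values) > 0, coarse.values, 1.0
        )
        mask = np.abs(coarse.values) > 1e-12
        assert np.max(np.abs(ratio[mask] - 1.0)) < 1e-6

    def test_non_negativity_within_solver_tolerance(self, base_model):
        tc = simulate(base_model, 48 * HOURS,
                      doses=[DoseSpec("IFNG", fx.IFNG_DOSE_NM)], atol=1e-10)
        assert tc.values.min() >= -1e-9  # 10x solver atol

    def test_determinism_bitwise(self, base_model):
        doses = [DoseSpec("IFNG", fx.IFNG_DOSE_NM)]
        a = simulate(base_model, 4 * HOURS, doses=doses)
        b = simulate(base_model, 4 * HOURS, doses=doses)
        assert np.array_equal(a.values, b.values)

    def test_unknown_dose_species_rejected(self, base_model):
        with pytest.raises(ValueError, match="GHOSTLIGAND"):
            simulate(base_model, HOURS, doses=[DoseSpec("GHOSTLIGAND", 1.0)])

    def test_nonpositive_duration_rejected(self, base_model):
        with pytest.raises(ValueError):
            simulate(base_model, 0.0)

    def test_provenance_records_settings(self, base_model):
        tc = simulate(base_model, HOURS, doses=[DoseSpec("EGF", 1.5625)])
        assert tc.provenance["doses"] == [("EGF", 1.5625, 0.0)]
        assert tc.provenance["solver"]["method"] == "BDF"
        assert "model_hash" in tc.provenance


class TestSteadyStateCheck:
    def _tc(self, values):
        from memgrow.dynamics import TimeCourse
        arr = np.asarray(values, dtype=float)[None, :]
        return TimeCourse(np.linspace(0, 1, arr.shape[1]), ["X"], arr)

    def test_constant_trajectory_passes(self):
        assert steady_state_check(self._tc([5, 5, 5]), ["X"])["X"]

    def test_fast_decay_fails(self):
        assert not steady_state_check(self._tc([1.0, 0.1, 0.01]), ["X"])["X"]

    def test_boundary_drift_inclusive(self):
        # drift exactly equal to rel_tol passes (binary-exact values)
        tc = self._tc([1.0, 1.0, 1.0078125])
        assert steady_state_check(tc, ["X"], rel_tol=0.0078125)["X"]
        assert not steady_state_check(tc, ["X"], rel_tol=0.0078)["X"]
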