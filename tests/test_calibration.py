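"""Grid construction, SSE, and sequential grid-search fitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from memgrow import fixtures as fx
from memgrow.calibration import (
    FitResult, GridSpec, enumerate_free_parameters, fit_KA, fit_basal_rates,
    log_grid, sse,
)
from memgrow.dynamics import TimeCourse, simulate

GRID_STEP = 3.0 / 14  # log10 spacing of the 15-point / 3-decade grid


class TestLogGrid:
    def test_default_span(self):
        g = log_grid(GridSpec(1.0))
        assert len(g) == 15
        assert g[0] == pytest.approx(10 ** -1.5, rel=1e-12)
        assert g[-1] == pytest.approx(10 ** 1.5, rel=1e-12)
        assert g[7] == pytest.approx(1.0, rel=1e-12)  # default at center

    def test_two_points_are_endpoints(self):
        g = log_grid(GridSpec(2.0, points=2))
        assert g == pytest.approx([2 * 10 ** -1.5, 2 * 10 ** 1.5], rel=1e-12)

    def test_log_symmetry(self):
        g = log_grid(GridSpec(3.7, decades=3, points=15))
        for i in range(len(g)):
            assert g[i] * g[len(g) - 1 - i] == pytest.approx(3.7 ** 2, rel=1e-10)

    def test_strictly_increasing(self):
        g = log_grid(GridSpec(0.01, decades=4, points=9))
        assert np.all(np.diff(g) > 0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(1.0, points=1)
        with pytest.raises(ValueError):
            GridSpec(1.0, decades=0)
        with pytest.raises(ValueError):
            GridSpec(0.0)


class TestSSE:
    def _tc(self):
        t = np.linspace(0, 10, 11)
        vals = np.vstack([2 * np.ones_like(t), 1 + t])
        return TimeCourse(t, ["A", "B"], vals)

    def test_exact_match_is_zero(self):
        tc = self._tc()
        data = pd.DataFrame({"A": [1.0, 1.0]}, index=[0.0, 5.0])
        assert sse(tc, data, {}) == 0.0

    def test_single_point_difference_squared(self):
        tc = self._tc()
        data = pd.DataFrame({"A": [3.0]}, index=[4.0])
        # simulated fold change is 1, data 3 -> (1-3)^2 = 4
        assert sse(tc, data, {}) == pytest.approx(4.0)

    def test_additive_over_tables(self):
        # per-condition SSEs sum: (2-3)^2 + (6-1)^2 = 26 on raw values
        tc = self._tc()
        d1 = pd.DataFrame({"A": [3.0]}, index=[1.0])
        d2 = pd.DataFrame({"B": [1.0]}, index=[5.0])
        total = sse(tc, d1, {}, fold_change=False) + sse(tc, d2, {}, fold_change=False)
        assert total == pytest.approx(26.0)

    def test_interpolation_between_output_points(self):
        tc = self._tc()
        data = pd.DataFrame({"B": [3.5]}, index=[2.5])
        assert sse(tc, data, {}, fold_change=False) == pytest.approx(0.0, abs=1e-12)

    def test_data_outside_range_rejected(self):
        tc = self._tc()
        data = pd.DataFrame({"A": [1.0]}, index=[99.0])
        with pytest.raises(ValueError):
            sse(tc, data, {})

    def test_mapping_renames_observable(self):
        tc = self._tc()
        data = pd.DataFrame({"obsA": [1.0]}, index=[0.0])
        assert sse(tc, data, {"obsA": "A"}) == 0.0


class TestFitBasalRates:
    def test_consistent_gene_is_skipped(self, small_expanded):
        model, report, net = small_expanded
        new_genes = [p["id"] for p in report.provenance if p["entity"] == "gene"]
        fitted, results = fit_basal_rates(model, new_genes, duration_s=24 * 3600.0)
        assert all(r.skipped for r in results)
        assert fitted.equals(model)

    def test_perturbed_gene_recovered_within_one_grid_step(self, small_expanded):
        model, report, net = small_expanded
        gene = [p["id"] for p in report.provenance if p["entity"] == "gene"][0]
        broken = model.copy()
        true_val = broken.genes[gene].kTC_basal
        broken.genes[gene].kTC_basal = true_val * 10.0
        fitted, results = fit_basal_rates(broken, [gene], duration_s=24 * 3600.0)
        res = results[0]
        assert not res.skipped
        assert abs(np.log10(res.chosen / true_val)) <= GRID_STEP + 1e-9

    def test_unknown_gene_rejected(self, small_expanded):
        model, _, _ = small_expanded
        with pytest.raises(ValueError):
            fit_basal_rates(model, ["NOSUCHGENE"])


class TestFitKA:
    def test_shifted_parameter_recovered_or_compensated(self, recovery_fit):
        """One K_A at a time shifted two grid steps off default: the
        sequential fit either recovers it within one grid step or finds a
        compensated parameter set reproducing the noise-free data to
        <= 0.05 RMS per fold-change point (the sloppy-direction case)."""
        for exp in recovery_fit["experiments"]:
            rms = np.sqrt(exp["final_sse"] / exp["n_data_points"])
            assert exp["grid_step_error"] <= 1.0 + 1e-9 or rms <= 0.05, (
                exp["parameter"], exp["grid_step_error"], rms)

    def test_fit_improves_on_defaults(self, recovery_fit):
        for exp in recovery_fit["experiments"]:
            assert exp["final_sse"] <= exp["initial_sse"] + 1e-15

    def test_coordinate_descent_monotone_chain(self, recovery_fit):
        """The total SSE never increases across the fit sequence: each
        step's minimum equals the next step's incumbent score, which its
        own minimum cannot exceed."""
        for exp in recovery_fit["experiments"]:
            fits = exp["fits"]
            center = len(fits[0].grid) // 2
            for prev, nxt in zip(fits[:-1], fits[1:]):
                assert nxt.objective[center] == pytest.approx(
                    min(prev.objective), rel=1e-9, abs=1e-12)
                assert min(nxt.objective) <= nxt.objective[center] + 1e-15

    def test_chosen_value_on_grid(self, recovery_fit):
        for exp in recovery_fit["experiments"]:
            for f in exp["fits"]:
                assert any(np.isclose(f.chosen, g, rtol=1e-12) for g in f.grid)

    def test_full_fit_deterministic(self, small_expanded):
        from memgrow.calibration import fit_KA

        model, report, net = small_expanded
        keys = [tuple(p["id"].split("__"))
                for p in report.provenance if p["entity"] == "tar"][:1]
        conds = fx.standard_conditions()
        obs = {model.mrna_species("STAT1"): model.mrna_species("STAT1")}
        data = fx.make_ground_truth_timecourses(model, conds, obs)
        a = fit_KA(model, data, conds, mapping={}, order=keys)[1]
        b = fit_KA(model, data, conds, mapping={}, order=keys)[1]
        assert [r.to_dict() for r in a] == [r.to_dict() for r in b]

    def test_mismatched_conditions_rejected(self, small_expanded):
        model, _, _ = small_expanded
        with pytest.raises(ValueError):
            fit_KA(model, {"egf": pd.DataFrame()}, {"other": []}, mapping={})


class TestFreeParameterInventory:
    def test_candidate_expansion_counts_43(self, expanded_candidate):
        """27 half-maximal constants + 16 degradation rates (mRNA and
        protein for each of 8 new genes)."""
        model, report = expanded_candidate
        params = enumerate_free_parameters(model, report)
        assert len(params) == 43
        assert sum(p.startswith("K_A[") for p in params) == 27
        assert sum(p.startswith("kTCd[") for p in params) == 8
        assert sum(p.startswith("kTLd[") for p in params) == 8
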