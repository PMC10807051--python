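"""Expansion engine: gene modules, TAR creation, count arithmetic."""

from __future__ import annotations

import pytest

from memgrow import fixtures as fx
from memgrow.associations import AssociationNetwork, network_from_edges
from memgrow.expansion import (
    ExpansionReport, OmicsRecord, edges_to_tars, expand_model, init_KA,
    make_gene_entities, read_omics_table, write_omics_table,
)


class TestExpansionCounts:
    def test_candidate_expansion_deltas(self, expanded_candidate, base_model):
        """9 genes / 14 connections against a base containing STAT1:
        +8 genes, +16 species, +16 rate laws, +27 regulations."""
        model, report = expanded_candidate
        assert report.genes_added == 8
        assert report.species_added == 16
        assert report.ratelaws_added == 16
        assert report.tars_added == 27
        assert report.skipped_genes == ["STAT1"]
        assert model.counts["genes"] - base_model.counts["genes"] == 8
        assert model.counts["species"] - base_model.counts["species"] == 16
        assert model.counts["ratelaws"] - base_model.counts["ratelaws"] == 16
        assert model.counts["tars"] - base_model.counts["tars"] == 27

    def test_self_edge_collapses_one_of_28_candidates(self, expanded_candidate):
        _, report = expanded_candidate
        assert report.collapsed_tars == ["IRF1->IRF1(activator)"]
        assert report.dropped_self_tars == []

    def test_autoregulation_disabled_drops_self(self, base_model, candidate_net,
                                                candidate_omics):
        model, report = expand_model(
            base_model, candidate_net, candidate_omics, allow_autoregulation=False
        )
        assert report.tars_added == 26
        assert report.dropped_self_tars == ["IRF1->IRF1(activator)"]

    def test_every_added_entity_has_provenance(self, expanded_candidate):
        _, report = expanded_candidate
        genes = [p for p in report.provenance if p["entity"] == "gene"]
        tars = [p for p in report.provenance if p["entity"] == "tar"]
        assert len(genes) == report.genes_added
        assert len(tars) == report.tars_added

    def test_empty_network_zero_delta(self, base_model):
        model, report = expand_model(base_model, AssociationNetwork(), {})
        assert (report.genes_added, report.species_added,
                report.ratelaws_added, report.tars_added) == (0, 0, 0, 0)
        assert model.equals(base_model)

    def test_idempotent_second_expansion(self, expanded_candidate, candidate_net,
                                         candidate_omics):
        model, _ = expanded_candidate
        again, report = expand_model(model, candidate_net, candidate_omics)
        assert (report.genes_added, report.species_added,
                report.ratelaws_added, report.tars_added) == (0, 0, 0, 0)

    def test_complete_omics_means_no_defaults(self, expanded_candidate):
        _, report = expanded_candidate
        # only the zero-concentration activated-TF regulator takes the
        # documented K_A fallback; no gene-level parameter is defaulted
        assert all(d.startswith("K_A[STAT1_act") for d in report.defaults_used)


class TestMakeGeneEntities:
    def test_full_omics_adds_two_species_two_ratelaws(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        rec = OmicsRecord("NEWG", 50.0, 12.0, 5.0, 30.0, 2.0)
        assert make_gene_entities("NEWG", rec, m, rep)
        assert rep.species_added == 2 and rep.ratelaws_added == 2
        assert "mRNA_NEWG" in m.species and "NEWG" in m.species
        m.validate()

    def test_phospho_measurement_adds_third_species(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        rec = OmicsRecord("PHOS", 50.0, 12.0, 5.0, 30.0, 2.0, phospho_nM=3.0)
        make_gene_entities("PHOS", rec, m, rep)
        assert rep.species_added == 3
        assert "pPHOS" in m.species

    def test_existing_gene_is_noop(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        assert not make_gene_entities("STAT1", None, m, rep)
        assert rep.genes_added == 0 and rep.skipped_genes == ["STAT1"]

    def test_missing_half_life_uses_base_mean(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        rec = OmicsRecord("NOHL", 50.0, 12.0, None, None, 2.0)
        make_gene_entities("NOHL", rec, m, rep)
        assert "NOHL:kTCd" in rep.defaults_used
        base_mean = sum(g.kTCd for g in base_model.genes.values()) / len(base_model.genes)
        assert m.genes["NOHL"].kTCd == pytest.approx(base_mean)


class TestEdgesToTars:
    def test_one_edge_makes_two_directed_tars(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        for g in ("GA", "GB"):
            make_gene_entities(g, OmicsRecord(g, 50, 10, 5, 30, 2), m, rep)
        net = network_from_edges([("GA", "GB", 0.8)])
        tars = edges_to_tars(net, m, rep)
        assert {(t.regulator, t.target_gene, t.sign) for t in tars} == {
            ("GA", "GB", "activator"), ("GB", "GA", "activator"),
        }

    def test_negative_edge_makes_repressors(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        for g in ("GA", "GB"):
            make_gene_entities(g, OmicsRecord(g, 50, 10, 5, 30, 2), m, rep)
        tars = edges_to_tars(network_from_edges([("GA", "GB", -0.2)]), m, rep)
        assert all(t.sign == "repressor" for t in tars)

    def test_ka_initialized_to_half_regulator_concentration(self, base_model):
        m = base_model.copy()
        rep = ExpansionReport()
        make_gene_entities("GA", OmicsRecord("GA", 50, 10.0, 5, 30, 2), m, rep)
        make_gene_entities("GB", OmicsRecord("GB", 50, 24.0, 5, 30, 2), m, rep)
        tars = edges_to_tars(network_from_edges([("GA", "GB", 1.0)]), m, rep)
        ka = {t.regulator: t.K_A for t in tars}
        assert ka["GA"] == pytest.approx(5.0)
        assert ka["GB"] == pytest.approx(12.0)
        assert all(t.n_A == 4.0 for t in tars)

    def test_missing_endpoint_gene_is_error(self, base_model):
        m = base_model.copy()
        with pytest.raises(ValueError, match="GHOST"):
            edges_to_tars(network_from_edges([("STAT1", "GHOST", 1.0)]), m)


class TestInitKA:
    def test_half_rule(self):
        assert init_KA(10.0) == (5.0, False)

    def test_zero_concentration_takes_fallback(self):
        ka, used = init_KA(0.0, fallback_nm=8.0)
        assert ka == 4.0 and used

    def test_linear_scaling(self):
        assert init_KA(3.7)[0] * 10 == pytest.approx(init_KA(37.0)[0])

    def test_zero_without_fallback_is_error(self):
        with pytest.raises(ValueError):
            init_KA(0.0)


class TestRebalancing:
    def test_rebalanced_initial_state_is_fixed_point(self, expanded_candidate):
        """After expansion the omics-derived state must be an exact fixed
        point: every species derivative vanishes at t=0."""
        import numpy as np
        from memgrow.dynamics import build_rhs

        model, _ = expanded_candidate
        rhs, y0, genes, species = build_rhs(model)
        dy = rhs(0.0, y0)
        scale = np.maximum(np.abs(y0), 1e-9)
        assert float(np.max(np.abs(dy) / scale)) < 1e-12

    def test_without_rebalance_raw_formula_kept(self, base_model, candidate_net,
                                                  candidate_omics):
        from memgrow import rates
        model, _ = expand_model(
            base_model, candidate_net, candidate_omics, rebalance_basal=False
        )
        rec = candidate_omics["ACSL5"]
        g = model.genes["ACSL5"]
        expected = rates.basal_transcription_rate(
            rates.mrna_degradation_rate(rec.mRNA_half_life_h),
            rec.mRNA_mpc, g.kG_in, g.kG_ac, rec.copy_number,
        )
        assert g.kTC_basal == pytest.approx(expected, rel=1e-12)


class TestOmicsTableIO:
    def test_round_trip(self, tmp_path, candidate_omics):
        p = tmp_path / "omics.tsv"
        write_omics_table(candidate_omics, p)
        back = read_omics_table(p)
        assert set(back) == set(candidate_omics)
        for g, rec in candidate_omics.items():
            assert back[g] == rec
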