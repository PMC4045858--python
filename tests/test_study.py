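import json

import numpy as np
import pytest

from gluconet import (MetabolicModel, Metabolite, Reaction, StudyConfig,
                      add_gluconate, apply_study_constraints, close_gluconate,
                      open_gluconate, fba, fva, element_imbalance,
                      find_sodium_pump, robustness, relaxation_scan,
                      shadow_comparison, unique_species_affect_counts,
                      run_study, make_toy_network, ToyNetworkSpec)
from gluconet.study import (ExtensionError, GLUCONATE_EXCHANGE,
                            GLUCONATE_TRANSPORT, GLUCONOKINASE)


@pytest.fixture(scope="module")
def constrained(toy_model_module):
    return apply_study_constraints(toy_model_module, StudyConfig())


@pytest.fixture(scope="module")
def toy_model_module():
    return make_toy_network()


# Toy-scale analytical expectations, derived from the generator's
# constraint arithmetic (see the fixture construction): the optimum is
# reached once non-oxidative recycling saturates, and collapses once
# the passive CO2 outlet does.
SPEC = ToyNetworkSpec()
G6PD_MIN = SPEC.hms_split_fraction_bounds[0] * SPEC.glucose_uptake   # 0.056
UPTAKE_AT_MAX = 6 * SPEC.recycle_cap - G6PD_MIN                      # 0.124
UPTAKE_AT_DECLINE = SPEC.capped_exchange_bound - G6PD_MIN            # 0.444


class TestAddGluconate:
    def test_adds_three_reactions_and_two_species(self):
        base = make_toy_network(ToyNetworkSpec(include_gluconate_branch=False))
        extended = add_gluconate(base)
        assert len(extended.reactions) == len(base.reactions) + 3
        assert len(extended.metabolites) == len(base.metabolites) + 2
        for rid in (GLUCONATE_EXCHANGE, GLUCONATE_TRANSPORT, GLUCONOKINASE):
            assert rid in extended.reaction_ids
        assert extended.get_reaction(GLUCONATE_EXCHANGE).is_exchange
        # created closed to uptake: the baseline condition
        assert extended.get_reaction(GLUCONATE_EXCHANGE).lower_bound == 0.0

    def test_applying_twice_raises(self, toy_model_module):
        with pytest.raises(ExtensionError, match="applied twice"):
            add_gluconate(toy_model_module)

    def test_missing_entry_point_is_named(self, chain_model):
        with pytest.raises(ExtensionError, match="6pgc_c"):
            add_gluconate(chain_model)

    def test_gluconokinase_is_carbon_and_phosphorus_balanced(
            self, toy_model_module):
        balance = element_imbalance(toy_model_module, GLUCONOKINASE,
                                    elements=("C", "P", "H", "O", "N"))
        assert all(abs(v) < 1e-12 for v in balance.values()), balance
        assert element_imbalance(toy_model_module, GLUCONATE_TRANSPORT) == \
            {"C": 0.0, "P": 0.0}
        assert element_imbalance(toy_model_module, GLUCONATE_EXCHANGE) == {}

    def test_preexisting_content_untouched(self):
        base = make_toy_network(ToyNetworkSpec(include_gluconate_branch=False))
        extended = add_gluconate(base)
        for rxn in base.reactions:
            ext = extended.get_reaction(rxn.id)
            assert ext.stoichiometry == rxn.stoichiometry
            assert (ext.lower_bound, ext.upper_bound) == \
                (rxn.lower_bound, rxn.upper_bound)

    def test_closed_extension_reproduces_unextended_objective(self):
        base = make_toy_network(ToyNetworkSpec(include_gluconate_branch=False))
        extended = close_gluconate(add_gluconate(base))
        assert fba(extended).objective_value == pytest.approx(
            fba(base).objective_value, abs=1e-6)


class TestConstraints:
    def test_glucose_fixed_and_hms_floated(self, constrained):
        glc = constrained.get_reaction("EX_glc_D_e")
        assert (glc.lower_bound, glc.upper_bound) == (-1.12, -1.12)
        g6pd = constrained.get_reaction("G6PDH")
        assert g6pd.lower_bound == pytest.approx(0.05 * 1.12)
        assert g6pd.upper_bound == pytest.approx(0.10 * 1.12)
        assert constrained.objective == {"NaKt": 1.0}

    def test_pump_found_by_stoichiometry(self):
        model = MetabolicModel(
            metabolites=[Metabolite(i, compartment=i.rsplit("_", 1)[-1])
                         for i in ("atp_c", "adp_c", "pi_c", "na1_c", "na1_e",
                                   "k_c", "k_e", "h2o_c")],
            reactions=[Reaction("R_pump_anon", {
                "atp_c": -1, "h2o_c": -1, "na1_c": -3, "k_e": -2,
                "adp_c": 1, "pi_c": 1, "na1_e": 3, "k_c": 2}, 0, 1000)],
        )
        assert find_sodium_pump(model) == "R_pump_anon"

    def test_config_validation(self):
        with pytest.raises(ValueError, match="glucose_uptake"):
            StudyConfig(glucose_uptake=-1.0)
        with pytest.raises(ValueError, match="sweep_grid"):
            StudyConfig(sweep_grid=(1.0, 0.5))


class TestGluconateEffect:
    def test_opening_gluconate_raises_the_optimum(self, constrained):
        closed = fba(close_gluconate(constrained)).objective_value
        opened = fba(open_gluconate(constrained)).objective_value
        assert opened > closed + 1e-6
        assert closed == pytest.approx(2.19, abs=1e-6)
        assert opened == pytest.approx(2.398, abs=1e-6)

    def test_gluconokinase_span_at_pinned_optimum(self, constrained):
        """With the objective pinned, gluconokinase is forced to carry
        flux: its FVA minimum is strictly positive and the extrema
        match the generator's saturation arithmetic."""
        result = fva(open_gluconate(constrained), fix_objective_fraction=1.0)
        assert result.loc[GLUCONOKINASE, "minimum"] == pytest.approx(
            UPTAKE_AT_MAX, abs=1e-6)
        assert result.loc[GLUCONOKINASE, "maximum"] == pytest.approx(
            UPTAKE_AT_DECLINE, abs=1e-6)


@pytest.fixture(scope="module")
def curve(constrained):
    cfg = StudyConfig(sweep_grid=tuple(np.round(np.arange(0, 1.2001, 0.02), 3)))
    return robustness(constrained, cfg)


class TestRobustness:
    def test_origin_matches_closed_baseline(self, constrained, curve):
        closed = fba(close_gluconate(constrained)).objective_value
        assert curve.objective[0] == pytest.approx(closed, abs=1e-6)

    def test_rise_plateau_drop_shape(self, curve):
        z = np.array([v for v in curve.objective if v is not None])
        u = np.array([x for x, v in zip(curve.uptake, curve.objective)
                      if v is not None])
        zmax = z.max()
        rising = u < UPTAKE_AT_MAX - 1e-9
        plateau = (u > UPTAKE_AT_MAX + 1e-9) & (u < UPTAKE_AT_DECLINE + 1e-9)
        falling = u > UPTAKE_AT_DECLINE + 1e-9
        assert np.all(np.diff(z[rising]) > 0)
        assert np.allclose(z[plateau], zmax, atol=1e-6)
        assert np.all(np.diff(z[falling]) < 0)

    def test_breakpoints_match_construction(self, curve):
        assert curve.first_max_uptake == pytest.approx(UPTAKE_AT_MAX, abs=2e-3)
        assert curve.decline_uptake == pytest.approx(UPTAKE_AT_DECLINE,
                                                     abs=2e-3)

    def test_piecewise_linear_segments(self, constrained):
        """LP parametric property: between breakpoints the objective is
        linear in the forced uptake (checked on a dense sub-grid)."""
        grid = tuple(np.round(np.arange(0.0, 0.0801, 0.01), 4))
        cfg = StudyConfig(sweep_grid=grid, refine_breakpoints=False)
        z = robustness(constrained, cfg).objective
        slopes = np.diff(z) / 0.01
        assert np.allclose(slopes, slopes[0], atol=1e-6)

    def test_forced_uptake_past_collapse_is_recorded_infeasible(
            self, constrained):
        cfg = StudyConfig(sweep_grid=(0.0, 0.2, 5.0),
                          refine_breakpoints=False)
        curve = robustness(constrained, cfg)
        assert curve.status[-1] == "infeasible"
        assert curve.objective[-1] is None
        assert curve.objective[1] is not None


class TestRelaxationScan:
    def test_already_relaxed_exchange_has_no_effect(self, constrained):
        scan = relaxation_scan(close_gluconate(constrained))
        assert scan.loc["EX_co2_e", "delta_objective"] == pytest.approx(0.0,
                                                                        abs=1e-9)
        assert not scan.loc["EX_co2_e", "affects"]

    def test_relaxation_never_decreases_the_optimum(self, constrained):
        for condition in (close_gluconate(constrained),
                          open_gluconate(constrained)):
            scan = relaxation_scan(condition)
            deltas = scan["delta_objective"].dropna()
            assert (deltas >= -1e-9).all()

    def test_affecting_set_shrinks_when_gluconate_opens(self, constrained):
        closed_scan = relaxation_scan(close_gluconate(constrained))
        open_scan = relaxation_scan(open_gluconate(constrained))
        affects_closed = set(closed_scan.index[closed_scan["affects"]])
        affects_open = set(open_scan.index[open_scan["affects"]])
        # closed: glucose supply and the (closed) gluconate exchange
        # both matter; open: only glucose supply remains limiting
        assert affects_closed == {"EX_glc_D_e", GLUCONATE_EXCHANGE}
        assert affects_open == {"EX_glc_D_e"}


class TestShadowComparison:
    def test_trivial_unaffecting_metabolite(self, constrained):
        table = shadow_comparison(close_gluconate(constrained),
                                  open_gluconate(constrained))
        row = table.loc["pyr_e"]    # free secretion: never limiting
        assert row["sp_without"] == 0.0 and row["sp_with"] == 0.0
        assert not row["affects_without"] and not row["affects_with"]

    def test_affecting_count_drops_and_gluconate_stops_limiting(
            self, constrained):
        """Opening the gluconate feed relieves limitations: fewer
        species constrain the pump, and gluconate itself (limiting
        while unavailable) stops being so."""
        table = shadow_comparison(close_gluconate(constrained),
                                  open_gluconate(constrained))
        counts = unique_species_affect_counts(table, open_gluconate(constrained))
        assert counts["affecting_with"] < counts["affecting_without"]
        assert table.loc["glcn_e", "affects_without"]
        assert not table.loc["glcn_e", "affects_with"]

    def test_infeasible_condition_is_named(self, constrained):
        broken = close_gluconate(constrained)
        broken.set_bounds("EX_glc_D_e", 0.0, 0.0)   # starve the network
        from gluconet import InfeasibleModelError
        with pytest.raises(InfeasibleModelError, match="closed-gluconate"):
            shadow_comparison(broken, open_gluconate(constrained))


class TestRunStudy:
    def test_artifacts_and_internal_consistency(self, toy_model_module,
                                                tmp_path):
        cfg = StudyConfig(
            sweep_grid=tuple(np.round(np.arange(0, 0.8001, 0.05), 3)))
        report = run_study(toy_model_module, cfg, outdir=str(tmp_path))
        for name in ("fva_before.tsv", "fva_after.tsv", "changes.tsv",
                     "robustness.tsv", "shadow.tsv", "relaxation.tsv",
                     "summary.json"):
            assert (tmp_path / name).exists(), name
        summary = json.loads((tmp_path / "summary.json").read_text())
        counts = summary["change_counts"]
        assert (counts["unchanged"] + counts["changed"] + counts["activated"]
                + counts["deactivated"] == counts["total"]
                == len(toy_model_module.reactions))
        assert summary["objective_gain"] == pytest.approx(0.208, abs=1e-6)
        assert summary["gntk_flux_min"] == pytest.approx(UPTAKE_AT_MAX,
                                                         abs=1e-6)
        assert summary["gntk_flux_max"] == pytest.approx(UPTAKE_AT_DECLINE,
                                                         abs=1e-6)
        assert summary["relaxation_affecting_closed"] == 2
        assert summary["relaxation_affecting_open"] == 1

    def test_unextended_model_is_extended_automatically(self, tmp_path):
        base = make_toy_network(ToyNetworkSpec(include_gluconate_branch=False))
        cfg = StudyConfig(sweep_grid=(0.0, 0.1, 0.2),
                          refine_breakpoints=False)
        report = run_study(base, cfg)
        assert report["summary"]["objective_gain"] > 0

    def test_closed_exchange_config_changes_nothing(self, toy_model_module):
        """With the gluconate exchange kept shut in both conditions the
        comparison is before==after: nothing activates."""
        cfg = StudyConfig(gluconate_exchange_bounds=(0.0, 1000.0),
                          sweep_grid=(0.0,), refine_breakpoints=False)
        report = run_study(toy_model_module, cfg)
        counts = report["summary"]["change_counts"]
        assert counts["activated"] == 0 and counts["changed"] == 0
        assert report["summary"]["objective_gain"] == pytest.approx(0.0,
                                                                    abs=1e-9)
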