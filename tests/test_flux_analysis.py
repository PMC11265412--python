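"""FBA/FVA correctness against enumeration oracles, and phenotype calls."""

import numpy as np
import pytest

from pangem.flux_analysis import (
    carbon_source_growth,
    core_fluxome,
    fba,
    fermentation_profile,
    fva,
    single_omission_essentiality,
)
from pangem.model import GPRRule, Medium
from pangem.synthetic import strain_medium

from conftest import (
    brute_force_fba,
    linear_chain_model,
    make_network,
    random_toy_network,
)


class TestFBA:
    def test_linear_chain_optimum_is_uptake(self):
        solution = fba(linear_chain_model(uptake=10.0))
        assert solution.status == "optimal"
        assert solution.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_closed_model_zero_growth(self):
        model = linear_chain_model(uptake=0.0)
        solution = fba(model)
        assert solution.status == "optimal"
        assert solution.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_matches_vertex_enumeration_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            model = random_toy_network(rng)
            expected, _ = brute_force_fba(model, "r0")
            solution = fba(model)
            assert solution.status == "optimal"
            assert solution.objective_value == pytest.approx(expected, abs=1e-6)

    def test_synthetic_growth_matches_closed_form(self, strain_models, medium, population):
        """ATP-limited design: optimum growth = scale - NGAM/20, exactly."""
        truth = population[3]
        for strain, model in list(strain_models.items())[::5]:
            med = strain_medium(medium, truth.uptake_scale[strain])
            solution = fba(model, med)
            assert solution.objective_value == pytest.approx(
                truth.growth_rate[strain], abs=1e-8)


class TestFVA:
    def test_chain_pinned_at_full_optimum(self):
        ranges = fva(linear_chain_model(uptake=10.0), fraction_of_optimum=1.0).ranges
        for rid in ("EX_A", "T_A", "R1", "BIOMASS"):
            lo, hi = ranges[rid]
            assert (abs(lo), abs(hi)) == (pytest.approx(10.0, abs=1e-7),) * 2

    def test_disconnected_reaction_pinned_to_zero(self):
        model = linear_chain_model()
        model.reactions["DEAD"] = model.reactions["R1"].copy()
        model.reactions["DEAD"].id = "DEAD"
        model.reactions["DEAD"].stoichiometry = {"X": -1.0, "Y": 1.0}
        lo, hi = fva(model).ranges["DEAD"]
        assert lo == pytest.approx(0.0, abs=1e-9) and hi == pytest.approx(0.0, abs=1e-9)

    def test_relaxed_fraction_ranges_nest(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            model = random_toy_network(rng)
            tight = fva(model, fraction_of_optimum=1.0).ranges
            loose = fva(model, fraction_of_optimum=0.5).ranges
            for rid in tight:
                assert loose[rid][0] <= tight[rid][0] + 1e-6
                assert loose[rid][1] >= tight[rid][1] - 1e-6

    def test_ranges_bracket_fba_fluxes(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            model = random_toy_network(rng)
            solution = fba(model)
            ranges = fva(model, fraction_of_optimum=1.0).ranges
            for rid, flux in solution.fluxes.items():
                lo, hi = ranges[rid]
                assert lo - 1e-6 <= flux <= hi + 1e-6

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            fva(linear_chain_model(), fraction_of_optimum=1.5)


class TestCarbonSourceGrowth:
    def test_species_specific_catabolism(self, strain_models, medium, population):
        truth = population[3]
        strains = list(strain_models)[::7]
        for strain in strains:
            model = strain_models[strain]
            for sp, exchange in truth.carbon_source_of.items():
                predicted = carbon_source_growth(model, medium, exchange, "EX_glc_e")
                assert predicted == truth.csource_growth[strain][sp]

    def test_missing_exchange_immediately_false(self, strain_models, medium):
        model = next(iter(strain_models.values())).copy()
        del model.reactions["EX_cs_sp1_e"]
        assert carbon_source_growth(model, medium, "EX_cs_sp1_e", "EX_glc_e") is False

    def test_rate_exactly_at_threshold_is_no_growth(self):
        # unit yield and uptake 0.01 put the optimum exactly at the threshold
        model = linear_chain_model(uptake=5.0)
        medium = Medium({"EX_A": 5.0})
        assert carbon_source_growth(model, medium, "EX_A", "EX_A",
                                    uptake=0.01, ngam=0.0) is False
        assert carbon_source_growth(model, medium, "EX_A", "EX_A",
                                    uptake=0.02, ngam=0.0) is True


class TestEssentiality:
    def test_planted_auxotrophies_recovered(self, strain_models, medium, population):
        truth = population[3]
        for strain in list(strain_models)[::5]:
            profile = single_omission_essentiality(strain_models[strain], medium)
            assert profile.essential == truth.essential_components[strain]

    def test_statelessness(self, strain_models, medium):
        strain, model = next(iter(strain_models.items()))
        first = single_omission_essentiality(model, medium)
        second = single_omission_essentiality(model.copy(), medium)
        assert first.verdicts == second.verdicts

    def test_add_back_restores_growth(self, strain_models, medium, population):
        """Complement check: re-opening an essential uptake rescues growth."""
        truth = population[3]
        strain = next(s for s, ess in truth.essential_components.items() if len(ess) > 1)
        model = strain_models[strain]
        for component in truth.essential_components[strain]:
            without = medium.without(component)
            sol = fba(model, without)
            assert sol.status != "optimal" or sol.objective_value < 0.01
            sol_back = fba(model, medium)
            assert sol_back.objective_value > 0.01

    def test_non_growing_baseline_raises(self, strain_models):
        model = next(iter(strain_models.values()))
        with pytest.raises(RuntimeError):
            single_omission_essentiality(model, Medium({}, name="empty"))


class TestFermentationProfile:
    def test_homolactic_toy(self):
        """Glucose -> 2 lactate at uptake 10 secretes 20 lactate."""
        model = make_network(
            {
                "EX_glc": ({"glc_e": -1.0}, "exchange", -10.0, 1000.0),
                "T_glc": ({"glc_e": -1.0, "glc": 1.0}, "spontaneous", 0.0, 1000.0),
                "GLYC": ({"glc": -1.0, "lac": 2.0, "e": 2.0}, "gene_associated", 0.0, 1000.0),
                "BIOMASS": ({"e": -1.0}, "biomass", 0.0, 1000.0),
                "T_lac": ({"lac": -1.0, "lac_e": 1.0}, "spontaneous", 0.0, 1000.0),
                "EX_lac": ({"lac_e": -1.0}, "exchange", 0.0, 1000.0),
                "NGAM": ({"e": -1.0}, "sink", 0.0, 1000.0),
            },
            "BIOMASS", "NGAM",
            gprs={"GLYC": GPRRule.from_sets([["g"]])},
        )
        profile = fermentation_profile(model, Medium({"EX_glc": 10.0}), ngam=0.0)
        assert profile.secreted == {"EX_lac"}
        assert profile.ranges["EX_lac"][1] == pytest.approx(20.0, abs=1e-6)

    def test_closed_medium_raises(self):
        with pytest.raises(RuntimeError):
            fermentation_profile(linear_chain_model(), Medium({}, name="closed"), ngam=0.0)

    def test_species_byproducts(self, strain_models, medium, population):
        truth = population[3]
        by_mode = {"lac": "EX_lac_e", "act": "EX_act_e", "eth": "EX_eth_e"}
        for strain in ["sp1_01", "sp2_01", "sp3_01"]:
            mode = ["lac", "act", "eth"][int(strain[2]) - 1]
            profile = fermentation_profile(strain_models[strain], medium)
            assert by_mode[mode] in profile.secreted

    def test_secreted_set_order_invariant(self, strain_models, medium):
        strain, model = next(iter(strain_models.items()))
        shuffled = model.copy()
        shuffled.reactions = dict(reversed(list(shuffled.reactions.items())))
        p1 = fermentation_profile(model, medium)
        p2 = fermentation_profile(shuffled, medium)
        assert p1.secreted == p2.secreted


class TestCoreFluxome:
    def test_uptake_scaled_strains_correlate_perfectly(
            self, strain_models, medium, population):
        truth = population[3]
        models = [strain_models[s] for s in list(strain_models)[:6]]
        media = {m.strain_id: strain_medium(medium, truth.uptake_scale[m.strain_id])
                 for m in models}
        out = core_fluxome(models, media, ["T_glc", "HEX1", "PFK_L", "BIOMASS"])
        for rid, entry in out.items():
            assert entry["active_in_all"]
            assert 1.0 - abs(entry["r"]) <= 1e-6

    def test_constant_flux_reaction_has_undefined_r(
            self, strain_models, medium, population):
        truth = population[3]
        models = [strain_models[s] for s in list(strain_models)[:4]]
        media = {m.strain_id: strain_medium(medium, truth.uptake_scale[m.strain_id])
                 for m in models}
        out = core_fluxome(models, media, ["NGAM"])
        assert out["NGAM"]["r"] is None  # NGAM is pinned at 1 in every strain

    def test_too_few_strains_rejected(self, strain_models, medium):
        models = list(strain_models.values())[:2]
        with pytest.raises(ValueError):
            core_fluxome(models, medium, ["HEX1"])


class TestCarbonConservation:
    def test_secreted_carbon_bounded_by_uptake(self, strain_models, reactome, medium):
        """On the balanced synthetic network, carbon out never exceeds carbon in."""
        from pangem.model import parse_formula
        from pangem.qc import apply_medium

        for strain in list(strain_models)[::9]:
            model = strain_models[strain]
            solution = fba(model, medium)
            c_in = c_out = 0.0
            for rid, flux in solution.fluxes.items():
                rxn = model.reactions[rid]
                if rxn.rtype != "exchange":
                    continue
                met = next(iter(rxn.stoichiometry))
                carbons = parse_formula(reactome.metabolites[met].formula).get("C", 0)
                if flux < 0:
                    c_in += -flux * carbons
                else:
                    c_out += flux * carbons
            assert c_out <= c_in + 1e-6
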