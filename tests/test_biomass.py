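import math

import numpy as np
import pytest

from fbarebalance import (
    MetabolicModel,
    Metabolite,
    Reaction,
    ToyModelParams,
    check_biomass_mass,
    extract_biomass_spec,
    gam_to_separate_reaction,
    lump_biomass,
    make_toy_model,
    molecular_weight,
    parse_formula,
)
from fbarebalance.biomass import BiomassError, GamSpec
from fbarebalance.solvers import fba_optimum


def gam_only_model(g=10.0):
    """Biomass that is pure ATP hydrolysis (no mass requirement)."""
    formulas = {
        "atp": "C10H12N5O13P3", "adp": "C10H12N5O10P2",
        "h2o": "H2O", "pi": "HO4P", "h": "H",
    }
    mets = [
        Metabolite(mid, formula=parse_formula(f), compartment="c")
        for mid, f in formulas.items()
    ]
    rxns = [
        Reaction("REGEN", {"adp": -1, "pi": -1, "h": -1, "atp": 1, "h2o": 1},
                 0, 1000),
        Reaction("BIOMASS", {"atp": -g, "h2o": -g, "adp": g, "pi": g, "h": g},
                 0, 1000),
    ]
    return MetabolicModel(mets, rxns, {"BIOMASS": 1.0}, "BIOMASS")


class TestExtractBiomassSpec:
    def test_gam_read_off_adp_coefficient(self, toy_spec_gam):
        spec, gam = toy_spec_gam
        assert gam.g == 10.0
        assert gam.gamma == 10.0
        # hydrolysis signs: ATP, H2O consumed; ADP, Pi, H+ produced
        assert {r: s for r, (_, s) in gam.gam_metabolites.items()} == {
            "atp": -1, "adp": 1, "h2o": -1, "pi": 1, "h": 1,
        }

    def test_split_conserves_coefficients(self, toy_model, toy_spec_gam):
        spec, gam = toy_spec_gam
        stoich = toy_model.biomass_reaction.stoichiometry
        for mid, (c_B, c_gam) in gam.split.items():
            assert c_B + c_gam == pytest.approx(stoich[mid], rel=1e-12)
            assert abs(c_gam) == pytest.approx(gam.g)
        # toy GAM species carry no biomass part
        assert all(gam.c_B(mid) == 0.0 for mid in gam.gam_metabolite_ids)

    def test_explicit_adp_coefficient(self):
        model = make_toy_model(ToyModelParams(seed=5, gam=10.0))
        _, gam = extract_biomass_spec(model)
        assert gam.g == 10.0

    def test_gamma_capped_by_user_maximum(self, toy_model):
        _, gam = extract_biomass_spec(toy_model, gamma_max=3.0)
        assert gam.gamma == 3.0
        _, gam = extract_biomass_spec(toy_model, gamma_max=50.0)
        assert gam.gamma == 10.0

    def test_gamma_must_be_positive_and_below_g(self):
        with pytest.raises(BiomassError, match="gamma"):
            GamSpec(g=10.0, gam_metabolites={}, split={}, gamma=11.0)
        with pytest.raises(BiomassError, match="gamma"):
            GamSpec(g=10.0, gam_metabolites={}, split={}, gamma=0.0)

    def test_missing_adp_with_atp_present_is_ambiguous(self):
        model = gam_only_model()
        stoich = dict(model.biomass_reaction.stoichiometry)
        del stoich["adp"]
        from dataclasses import replace

        model.reactions[1] = replace(model.reactions[1], stoichiometry=stoich)
        with pytest.raises(BiomassError, match="cannot detect GAM"):
            extract_biomass_spec(model)


class TestCheckBiomassMass:
    def test_toy_weighs_exactly_one_gram(self, toy_spec_gam):
        spec, gam = toy_spec_gam
        assert check_biomass_mass(spec, gam) == pytest.approx(1.0, abs=1e-12)

    def test_doubling_a_coefficient_adds_its_mass(self, toy_model):
        from dataclasses import replace

        model = toy_model.copy()
        idx = model.reaction_index["BIOMASS"]
        stoich = dict(model.reactions[idx].stoichiometry)
        c = stoich["bm1"]
        mw = molecular_weight(model.metabolite("bm1").formula)
        stoich["bm1"] = 2 * c
        model.reactions[idx] = replace(model.reactions[idx], stoichiometry=stoich)
        spec, gam = extract_biomass_spec(model)
        with pytest.warns(UserWarning, match="biomass weighs"):
            total = check_biomass_mass(spec, gam)
        assert total == pytest.approx(1.0 + abs(c) * mw, rel=1e-9)

    def test_gam_only_biomass_weighs_nothing(self):
        spec, gam = extract_biomass_spec(gam_only_model())
        with pytest.warns(UserWarning):
            total = check_biomass_mass(spec, gam)
        assert total == pytest.approx(0.0, abs=1e-12)


class TestGamExtraction:
    def test_separate_reaction_carries_hydrolysis(self, toy_model, toy_spec_gam):
        _, gam = toy_spec_gam
        model2, rid = gam_to_separate_reaction(toy_model, gam)
        stoich = model2.reaction(rid).stoichiometry
        assert stoich["atp"] == pytest.approx(-10.0)
        assert stoich["h2o"] == pytest.approx(-10.0)
        assert stoich["adp"] == pytest.approx(10.0)
        # biomass no longer contains the GAM species
        biomass = model2.biomass_reaction.stoichiometry
        assert not set(gam.gam_metabolite_ids) & set(biomass)

    def test_extracted_reaction_is_elementally_balanced(
        self, toy_model, toy_spec_gam
    ):
        _, gam = toy_spec_gam
        model2, rid = gam_to_separate_reaction(toy_model, gam)
        net = {}
        for mid, c in model2.reaction(rid).stoichiometry.items():
            for el, n in model2.metabolite(mid).formula.items():
                net[el] = net.get(el, 0.0) + c * n
        assert all(abs(v) < 1e-9 for v in net.values())

    def test_reextraction_sees_zero_gam_and_refuses_again(
        self, toy_model, toy_spec_gam
    ):
        _, gam = toy_spec_gam
        model2, _ = gam_to_separate_reaction(toy_model, gam)
        spec2, gam2 = extract_biomass_spec(model2)
        assert gam2.g == 0.0
        with pytest.raises(BiomassError, match="already extracted"):
            gam_to_separate_reaction(model2, gam2)

    def test_mass_check_invariant_under_extraction(self, toy_model, toy_spec_gam):
        spec, gam = toy_spec_gam
        before = check_biomass_mass(spec, gam)
        model2, _ = gam_to_separate_reaction(toy_model, gam)
        spec2, gam2 = extract_biomass_spec(model2)
        assert check_biomass_mass(spec2, gam2) == pytest.approx(before, rel=1e-12)


class TestLumpBiomass:
    @pytest.fixture()
    def four_component_model(self):
        return make_toy_model(ToyModelParams(seed=7, n_components=4))

    def test_classes_replace_organic_components(self, four_component_model):
        model = four_component_model
        class_map = {"bm1": "protein", "bm2": "protein",
                     "bm3": "rna", "bm4": "rna"}
        lumped = lump_biomass(model, class_map)
        _, gam = extract_biomass_spec(model)
        biomass = lumped.biomass_reaction.stoichiometry
        organic = set(biomass) - set(gam.gam_metabolite_ids)
        assert organic == {"protein_pseudo", "rna_pseudo"}
        assert biomass["protein_pseudo"] == -1.0

    def test_mass_is_preserved(self, four_component_model):
        model = four_component_model
        spec, gam = extract_biomass_spec(model)
        before = check_biomass_mass(spec, gam)
        lumped = lump_biomass(
            model, {"bm1": "protein", "bm2": "protein", "bm3": "rna",
                    "bm4": "rna"}
        )
        spec2, gam2 = extract_biomass_spec(lumped)
        assert check_biomass_mass(spec2, gam2) == pytest.approx(before, rel=1e-9)

    def test_growth_optimum_is_preserved(self, four_component_model):
        model = four_component_model
        lumped = lump_biomass(
            model, {"bm1": "protein", "bm2": "protein", "bm3": "rna",
                    "bm4": "rna"},
            class_maintenance={"protein": 4.0, "rna": 1.0},
        )
        mu0 = fba_optimum(model).objective_value
        mu1 = fba_optimum(lumped).objective_value
        assert mu1 == pytest.approx(mu0, rel=1e-7)

    def test_maintenance_subtracted_from_total_gam(self):
        # residual biomass GAM = 31.578 - (21.970 + 0.256 + 0.137) = 9.215
        model = make_toy_model(
            ToyModelParams(seed=7, n_components=3, gam=31.578)
        )
        lumped = lump_biomass(
            model,
            {"bm1": "protein", "bm2": "rna", "bm3": "dna"},
            class_maintenance={"protein": 21.970, "rna": 0.256, "dna": 0.137},
        )
        _, gam = extract_biomass_spec(lumped)
        assert gam.g == pytest.approx(9.215, abs=1e-12)
        synth = lumped.reaction("protein_synthesis").stoichiometry
        assert synth["atp"] == pytest.approx(-21.970)

    def test_errors(self, four_component_model):
        model = four_component_model
        with pytest.raises(BiomassError, match="no class"):
            lump_biomass(model, {"bm1": "protein"})
        full_map = {"bm1": "protein", "bm2": "protein", "bm3": "rna",
                    "bm4": "rna"}
        with pytest.raises(BiomassError, match="exceeds total GAM"):
            lump_biomass(model, full_map, class_maintenance={"protein": 99.0})
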