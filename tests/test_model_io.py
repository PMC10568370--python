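import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fbarebalance import (
    Measurement,
    MeasurementSet,
    MetabolicModel,
    Metabolite,
    Reaction,
    molecular_weight,
    parse_formula,
    read_model,
    read_scenario,
    write_model,
)
from fbarebalance.model_io import (
    ATOMIC_MASSES,
    FormulaError,
    ModelError,
    ScenarioError,
)


class TestParseFormula:
    @pytest.mark.parametrize(
        "formula, expected",
        [
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("H2O", {"H": 2, "O": 1}),
            ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
            ("H", {"H": 1}),
            ("HO4P", {"H": 1, "O": 4, "P": 1}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_hill_notation(self, formula, expected):
        assert parse_formula(formula) == expected

    @pytest.mark.parametrize(
        "bad", ["Xx5", "", "  ", "(C2H4)n", "C6R", "R", "C6.5H12", "6C"]
    )
    def test_rejects_invalid(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)


class TestMolecularWeight:
    def test_water(self):
        # 2*1.008 + 15.999 = 18.015 g/mol
        assert molecular_weight({"H": 2, "O": 1}) == pytest.approx(
            0.018015, abs=1e-9
        )

    def test_glucose(self):
        # 6*12.011 + 12*1.008 + 6*15.999 = 180.156 g/mol
        assert molecular_weight(parse_formula("C6H12O6")) == pytest.approx(
            0.180156, abs=1e-9
        )

    def test_empty_and_unknown_element(self):
        with pytest.raises(FormulaError):
            molecular_weight({})
        with pytest.raises(FormulaError):
            molecular_weight({"Xx": 1})

    @given(
        st.dictionaries(
            st.sampled_from(sorted(ATOMIC_MASSES)),
            st.integers(1, 50),
            min_size=1,
            max_size=5,
        ),
        st.dictionaries(
            st.sampled_from(sorted(ATOMIC_MASSES)),
            st.integers(1, 50),
            min_size=1,
            max_size=5,
        ),
    )
    @settings(derandomize=True, max_examples=50)
    def test_additive_over_compositions(self, a, b):
        merged = dict(a)
        for el, n in b.items():
            merged[el] = merged.get(el, 0) + n
        assert molecular_weight(merged) == pytest.approx(
            molecular_weight(a) + molecular_weight(b), rel=1e-12
        )


class TestModelValidation:
    def test_bounds_and_references(self):
        met = Metabolite("A", compartment="c")
        with pytest.raises(ModelError, match="lower bound"):
            MetabolicModel(
                [met], [Reaction("r", {"A": 1.0}, 5.0, 1.0)], {"r": 1.0}, "r"
            )
        with pytest.raises(ModelError, match="unknown"):
            MetabolicModel(
                [met], [Reaction("r", {"B": 1.0}, 0.0, 1.0)], {"r": 1.0}, "r"
            )
        with pytest.raises(ModelError, match="biomass"):
            MetabolicModel(
                [met], [Reaction("r", {"A": 1.0}, 0.0, 1.0)], {"r": 1.0}, "nope"
            )

    def test_measurement_set_rejects_fixed_bounds(self):
        met = Metabolite("A", compartment="c")
        model = MetabolicModel(
            [met],
            [
                Reaction("r1", {"A": 1.0}, 0.0, 10.0),
                Reaction("r2", {"A": -1.0}, 2.0, 2.0),
            ],
            {"r1": 1.0},
            "r1",
        )
        ms = MeasurementSet({"r2": Measurement(2.0)})
        with pytest.raises(ScenarioError, match="lb != ub"):
            ms.validate_against(model)

    def test_negative_sd_rejected(self):
        with pytest.raises(ScenarioError, match="negative"):
            MeasurementSet({"r": Measurement(1.0, sd=-0.1)})


class TestSbmlRoundTrip:
    def test_toy_model_round_trips(self, toy_model, tmp_path):
        path = tmp_path / "toy.xml"
        write_model(toy_model, path)
        back = read_model(path)
        assert back.biomass_reaction_id == toy_model.biomass_reaction_id
        assert [r.id for r in back.reactions] == [
            r.id for r in toy_model.reactions
        ]
        for orig, rt in zip(toy_model.reactions, back.reactions):
            assert rt.stoichiometry == pytest.approx(orig.stoichiometry)
            assert rt.lower_bound == orig.lower_bound
            assert rt.upper_bound == orig.upper_bound
        for orig, rt in zip(toy_model.metabolites, back.metabolites):
            assert rt.id == orig.id
            assert rt.formula == orig.formula

    def test_missing_objective_is_an_error(self, toy_model, tmp_path):
        import cobra

        from fbarebalance.model_io import _model_to_cobra

        cm = _model_to_cobra(toy_model)
        cm.objective = cm.problem.Objective(0)
        path = tmp_path / "noobj.xml"
        cobra.io.write_sbml_model(cm, str(path))
        with pytest.raises(ModelError, match="no biomass reaction"):
            read_model(path)
        # an explicit override rescues it
        model = read_model(path, biomass_reaction_id="BIOMASS")
        assert model.biomass_reaction_id == "BIOMASS"

    def test_missing_file(self, tmp_path):
        with pytest.raises(ModelError, match="not found"):
            read_model(tmp_path / "nope.xml")


class TestScenarioFiles:
    def test_yaml_scenario(self, toy_model, tmp_path):
        path = tmp_path / "scenario.yaml"
        path.write_text(
            "measurements:\n"
            "  EX_glc__D: {value: -9.5, sd: 0.2}\n"
            "  BIOMASS: {value: 1.2}\n"
            "  EX_co2: 11.0\n"
            "mode: lp\n"
            "adjust: {fluxes: true, gam: true}\n"
            "gam: {max_change: 5.0}\n"
            "biomass: {max_rel_change: 0.5}\n"
            "weights: {flux_scheme: relative, flux_scale: 0.01}\n"
        )
        measurements, config = read_scenario(path, toy_model)
        assert len(measurements) == 3
        assert measurements["EX_glc__D"].sd == 0.2
        assert measurements["BIOMASS"].sd is None
        assert config.mode == "lp"
        assert config.adjust_gam and config.adjust_fluxes
        assert not config.adjust_biomass
        assert config.gam_max_change == 5.0
        assert config.max_rel_beta == 0.5
        assert config.flux_weight_scheme == "relative"
        assert config.flux_scale == 0.01

    def test_empty_measurements_rejected(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("measurements: {}\n")
        with pytest.raises(ScenarioError, match="no measurements"):
            read_scenario(path)

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("measurements: {r: 1.0}\nfrobnicate: 1\n")
        with pytest.raises(ScenarioError, match="unknown scenario keys"):
            read_scenario(path)

    def test_unknown_reaction_rejected(self, toy_model, tmp_path):
        path = tmp_path / "unknown.yaml"
        path.write_text("measurements: {not_a_reaction: 1.0}\n")
        with pytest.raises(ScenarioError, match="not in model"):
            read_scenario(path, toy_model)

    def test_json_scenario(self, tmp_path):
        path = tmp_path / "scenario.json"
        path.write_text('{"measurements": {"r": {"value": 2.0, "sd": 0.5}}}')
        measurements, config = read_scenario(path)
        assert measurements["r"] == Measurement(2.0, 0.5)
        assert config.mode == "qp"
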