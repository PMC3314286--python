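"""Structure of the merged reaction network and its variants."""

import numpy as np
import pytest

import smadtif as st
from smadtif.network import CONSERVED_GROUPS, Mechanism
from smadtif.parameters import ParameterSet


@pytest.mark.parametrize("mech,present,absent", [
    ("INTEGRATED", {"pS24nTIF1g", "pS2nTIF1g", "S4ub_n", "S4ub_c", "FAM"},
     {"S4nTIF1g"}),
    ("REPRESSOR", {"S4ub_n", "S4ub_c", "FAM", "TIF1g_n"},
     {"pS2nTIF1g", "pS24nTIF1g", "S4nTIF1g"}),
    ("COMPETITION", {"pS2nTIF1g", "S4nTIF1g", "TIF1g_n"},
     {"pS24nTIF1g", "S4ub_n", "S4ub_c", "FAM"}),
    ("BASE", set(),
     {"TIF1g_n", "pS24nTIF1g", "pS2nTIF1g", "S4nTIF1g", "S4ub_n", "FAM"}),
])
def test_variant_species_sets(mech, present, absent):
    names = set(st.build_model(mech).species_names)
    assert present <= names
    assert not (absent & names)


def test_integrated_has_fam_dependent_deubiquitination():
    system = st.build_model("INTEGRATED")
    dub = [r for r in system.reactions if r.id == "dub_S4ub"]
    assert len(dub) == 1 and "FAM" in dub[0].modifiers


def test_repressor_has_no_stable_tif1g_smad_complex():
    system = st.build_model("REPRESSOR")
    cat = [r for r in system.reactions if r.id == "ub_pS24n_cat"]
    assert len(cat) == 1 and "TIF1g_n" in cat[0].modifiers
    # TIF1γ appears only as a catalyst, never inside a complex species
    for sp in system.species:
        if sp.composition.get("TIF1g") and sp.name != "TIF1g_n":
            pytest.fail(f"unexpected TIF1γ complex species {sp.name}")


@pytest.mark.parametrize("mech", [m.value for m in Mechanism])
def test_conservation_weights_annihilate_stoichiometry(mech):
    system = st.build_model(mech)
    for group, w in system.conservation_weights().items():
        assert np.allclose(w @ system._stoich, 0.0, atol=1e-12), group


def test_rhs_at_zero_state_has_only_receptor_synthesis():
    system = st.build_model("INTEGRATED")
    d = system.rhs(np.zeros(system.n_species), 0.0, ligand=0.0)
    # evaluated by hand: at the all-zero state every mass-action flux
    # vanishes; only the constitutive productions p_RI, p_RII remain
    expect = np.zeros(system.n_species)
    expect[system.index["RI"]] = system.params["p_RI"]
    expect[system.index["RII"]] = system.params["p_RII"]
    assert np.allclose(d, expect, atol=1e-18)


def test_bimolecular_flux_quadruples_when_both_reactants_double():
    system = st.build_model("BASE")
    state = system.initial_state()
    state[system.index["pS2n"]] = 2.0
    state[system.index["S4n"]] = 3.0
    f1 = system.reaction_fluxes(state)["on_pS24n"]
    state[system.index["pS2n"]] *= 2
    state[system.index["S4n"]] *= 2
    f2 = system.reaction_fluxes(state)["on_pS24n"]
    assert f2 == pytest.approx(4 * f1, rel=1e-12)


def test_tif1g_zero_silences_all_tif1g_fluxes():
    system = st.build_model("INTEGRATED", init={"TIF1g_n": 0.0})
    rng = np.random.default_rng(7)
    tif_rxns = ["on_pS24nT", "off_pS24nT", "ub_pS24nT", "off_pS2nT"]
    for _ in range(20):
        state = rng.uniform(0, 30, system.n_species)
        # TIF1γ-containing pools stay empty when total TIF1γ is zero
        for name in ("TIF1g_n", "pS24nTIF1g", "pS2nTIF1g"):
            state[system.index[name]] = 0.0
        fluxes = system.reaction_fluxes(state, ligand=10.0)
        assert all(fluxes[r] == 0.0 for r in tif_rxns)


def test_conserved_totals_track_group_membership(integrated_system):
    state = integrated_system.initial_state()
    totals = integrated_system.conserved_totals(state)
    assert totals["Smad4"] == pytest.approx(50.0, rel=1e-12)
    assert totals["Smad2"] == pytest.approx(60.6, rel=1e-12)
    # moving all cytoplasmic Smad4 into cytoplasmic Smad4ub changes nothing
    moved = state.copy()
    moved[integrated_system.index["S4ub_c"]] += moved[
        integrated_system.index["S4c"]]
    moved[integrated_system.index["S4c"]] = 0.0
    assert integrated_system.conserved_totals(moved)["Smad4"] == pytest.approx(
        50.0, rel=1e-12)
    # a ternary complex counts once toward Smad2, Smad4 and TIF1γ
    tern = state.copy()
    tern[integrated_system.index["pS24nTIF1g"]] = 1.0
    t2 = integrated_system.conserved_totals(tern)
    nuc_to_cell = st.NUCLEAR_VOLUME_L / st.CELL_VOLUME_L
    assert t2["Smad4"] - totals["Smad4"] == pytest.approx(nuc_to_cell, rel=1e-9)
    assert t2["TIF1g"] - totals["TIF1g"] == pytest.approx(nuc_to_cell, rel=1e-9)


def test_parameter_manifest_catches_removed_symbol():
    params = ParameterSet.defaults()
    del params._data["k_dub"]
    with pytest.raises(KeyError, match="k_dub"):
        st.build_model("INTEGRATED", params)


def test_build_rejects_bad_inputs():
    with pytest.raises(ValueError):
        st.build_model("FRANKENSTEIN")
    with pytest.raises(ValueError):
        st.build_model("INTEGRATED", init={"TIF1g_n": -1.0})
    with pytest.raises(KeyError):
        st.build_model("BASE", init={"TIF1g_n": 5.0})  # not a BASE species


def test_rhs_input_validation(integrated_system):
    with pytest.raises(ValueError):
        integrated_system.rhs(np.zeros(3))
    bad = np.zeros(integrated_system.n_species)
    bad[0] = np.nan
    with pytest.raises(ValueError):
        integrated_system.rhs(bad)


def test_default_parameters_nonnegative_and_unit_tagged():
    params = ParameterSet.defaults()
    for symbol in params:
        assert params[symbol] >= 0
        assert params.units(symbol)


def test_k_in_S4ub_default_is_twice_smad4_import():
    params = ParameterSet.defaults()
    assert params["k_in_S4ub"] == pytest.approx(2 * params["k_in_smad4"],
                                                rel=1e-12)


def test_parameter_set_round_trips_through_file(tmp_path):
    p = ParameterSet.defaults().with_updates(k_dub=1.234e-3)
    path = tmp_path / "params.yaml"
    p.save(path)
    q = ParameterSet.load(path)
    assert q["k_dub"] == pytest.approx(1.234e-3, rel=1e-12)
    assert q.units("k_dub") == p.units("k_dub")


def test_unknown_parameter_key_rejected():
    with pytest.raises(KeyError):
        ParameterSet.defaults().with_updates(k_typo=1.0)
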