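"""Structure and balance checks of the brain network reconstruction."""

from fractions import Fraction

import numpy as np
import pytest

import gliaflux as gf
from gliaflux.brain import BrainOptions, build_brain_network
from gliaflux.network import (
    MetabolicNetwork,
    Reaction,
    Species,
    format_equation,
    parse_equation,
)

REQUIRED_ROLES = (
    "GS_a", "PDH_n", "GLC_to_c", "O2_to_c", "GLC_c_to_a", "GLC_c_to_e",
    "GLC_e_to_a", "GLC_e_to_n", "O2_c_to_a", "O2_c_to_n", "LAC_a_to_n",
)


def test_network_size_is_underdetermined_and_near_reference(brain_net):
    """Pathway-level reconstruction lands near 139 reactions / 108 species,
    with more reactions than species (underdetermined system)."""
    N, M = brain_net.n_reactions, brain_net.n_species
    assert N > M
    assert 0.75 * 139 <= N <= 1.25 * 139
    assert 0.75 * 108 <= M <= 1.25 * 108


def test_all_named_roles_resolve(brain_net):
    for role in REQUIRED_ROLES:
        j = brain_net.role_column(role)
        assert 0 <= j < brain_net.n_reactions


def test_element_balances_are_clean(brain_net):
    assert gf.carbon_balance_check(brain_net)[0] == []
    assert gf.nitrogen_balance_check(brain_net)[0] == []


def test_carbon_audit_flags_corrupted_aldolase(brain_net):
    rxns = []
    for r in brain_net.reactions:
        if r.id == "ALD_n":
            st = dict(r.stoichiometry)
            st["GAP[nc]"] = Fraction(2)  # 6 carbons in, 9 out
            r = Reaction(r.id, r.name, st, r.reversible, r.pathway_tag, r.cell_scope)
        rxns.append(r)
    broken = MetabolicNetwork(list(brain_net.species), rxns, name="broken")
    bad = gf.carbon_balance_check(broken)[0]
    assert [rid for rid, _ in bad] == ["ALD_n"]
    assert bad[0][1] != 0


def test_glutamine_synthetase_stoichiometry(brain_net):
    """GS consumes 1 glutamate, 1 ammonium and 1 ATP in the astrocyte and
    produces 1 glutamine and 1 ADP."""
    r = brain_net.reactions[brain_net.role_column("GS_a")]
    expect = {"GLU[ac]": -1, "NH4[ac]": -1, "ATP[ac]": -1,
              "GLN[ac]": 1, "ADP[ac]": 1}
    assert {k: int(v) for k, v in r.stoichiometry.items()} == expect


def test_sodium_pump_column(brain_net):
    """Na/K-ATPase: 1 ATP moves 3 Na+ out of and 2 K+ into the neuron."""
    S = gf.stoichiometric_matrix(brain_net)
    j = brain_net.reaction_index("NKA_n")
    idx = brain_net.species_index
    assert S[idx("NA[nc]"), j] == -3
    assert S[idx("NA[e]"), j] == 3
    assert S[idx("K[nc]"), j] == 2
    assert S[idx("K[e]"), j] == -2
    assert S[idx("ATP[nc]"), j] == -1
    assert S[idx("ADP[nc]"), j] == 1


def test_stoichiometric_matrix_shape_and_columns(brain_net):
    S = brain_net.S
    assert S.shape == (brain_net.n_species, brain_net.n_reactions)
    # column j equals the reaction stoichiometry expanded over species
    j = brain_net.reaction_index("PDH_n")
    r = brain_net.reactions[j]
    col = {brain_net.species[i].id: S[i, j] for i in np.nonzero(S[:, j])[0]}
    assert col == {k: float(v) for k, v in r.stoichiometry.items()}


def test_two_species_chain_matrix():
    net = gf.make_chain(1)
    S = gf.stoichiometric_matrix(net)
    # transport column: -1 on the upstream species, +1 downstream
    j = net.reaction_index("T1")
    assert list(S[:, j]) == [-1.0, 1.0]


def test_cells_interact_only_through_shared_compartments(brain_net):
    """No reaction couples neuronal compartments with astrocytic ones."""
    ncomp = {"nc", "nm", "nv"}
    acomp = {"ac", "am"}
    for r in brain_net.reactions:
        comps = {sid[:-1].split("[")[1] for sid in r.stoichiometry}
        assert not (comps & ncomp and comps & acomp), r.id


def test_glucose_route_topology(brain_net):
    """Capillary glucose feeds only the astrocyte and the interstitium;
    interstitial glucose feeds only the two cells."""
    S = brain_net.S
    consumers_c = {
        brain_net.reactions[j].id
        for j in np.nonzero(S[brain_net.species_index("GLC[c]")] < 0)[0]
    }
    assert consumers_c == {"GLCT_c_a", "GLCT_c_e"}
    consumers_e = {
        brain_net.reactions[j].id
        for j in np.nonzero(S[brain_net.species_index("GLC[e]")] < 0)[0]
    }
    assert consumers_e == {"GLCT_e_a", "GLCT_e_n"}


@pytest.mark.parametrize(
    "options, absent",
    [
        (BrainOptions(include_glycogen=False), ("GLYSYN_a", "GLYDEG_a")),
        (BrainOptions(include_g3p_shuttle=False),
         ("G3PDC_n", "G3PDM_n", "G3PDC_a", "G3PDM_a")),
        (BrainOptions(include_antioxidant=False),
         ("GSHSYN_a", "GPX_n", "GR_a", "ROS_n", "ASCT_a", "CYS2_in")),
    ],
)
def test_optional_subsystems_can_be_disabled(options, absent):
    net = build_brain_network(options)
    for rid in absent:
        assert not net.has_reaction(rid)
    assert gf.carbon_balance_check(net)[0] == []
    for role in REQUIRED_ROLES:
        net.role_column(role)


def test_equation_parser_round_trip(brain_net):
    for r in brain_net.reactions:
        if r.is_exchange:
            continue
        text = format_equation(r)
        reac, prod = parse_equation(text)
        stoich = {k: -v for k, v in reac.items()}
        for k, v in prod.items():
            stoich[k] = stoich.get(k, 0) + v
        assert stoich == dict(r.stoichiometry), r.id
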