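"""Toy networks and the brute-force polytope oracle."""

from math import comb

import numpy as np
import pytest

import gliaflux as gf
from gliaflux.toys import ToyNetworkSpec, build_toy


def test_chain_length_one_feasible_set_is_a_segment():
    chain = gf.make_chain(1)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    pts = gf.brute_force_polytope(chain, cs, resolution=11)
    assert len(pts) == 11
    np.testing.assert_allclose(pts[:, chain.reaction_index("IN")], 1.0)
    np.testing.assert_allclose(pts[:, chain.reaction_index("T1")], 1.0)
    out = np.sort(pts[:, chain.reaction_index("OUT")])
    np.testing.assert_allclose(out, np.linspace(0, 1, 11), atol=1e-12)


def test_chain_grid_matches_monotone_characterization():
    """For the pinned chain the feasible set is exactly the monotone
    non-increasing flux sequences; the grid count is the number of
    non-increasing triples, C(res+2, 3)."""
    res = 11
    chain = gf.make_chain(3)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    pts = gf.brute_force_polytope(chain, cs, resolution=res)
    assert len(pts) == comb(res + 2, 3)
    cols = [chain.reaction_index(r) for r in ("T1", "T2", "T3", "OUT")]
    seq = pts[:, cols]
    assert np.all(np.diff(seq, axis=1) <= 1e-9)
    assert np.allclose(seq[:, 0], 1.0)


def test_relaxed_prior_draws_stay_in_characterized_set():
    chain = gf.make_chain(3)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    ens = gf.sample_ensemble(chain, cs, gf.SamplerConfig(seed=2, K=200))
    cols = [chain.reaction_index(r) for r in ("T1", "T2", "T3", "OUT")]
    seq = ens.solutions[:, cols]
    assert np.all(np.diff(seq, axis=1) <= 1e-9)


def test_diamond_routes_split_and_rejoin():
    di = gf.make_diamond()
    cs = gf.constraints_for(di, {"IN": 1.0})
    pts = gf.brute_force_polytope(di, cs, resolution=7)
    assert len(pts) > 0
    r1 = pts[:, di.reaction_index("R1")]
    r2 = pts[:, di.reaction_index("R2")]
    out = pts[:, di.reaction_index("OUT")]
    j1 = pts[:, di.reaction_index("J1")]
    j2 = pts[:, di.reaction_index("J2")]
    assert np.all(r1 + r2 <= 1 + 1e-9)
    assert np.all(j1 <= r1 + 1e-9) and np.all(j2 <= r2 + 1e-9)
    assert np.all(out <= j1 + j2 + 1e-9)


def test_minibrain_symmetric_configuration_has_zero_shuttle():
    mb = gf.make_minibrain()
    cs = gf.constraints_for(mb, {"GLC_in": 1.0}, nu_max=3.0)
    nu = np.zeros(mb.n_reactions)
    for rid, v in [("GLC_in", 1.0), ("GLY_n", 0.5), ("GLY_a", 0.5),
                   ("OX_n", 0.5), ("OX_a", 0.5), ("O2_in", 3.0)]:
        nu[mb.reaction_index(rid)] = v
    assert gf.check_feasibility(mb, nu, cs)[0]
    assert gf.ccls_flux(nu, mb) == 0.0


def test_minibrain_skewed_partition_forces_anls():
    """With 80% of glucose to the astrocyte and symmetric capped oxidation,
    the astrocyte's glycolytic surplus must flow toward the neuron: the
    grid-mean lactate exchange is positive (ANLS)."""
    mb = gf.make_minibrain()
    cs = gf.constraints_for(mb, {"GLC_in": 1.0, "GLY_a": 0.8, "GLY_n": 0.2})
    cs.ub[mb.reaction_index("OX_n")] = 0.3
    cs.ub[mb.reaction_index("OX_a")] = 0.3
    pts = gf.brute_force_polytope(mb, cs, resolution=13)
    assert len(pts) > 0
    lact_a = pts[:, mb.reaction_index("LACT_a")]
    lact_n = pts[:, mb.reaction_index("LACT_n")]
    assert lact_a.mean() > 0
    # the extracellular pool cannot be net consumed
    assert np.all(lact_a + lact_n >= -1e-9)


def test_minibrain_fully_oxidative_corner_has_ogi_six():
    mb = gf.make_minibrain()
    cs = gf.constraints_for(mb, {"GLC_in": 1.0}, nu_max=6.0)
    nu = np.zeros(mb.n_reactions)
    for rid, v in [("GLC_in", 1.0), ("GLY_n", 0.5), ("GLY_a", 0.5),
                   ("OX_n", 1.0), ("OX_a", 1.0), ("O2_in", 6.0)]:
        nu[mb.reaction_index(rid)] = v
    assert gf.check_feasibility(mb, nu, cs)[0]
    assert gf.compute_ogi(nu, mb) == pytest.approx(6.0)


def test_brute_force_empty_on_infeasible_pin_matches_lp():
    chain = gf.make_chain(1)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    cs.ub[chain.reaction_index("T1")] = 0.5  # transport cannot carry the pin
    pts = gf.brute_force_polytope(chain, cs, resolution=11)
    assert len(pts) == 0
    x, cert = gf.lp_feasible_point(chain, cs)
    assert x is None and cert is not None


def test_brute_force_refuses_high_dimensional_problems(brain_net):
    cs = gf.make_constraints(brain_net, 0.1)
    with pytest.raises(ValueError):
        gf.brute_force_polytope(brain_net, cs, resolution=3)


def test_random_network_is_reproducible():
    n1, d1 = gf.make_random_network(6, 10, seed=5)
    n2, d2 = gf.make_random_network(6, 10, seed=5)
    np.testing.assert_array_equal(n1.S, n2.S)
    np.testing.assert_array_equal(d1, d2)
    assert [r.reversible for r in n1.reactions] == [r.reversible for r in n2.reactions]


def test_build_toy_dispatch():
    assert build_toy(ToyNetworkSpec(kind="chain", length=2)).name == "chain"
    assert build_toy(ToyNetworkSpec(kind="minibrain")).name == "minibrain"
    with pytest.raises(ValueError):
        build_toy(ToyNetworkSpec(kind="nope"))
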