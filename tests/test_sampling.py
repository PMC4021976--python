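"""Prior draws, projection, ensembles and the LP oracle."""

import numpy as np
import pytest

import gliaflux as gf
from gliaflux.sampling import _sample_seed


def test_prior_is_reproducible_and_respects_pins():
    chain = gf.make_chain(2)
    cs = gf.constraints_for(chain, {"IN": 0.7})
    v1 = gf.sample_prior(cs, _sample_seed(3, 0))
    v2 = gf.sample_prior(cs, _sample_seed(3, 0))
    np.testing.assert_array_equal(v1, v2)
    assert v1[chain.reaction_index("IN")] == 0.7
    assert np.all(v1 >= cs.lb) and np.all(v1 <= cs.ub)


def test_prior_component_means_near_bound_midpoints(brain_net):
    cs = gf.make_constraints(brain_net, 0.12)
    rng = np.random.default_rng(0)
    draws = np.array([gf.sample_prior(cs, rng) for _ in range(10_000)])
    free = cs.lb < cs.ub
    mid = 0.5 * (cs.lb + cs.ub)
    se = (cs.ub - cs.lb) / np.sqrt(12 * draws.shape[0])
    z = (draws.mean(axis=0) - mid)[free] / se[free]
    assert np.abs(z).max() < 5  # 3-sigma per component with a margin for N tests


def test_relax_returns_feasible_input_unchanged():
    chain = gf.make_chain(1)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    nu0 = np.array([1.0, 1.0, 0.3])
    out, iters, worst = gf.relax(chain, nu0, cs, gf.SamplerConfig())
    assert iters == 0
    np.testing.assert_array_equal(out, nu0)


def test_relax_projects_onto_chain_segment():
    """The feasible set of the pinned unit chain is the segment
    {(1, 1, t): 0 <= t <= 1}; the minimal-distance solution is the clip."""
    chain = gf.make_chain(1)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    cfg = gf.SamplerConfig()
    for t0 in (-0.4, 0.3, 1.7):
        nu0 = np.array([1.0, 0.2, t0])
        out, _, worst = gf.relax(chain, nu0, cs, cfg)
        assert out is not None and worst <= 10 * cfg.epsilon
        expect = np.array([1.0, 1.0, min(max(t0, 0.0), 1.0)])
        np.testing.assert_allclose(out, expect, atol=1e-8)


def test_ensemble_is_deterministic(brain_net):
    cs = gf.make_constraints(brain_net, 0.14)
    e1 = gf.sample_ensemble(brain_net, cs, gf.SamplerConfig(seed=7, K=120))
    e2 = gf.sample_ensemble(brain_net, cs, gf.SamplerConfig(seed=7, K=120))
    np.testing.assert_array_equal(e1.solutions, e2.solutions)


def test_chain_ensemble_covers_the_feasible_segment():
    chain = gf.make_chain(1)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    ens = gf.sample_ensemble(chain, cs, gf.SamplerConfig(seed=1, K=1000))
    assert ens.n_failed == 0
    out = ens.solutions[:, chain.reaction_index("OUT")]
    assert out.min() < 0.05 and out.max() > 0.95  # full segment support
    for row in ens.solutions[::50]:
        assert gf.check_feasibility(chain, row, cs)[0]


def test_exact_scale_covariance_with_matched_seeds(brain_net):
    """Scaling the pin and the prior bound by lambda scales every solution."""
    lam = 2.5
    cs1 = gf.make_constraints(brain_net, 0.12, nu_max=1.0)
    cs2 = gf.make_constraints(brain_net, lam * 0.12, nu_max=lam)
    e1 = gf.sample_ensemble(brain_net, cs1,
                            gf.SamplerConfig(seed=5, K=60, nu_max=1.0))
    e2 = gf.sample_ensemble(brain_net, cs2,
                            gf.SamplerConfig(seed=5, K=60, nu_max=lam))
    np.testing.assert_allclose(lam * e1.solutions, e2.solutions,
                               rtol=1e-6, atol=1e-7)


def test_lp_oracle_agrees_with_sampler_on_nonemptiness(brain_net):
    chain = gf.make_chain(1)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    x, cert = gf.lp_feasible_point(chain, cs)
    assert cert is None
    assert gf.check_feasibility(chain, x, cs, 1e-7)[0]
    cs_b = gf.make_constraints(brain_net, 0.15)
    xb, cert_b = gf.lp_feasible_point(brain_net, cs_b)
    assert cert_b is None


def test_contradictory_pin_yields_infeasibility_certificate(brain_net):
    """A glucose pin above what the two capillary routes can carry is
    infeasible: the LP certifies it and the sampler refuses."""
    cs = gf.make_constraints(brain_net, 0.5, nu_max=0.2)
    x, cert = gf.lp_feasible_point(brain_net, cs)
    assert x is None and cert is not None
    with pytest.raises(RuntimeError):
        gf.sample_ensemble(brain_net, cs, gf.SamplerConfig(seed=0, K=100,
                                                           nu_max=0.2))


def test_random_networks_embed_feasible_points_and_sample():
    for seed in range(10):
        net, nu_dagger = gf.make_random_network(6, 10, density=0.4, seed=seed)
        cs = gf.constraints_for(net, {}, nu_max=2.0)
        assert gf.check_feasibility(net, nu_dagger, cs, 1e-6)[0]
        ens = gf.sample_ensemble(net, cs, gf.SamplerConfig(seed=seed, K=50,
                                                           nu_max=2.0))
        assert ens.K >= 45  # >= 90% of draws converge


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        gf.SamplerConfig(step=2.5)
    with pytest.raises(ValueError):
        gf.SamplerConfig(nu_max=-1.0)


from hypothesis import given, settings, strategies as st


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.floats(-1, 2), min_size=5, max_size=5))
def test_projection_is_idempotent_on_chain(raw):
    """Projecting an already-projected point changes nothing (fixed point)."""
    chain = gf.make_chain(3)
    cs = gf.constraints_for(chain, {"IN": 1.0})
    cfg = gf.SamplerConfig()
    nu0 = np.clip(np.asarray(raw), cs.lb, cs.ub)
    nu0[chain.reaction_index("IN")] = 1.0
    out, _, worst = gf.relax(chain, nu0, cs, cfg)
    assert out is not None
    again, iters, _ = gf.relax(chain, out, cs, cfg)
    assert iters == 0
    np.testing.assert_array_equal(out, again)
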