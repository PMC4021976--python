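import numpy as np
import pytest

import gliaflux as gf
from gliaflux.pipeline import RunConfig, reproduce_study


@pytest.fixture(scope="session")
def brain_net():
    return gf.build_brain_network()


@pytest.fixture(scope="session")
def basal_ensemble(brain_net):
    """One moderate ensemble at a near-basal glucose uptake."""
    cs = gf.make_constraints(brain_net, 0.15)
    ens = gf.sample_ensemble(brain_net, cs, gf.SamplerConfig(seed=42, K=400))
    return cs, ens


@pytest.fixture(scope="session")
def study_report():
    """Reduced-size full reproduction (calibration + sweep + targets).

    Sample sizes are chosen so the whole suite stays within a desk-scale
    budget; the acceptance script runs the same protocol at larger K.
    """
    cfg = RunConfig(seed=123, K=1000, K_calibration=600, K_silent=500)
    return reproduce_study(cfg)
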