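import pytest

from modsnn import desk_preset, generate_network, settle, stage_seed
from modsnn.experiment import make_fixture


@pytest.fixture(scope="session")
def desk_config():
    return desk_preset(master_seed=3)


@pytest.fixture(scope="session")
def settled_desk(desk_config):
    """A settled track-patterned desk-scale network (shared, read-only:
    tests must copy() before mutating)."""
    cfg = desk_config
    net = generate_network(cfg.growth)
    net, _ = settle(net, cfg.settle_s, noise=cfg.noise, stdp=cfg.stdp,
                    dynamics=cfg.dynamics,
                    seed=stage_seed(cfg.master_seed, "settle"),
                    in_place=True)
    return net


@pytest.fixture
def toy_network():
    return make_fixture("toy_network")


@pytest.fixture
def scripted_raster():
    return make_fixture("scripted_raster", seed=0)
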