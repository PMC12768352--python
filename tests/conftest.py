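"""Shared fixtures: a synthetic reference bundle and small simulated libraries."""

import pytest

import sirnakit as sk


@pytest.fixture(scope="session")
def refs():
    return sk.make_references(seed=1)


@pytest.fixture(scope="session")
def default_config(refs):
    return sk.config_from_references(refs, biology_seed=7, depth=20_000)


@pytest.fixture(scope="session")
def small_library(refs, default_config):
    """One simulated library at modest depth, fully assigned."""
    pool = sk.apply_protocol(sk.simulate_pool(default_config), "standard")
    reads, truth = sk.sample_library(pool, sampling_seed=11)
    collapsed = sk.length_filter(sk.collapse(s for _, s in reads))
    lib = sk.assign(collapsed, refs)
    return {"reads": reads, "truth": truth, "lib": lib, "pool": pool}
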