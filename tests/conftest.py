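import pytest

from melrna.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One default simulation shared across tests (seed-fixed, read-only)."""
    return simulate(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_simdir(default_sim, tmp_path_factory):
    """The default simulation written to disk."""
    outdir = tmp_path_factory.mktemp("sim")
    paths = default_sim.write(outdir)
    return outdir, paths


@pytest.fixture(scope="session")
def clean_sim():
    """Zero-background, exact-TSS simulation: every pipeline stage is exact."""
    cfg = SimConfig(
        seed=11,
        tss_offset_probs=(1.0,),
        n_background_fragments=0,
    )
    return simulate(cfg)
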