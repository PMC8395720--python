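import pandas as pd
import pytest

from dirseq import panel as panel_mod
from dirseq import simulate as sim_mod


@pytest.fixture(scope="session")
def scheme():
    return panel_mod.build_scheme()


@pytest.fixture(scope="session")
def small_snps():
    return panel_mod.synthesize_snps(20, seed=1)


@pytest.fixture(scope="session")
def small_panel(small_snps, scheme):
    return panel_mod.build_panel(small_snps, scheme=scheme, tag_seed=1)


@pytest.fixture(scope="session")
def small_manifest(small_panel):
    return panel_mod.manifest_frame(small_panel)


@pytest.fixture(scope="session")
def small_run(small_panel, scheme, tmp_path_factory):
    """An error-free simulated run at modest depth, shared across tests."""
    design = sim_mod.SimulationDesign(
        panel=small_panel, scheme=scheme, reads_per_library=2000,
        epsilon=0.0, seed=7,
    )
    truth = sim_mod.simulate_counts(design)
    outdir = tmp_path_factory.mktemp("run_eps0")
    libraries = sim_mod.emit_fastq(truth, outdir)
    return truth, libraries, outdir
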