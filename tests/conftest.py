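import numpy as np
import pandas as pd
import pytest

from methlink.io_formats import read_dmr_bed
from methlink.pipeline import run_all
from methlink.synthetic import SimulationConfig, generate_study

DEFAULT_SEED = 11


@pytest.fixture(scope="session")
def default_study(tmp_path_factory):
    """A full default synthetic study (24 samples, 30 planted triplets, 300 decoys)."""
    out = tmp_path_factory.mktemp("study") / "default"
    config = SimulationConfig(seed=DEFAULT_SEED)
    manifest = generate_study(config, out)
    return {"dir": out, "config": config, "manifest": manifest}


@pytest.fixture(scope="session")
def default_run(default_study):
    """One end-to-end pipeline run over the default study."""
    result = run_all(default_study["dir"], out_dir=None, seed=7)
    truth = pd.read_csv(default_study["dir"] / "truth_triplets.tsv", sep="\t")
    true_dmrs = read_dmr_bed(default_study["dir"] / "true_dmrs.bed")
    return {"result": result, "truth": truth, "true_dmrs": true_dmrs}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def tiny_meth_config(seed: int, **overrides) -> SimulationConfig:
    """Small methylation-only config for caller simulations."""
    base = dict(
        seed=seed,
        genome=(("chr1", 2_000_000),),
        n_cpg=1200,
        n_planted_dmrs=8,
        delta_beta=0.3,
        dmr_fixed_size=True,
        n_lnc_linked=0,
        n_lnc_decoy=0,
        n_prot_linked=0,
        n_prot_decoy=0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
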