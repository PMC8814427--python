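import numpy as np
import pandas as pd
import pytest

from aneupipe import GenomeModel, SegmentProfile, SimConfig
from aneupipe import io_cli, synthetic_data


@pytest.fixture(scope="session")
def toy_genome() -> GenomeModel:
    """Three small chromosomes, six arms — easy to reason about by hand."""
    return GenomeModel({"1": (1000, 400), "2": (800, 300), "3": (600, 200)})


def make_profile(sample, rows, purity=0.7, ploidy=2.0):
    seg = pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                      "copy_number"])
    return SegmentProfile(sample=sample, segments=seg, purity=purity,
                          ploidy=ploidy)


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully structured synthetic cohort shared across tests."""
    cfg = SimConfig(seed=42, n_tumor=60, n_normal=20, n_genes=300,
                    n_driver=8, n_module_genes=20)
    profiles, pp, truth = synthetic_data.gen_cohort(cfg)
    omics = synthetic_data.gen_omics(truth, cfg)
    clinical = synthetic_data.gen_clinical(truth, cfg)
    return {"config": cfg, "profiles": profiles, "pp": pp, "truth": truth,
            "omics": omics, "clinical": clinical}


@pytest.fixture(scope="session")
def small_bundle_dir(tmp_path_factory):
    """The same small cohort written to disk as a pipeline input bundle."""
    out = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=42, n_tumor=60, n_normal=20, n_genes=300,
                    n_driver=8, n_module_genes=20)
    pipeline_config = io_cli.write_simulation(cfg, out)
    return out, pipeline_config
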