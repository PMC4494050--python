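import pytest

from mescan import PipelineConfig, SimConfig, run_pipeline, simulate_tree
from mescan.simulate import run_simulation


def small_sim_config(seed=3, **overrides):
    params = dict(n_taxa=5, tree_shape="random", genome_length=120_000,
                  n_chromosomes=2, n_loci=50, default_read_pairs=800,
                  failed_taxon="T5", seed=seed)
    params.update(overrides)
    return SimConfig(**params)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small error-free simulated dataset (5 taxa, 50 loci, one failed
    library) with its ground truth."""
    cfg = small_sim_config()
    out = run_simulation(cfg, str(tmp_path_factory.mktemp("sim")))
    out["config"] = cfg
    return out


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_dataset):
    """Full pipeline run on the small dataset."""
    cfg = PipelineConfig(sim=None, bootstrap_replicates=50, seed=3)
    result = run_pipeline(cfg, str(tmp_path_factory.mktemp("run")),
                          inputs=small_dataset["paths"])
    return {"result": result, "sim": small_dataset,
            "true_tree": simulate_tree(small_dataset["config"])}
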