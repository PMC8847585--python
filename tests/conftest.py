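import pytest

from prc2sig import pipeline, syndata


@pytest.fixture(scope="session")
def small_config():
    """A 300-gene configuration that keeps generator tests fast."""
    return syndata.SynthConfig(n_genes=300, chrom_sizes={"chr1": 3_000_000}, seed=11)


@pytest.fixture(scope="session")
def small_data(small_config):
    genes = syndata.make_genes(small_config)
    truth = syndata.make_truth(genes, small_config)
    tracks, cpg = syndata.make_multiomics(genes, truth, small_config)
    control, treated, libstats = syndata.make_counts(genes, truth, small_config)
    return {
        "config": small_config,
        "genes": genes,
        "truth": truth,
        "tracks": tracks,
        "cpg": cpg,
        "control": control,
        "treated": treated,
        "libstats": libstats,
    }


@pytest.fixture(scope="session")
def benchmark():
    """The default 2000-gene synthetic benchmark, quantified end to end."""
    return pipeline.synthetic_features(syndata.SynthConfig())
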