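import pytest

from kskpipe import pipeline, simulate


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimulationConfig:
    """Compact read-simulation regime used across k-mer and assembly tests."""
    return simulate.SimulationConfig(seed=1, n_genes=10, gene_length_range=(500, 1500))


@pytest.fixture(scope="session")
def transcriptome(small_cfg):
    return simulate.generate_transcriptome(small_cfg)


@pytest.fixture(scope="session")
def variants(transcriptome, small_cfg):
    return simulate.plant_default_variants(transcriptome, small_cfg)


@pytest.fixture(scope="session")
def target_reads(transcriptome, small_cfg, variants):
    return simulate.generate_reads(
        transcriptome, small_cfg, variants, target=True, sample_label="target"
    )


@pytest.fixture(scope="session")
def pool_reads(transcriptome, small_cfg):
    """One read set per background cultivar, error-free draws from the reference."""
    return {
        f"pool{i + 1:02d}": simulate.generate_reads(
            transcriptome, small_cfg, target=False, sample_label=f"pool{i + 1:02d}"
        )
        for i in range(small_cfg.n_pool_samples)
    }


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under the default study conditions."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = pipeline.RunConfig(seed=11, out_dir=str(out))
    return pipeline.run_pipeline(cfg)


@pytest.fixture(scope="session")
def count_fixture():
    """Default-condition count matrix with planted DE genes and modules."""
    cfg = simulate.SimulationConfig(seed=7, n_genes=600)
    genes = [f"g{i + 1:04d}" for i in range(600)]
    truth = simulate.default_count_truth(genes, seed=7)
    counts, meta, lengths = simulate.generate_counts(cfg, truth, genes=genes)
    return counts, meta, lengths, truth
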