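import pytest

from enhancerkit.pipeline import PipelineConfig, run_pipeline
from enhancerkit.simulate import SimulationConfig, simulate_all, write_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def sim_fixture(tmp_path_factory):
    """Default synthetic fixture (in memory + written to disk)."""
    cfg = SimulationConfig(seed=FIXTURE_SEED)
    fix = simulate_all(cfg)
    d = tmp_path_factory.mktemp("fixture")
    write_fixture(fix, d)
    return fix, d


@pytest.fixture(scope="session")
def pipeline_run(sim_fixture, tmp_path_factory):
    """Full pipeline run over the session fixture."""
    fix, d = sim_fixture
    out = tmp_path_factory.mktemp("run")
    res = run_pipeline(PipelineConfig.from_fixture_dir(d, out))
    return fix, res, out


def truth_id(row) -> str:
    """Enhancer-call identifier for a truth-manifest row."""
    return f"{row.chrom}:{row.start}-{row.end}"


def small_sim_config(seed: int) -> SimulationConfig:
    """Reduced-size configuration for fast determinism/packing tests."""
    return SimulationConfig(
        seed=seed,
        chromosome_lengths=(3_000_000, 3_000_000),
        n_genes_refseq=80,
        n_active=8,
        n_intermediate=5,
        n_poised=5,
        n_erna_decoys_per_class=2,
        n_inducible_enhancers=8,
        n_ctcf_extra=8,
        rna_depth=20_000,
        mark_depth=6_000,
        me2_depth=60_000,
        n_factor_sites=50,
        n_random_gene_set=8,
    )
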