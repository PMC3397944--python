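import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from sagetag import PipelineConfig, run_pipeline
from sagetag.synthetic_data import SimulationConfig, simulate, write_simulation


def small_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast, fully-featured simulation: all five SC categories present."""
    base = dict(
        seed=seed,
        n_x_specific=4,
        n_yh_specific=2,
        n_shared=1,
        n_multi_nuclear=2,
        n_organelle=1,
        n_non_sc=2,
        partition_lengths={
            "X": 24000,
            "Yh": 12000,
            "other_nuclear": 14000,
            "organelle": 5000,
        },
        depth=3000,
        n_background_tags=30,
        allele_mutation_rates=(0.05, 0.30),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """The small simulation written out and pushed through the pipeline."""
    outdir = tmp_path_factory.mktemp("sim")
    write_simulation(small_sim, str(outdir))
    cfg = PipelineConfig.from_yaml(str(outdir / "pipeline.yaml"))
    summary = run_pipeline(cfg)
    return small_sim, cfg, summary
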