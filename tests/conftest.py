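import pytest

from seqdup import GeneratorConfig, generate_benchmark
from seqdup.impact import PipelineConfig, run_pipeline

# Scaled problem size for full-pipeline checks: the spec-default group
# structure and category mix at desk-scale sequence lengths (log-uniform
# 200-2000 bases).
BENCH_CFG = GeneratorConfig(seed=1, n_groups=1000, length_range=(200, 2000))


@pytest.fixture(scope="session")
def benchmark():
    """Seeded 1000-group synthetic benchmark with truth labels."""
    return generate_benchmark(BENCH_CFG)


@pytest.fixture(scope="session")
def pipeline_result():
    """Full pipeline run on the session benchmark (same seed/config)."""
    return run_pipeline(PipelineConfig(synthetic=BENCH_CFG))
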