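import json
from pathlib import Path

import pytest

from biphase import synthetic
from biphase.config import PipelineConfig, SyntheticConfig
from biphase.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_dataset():
    """One in-memory synthetic dataset under the default study conditions."""
    return synthetic.simulate_all(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default configuration, shared by tests."""
    out = tmp_path_factory.mktemp("pipeline") / "run"
    cfg = PipelineConfig(outdir=str(out), seed=7)
    run_pipeline(cfg)
    return Path(cfg.outdir)


@pytest.fixture(scope="session")
def default_manifest(default_run):
    return json.loads((default_run / "data" / "manifest.json").read_text())


def small_synthetic_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A fast, valid configuration for tests that exercise the full generator."""
    base = dict(
        seed=seed, n_chroms=2, chrom_length_bp=200_000, n_genes=20, n_tfs=4,
        n_deg=6, n_true_edges=10, n_decoy_sites=40,
        paralog_patterns={"no_divergence": 2, "one_sided": 2, "both_sided": 2},
    )
    base.update(overrides)
    return SyntheticConfig(**base)
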