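"""Shared fixtures: the 20-seed synthetic study batches used end to end.

The batches are session-scoped because each full workflow run costs tens of
seconds; the recovery, null-calibration and drug-response checks all consume
the same runs.
"""

import warnings

import pytest

from crosspath import (
    EnrichmentParams,
    SyntheticConfig,
    WorkflowConfig,
    generate_study,
    run_workflow,
)

N_SEEDS = 20

warnings.filterwarnings("ignore", message="Liblinear failed to converge")


def _run(seed: int, **cfg_overrides):
    study = generate_study(SyntheticConfig(seed=seed, **cfg_overrides))
    cfg = WorkflowConfig(enrichment=EnrichmentParams(seed=seed))
    report = run_workflow(
        study.mouse, study.human, study.mouse_sets, study.human_sets, cfg
    )
    return study, cfg, report


@pytest.fixture(scope="session")
def signal_batch():
    """Default study conditions, planted shared signal, one run per seed."""
    return [_run(seed) for seed in range(N_SEEDS)]


@pytest.fixture(scope="session")
def null_batch():
    """Same conditions with the shared effect silenced (species-specific kept)."""
    return [_run(seed, shared_effect_size=0.0) for seed in range(N_SEEDS)]
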