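"""Workflow orchestration: shared components, candidates, refinement, relaxation."""

import numpy as np
import pandas as pd
import pytest

from crosspath.datasets import ExpressionDataset
from crosspath.enrichment import EnrichmentMatrix, EnrichmentParams
from crosspath.simulate import SyntheticConfig, generate_study
from crosspath.spca import SparsePCModel
from crosspath.translatability import (
    NO_TRANSLATABLE,
    WorkflowConfig,
    WorkflowError,
    candidate_pathways,
    refine_translatable,
    relax_alpha,
    run_workflow,
    shared_components,
)

SMALL_STUDY = dict(
    n_pathways=20,
    genes_per_pathway=8,
    n_background_genes=100,
    samples_per_group=4,
    n_shared_dysregulated=2,
    n_species_specific=2,
    effect_size=2.5,
)

FAST_CFG = dict(
    enrichment=EnrichmentParams(n_permutations=200, seed=0),
    alpha_grid=(1.0, 1e-2, 1e-4, 1e-6),
    c_grid=tuple(np.logspace(-3, 2, 12)),
)


@pytest.fixture(scope="module")
def small_report():
    study = generate_study(SyntheticConfig(**SMALL_STUDY, seed=0))
    cfg = WorkflowConfig(**FAST_CFG)
    report = run_workflow(study.mouse, study.human, study.mouse_sets, study.human_sets, cfg)
    return study, cfg, report


class TestSharedComponents:
    def test_disjoint_sets(self):
        assert shared_components({"sPC1"}, {"sPC2", "sPC3", "sPC4", "sPC6"}) == []

    def test_overlap(self):
        assert shared_components({"sPC1"}, {"sPC1", "sPC3"}) == ["sPC1"]

    def test_empty(self):
        assert shared_components({"sPC1", "sPC2"}, set()) == []


class TestCandidatePathways:
    def _model(self, B, pathways):
        k = B.shape[1]
        return SparsePCModel(
            loadings=pd.DataFrame(B, index=pathways, columns=[f"sPC{j+1}" for j in range(k)]),
            rotation=np.eye(len(pathways))[:, :k],
            alpha=0.0,
            beta=0.0,
            explained_variance_fractions=np.zeros(k),
            total_variance=1.0,
        )

    def test_no_shared_no_candidates(self):
        model = self._model(np.ones((3, 2)), ["P1", "P2", "P3"])
        assert candidate_pathways(model, []) == []

    def test_planted_sparsity_pattern_recovered(self):
        B = np.zeros((5, 2))
        B[2, 0] = 0.9   # P3 on sPC1
        B[4, 0] = -0.3  # P7-like on sPC1
        B[1, 1] = 0.5   # P2 on sPC2 (not shared)
        model = self._model(B, ["P1", "P2", "P3", "P5", "P7"])
        assert candidate_pathways(model, ["sPC1"]) == ["P3", "P7"]
        assert candidate_pathways(model, [0]) == ["P3", "P7"]


class TestRefine:
    def _nes(self, rows, phenotype, species):
        df = pd.DataFrame.from_dict(rows, orient="index")
        samples = [f"{species}{i}" for i in range(df.shape[1])]
        df.columns = samples
        return EnrichmentMatrix(
            nes=df,
            species=species,
            phenotype=pd.Series(phenotype, index=samples),
            params=EnrichmentParams(),
        )

    def test_single_separating_candidate(self):
        rng = np.random.default_rng(0)
        healthy = [-1.2, -0.8, -1.0, -0.9]
        diseased = [1.1, 0.9, 1.3, 1.0]
        mouse = self._nes(
            {"GOOD": healthy + diseased, "NOISE": list(rng.normal(size=8))},
            [0] * 4 + [1] * 4,
            "m",
        )
        human = self._nes(
            {"GOOD": healthy + diseased, "NOISE": list(rng.normal(size=8))},
            [0] * 4 + [1] * 4,
            "h",
        )
        cfg = WorkflowConfig(**FAST_CFG)
        translatable, summary = refine_translatable(mouse, human, ["GOOD", "NOISE"], cfg)
        assert translatable == ["GOOD"]
        assert summary.loocv_metrics.f1 == 1.0

    def test_empty_candidates(self):
        mouse = self._nes({"P": [0.0, 1.0, 2.0, 3.0]}, [0, 0, 1, 1], "m")
        human = self._nes({"P": [0.0, 1.0, 2.0, 3.0]}, [0, 0, 1, 1], "h")
        translatable, summary = refine_translatable(mouse, human, [], WorkflowConfig(**FAST_CFG))
        assert translatable == [] and summary is None


class TestRunWorkflow:
    def test_recovers_planted_shared_pathways(self, small_report):
        study, _, report = small_report
        assert report.status == "ok"
        # every translatable pathway must be a candidate, and the planted
        # shared signal must reach the final set; at this scale the sparsest
        # accepted alpha may prune some planted pathways from the candidates
        recovered = set(report.translatable) & set(study.shared_pathways)
        assert len(recovered) >= 1
        assert set(report.translatable) <= set(report.candidates)
        human_only = set(study.specific_pathways["human"])
        assert not (set(report.translatable) & human_only)

    def test_report_orderings_canonical(self, small_report):
        _, _, report = small_report
        assert report.candidates == sorted(report.candidates)
        assert report.translatable == sorted(report.translatable)
        assert report.shared == sorted(report.shared)

    def test_rerun_byte_identical(self, small_report):
        study, cfg, report = small_report
        again = run_workflow(study.mouse, study.human, study.mouse_sets, study.human_sets, cfg)
        assert again.to_json() == report.to_json()

    def test_model_species_is_first_argument(self, small_report):
        study, cfg, report = small_report
        swapped = run_workflow(study.human, study.mouse, study.human_sets, study.mouse_sets, cfg)
        # the sPC model is built on whichever dataset is passed first: the
        # training-score sample ids follow that dataset
        assert report.spca_model.loadings.shape[0] == swapped.spca_model.loadings.shape[0]
        assert report.mouse_summary.species == swapped.mouse_summary.species == "mouse"
        assert report.to_json() != swapped.to_json()

    def test_constant_expression_fails_with_stage_name(self):
        study = generate_study(SyntheticConfig(**SMALL_STUDY, seed=1))
        flat = ExpressionDataset(
            values=pd.DataFrame(
                1.0, index=study.mouse.gene_ids, columns=study.mouse.sample_ids
            ),
            species="mouse",
            phenotype=study.mouse.phenotype,
        )
        with pytest.raises(WorkflowError) as err:
            run_workflow(flat, study.human, study.mouse_sets, study.human_sets,
                         WorkflowConfig(**FAST_CFG))
        assert err.value.stage in {"enrichment", "transform", "validate"}

    def test_null_shared_effect_reports_none(self):
        study = generate_study(
            SyntheticConfig(**SMALL_STUDY, shared_effect_size=0.0, seed=2)
        )
        cfg = WorkflowConfig(**FAST_CFG)
        report = run_workflow(study.mouse, study.human, study.mouse_sets, study.human_sets, cfg)
        if report.status == NO_TRANSLATABLE:
            assert not report.translatable
            if not report.shared:
                assert not report.candidates


class TestRelaxAlpha:
    def test_early_exit_identical_to_run_workflow(self, small_report):
        study, cfg, report = small_report
        if report.shared:
            relaxed = relax_alpha(
                study.mouse, study.human, study.mouse_sets, study.human_sets, cfg
            )
            assert relaxed.to_json() == report.to_json()

    def test_relaxation_trace_and_stopping_alpha(self):
        # shared-null study: the first workflow pass usually finds no overlap,
        # so the relaxation walks the grid; verify its stopping alpha against
        # a per-alpha re-evaluation of the overlap criterion
        study = generate_study(
            SyntheticConfig(**SMALL_STUDY, shared_effect_size=0.0, seed=3)
        )
        cfg = WorkflowConfig(**FAST_CFG)
        base = run_workflow(study.mouse, study.human, study.mouse_sets, study.human_sets, cfg)
        grid = [base.alpha, base.alpha / 10.0, base.alpha / 100.0]
        report = relax_alpha(
            study.mouse, study.human, study.mouse_sets, study.human_sets, cfg,
            alpha_grid=grid,
        )
        if base.shared:
            assert report.to_json() == base.to_json()
            return
        trace = report.provenance["alpha_relaxation_trace"]
        assert [t["alpha"] for t in trace] == grid[: len(trace)]
        for step in trace[:-1]:
            assert step["shared_components"] == []
        if report.shared:
            assert trace[-1]["shared_components"] == report.shared
            assert report.alpha == trace[-1]["alpha"]
        else:
            assert report.status == NO_TRANSLATABLE
            assert len(trace) == len(grid)
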