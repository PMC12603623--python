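"""Two-species workflow orchestration and translatable-pathway refinement.

The workflow, end to end:

1. harmonize the two species' gene-set collections (shared pathway names,
   size filter);
2. build the pathways x samples NES matrix for each species;
3. power transform each species' matrix independently;
4. choose the sparsity penalty alpha by LOOCV on the model species (the
   "mouse"), fit the sparse PC model there, and project the other species
   ("human") into it;
5. train one L1 SVM per species on the component scores and record which
   components each uses;
6. intersect the two nonzero-component sets; pathways loading on a shared
   component are *candidates*;
7. refine: pool both species' raw NES over the candidate pathways, power
   transform the pooled matrix, train a species-blind L1 SVM on phenotype -
   its nonzero-weight pathways are the final *translatable* set.

If the two species' SVMs share no component, the report carries the status
``"no translatable pathways"``; :func:`relax_alpha` implements the fallback
of walking alpha downward (denser components) until an overlap appears.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    ClassificationMetrics,
    CVReport,
    LinearL1SVM,
    default_c_grid,
    evaluate,
    fit_l1_svm,
    nonzero_features,
    predict,
    select_C,
)
from .datasets import ExpressionDataset, GeneSetCollection, harmonize_gene_sets
from .enrichment import EnrichmentMatrix, EnrichmentParams, build_enrichment_matrix
from .spca import AlphaSelectionResult, SparsePCModel, fit_spca, project, select_alpha
from .transform import PowerTransformModel, apply_power_transform, fit_power_transform

logger = logging.getLogger(__name__)

__all__ = [
    "WorkflowConfig",
    "WorkflowError",
    "SpeciesClassifierSummary",
    "TranslatabilityReport",
    "shared_components",
    "candidate_pathways",
    "refine_translatable",
    "run_workflow",
    "relax_alpha",
]

NO_TRANSLATABLE = "no translatable pathways"


class WorkflowError(RuntimeError):
    """A stage-named failure of the orchestrated workflow."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class WorkflowConfig:
    """All workflow constants in one place.

    ``alpha_grid`` defaults to 10 log-spaced points from 1 down to 1e-6;
    ``variance_threshold`` and ``n_components_criterion`` encode the
    ">= 50% of total variance in the first three components" selection rule.
    ``strict_alpha`` controls what happens when no grid alpha meets the
    threshold: abort (True), or fall back to the same threshold applied
    relative to the attainable maximum (largest alpha with mean LOOCV
    cumulative variance >= threshold * best), flagged in the report
    (False, default).
    """

    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    alpha_grid: tuple = tuple(np.logspace(0, -6, 10))
    variance_threshold: float = 0.5
    n_components_criterion: int = 3
    k: int | None = None
    beta: float = 0.0
    spca_tol: float = 1e-6
    spca_max_iter: int = 1000
    c_grid: tuple = tuple(default_c_grid())
    min_gene_set_size: int = 5
    max_gene_set_size: int = 1000
    feature_tol: float = 1e-8
    loading_tol: float = 1e-8
    strict_alpha: bool = False

    def __post_init__(self) -> None:
        if not self.alpha_grid or not self.c_grid:
            raise ValueError("grids must be non-empty")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")


@dataclass
class SpeciesClassifierSummary:
    species: str
    chosen_C: float
    cv_report: CVReport
    loocv_metrics: ClassificationMetrics
    training_metrics: ClassificationMetrics
    nonzero_components: list[str]
    model: LinearL1SVM = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "chosen_C": float(self.chosen_C),
            "cv": self.cv_report.to_dict(),
            "loocv_metrics": self.loocv_metrics.to_dict(),
            "training_metrics": self.training_metrics.to_dict(),
            "nonzero_components": list(self.nonzero_components),
            "weights": self.model.weights.tolist() if self.model else None,
            "intercept": self.model.intercept if self.model else None,
        }


@dataclass
class TranslatabilityReport:
    status: str                      # "ok" or NO_TRANSLATABLE
    alpha: float
    alpha_threshold_met: bool
    alpha_selection: AlphaSelectionResult
    mouse_summary: SpeciesClassifierSummary
    human_summary: SpeciesClassifierSummary
    shared: list[str]
    candidates: list[str]
    translatable: list[str]
    combined_summary: SpeciesClassifierSummary | None
    mouse_variance_fractions: list[float]
    human_variance_fractions: list[float]
    provenance: dict = field(default_factory=dict)
    # frozen artifacts for downstream (drug-response) evaluation
    spca_model: SparsePCModel = field(repr=False, default=None)
    mouse_transform: PowerTransformModel = field(repr=False, default=None)
    human_transform: PowerTransformModel = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not set(self.translatable) <= set(self.candidates):
            raise ValueError("translatable must be a subset of candidates")
        if not self.shared and (self.candidates or self.translatable):
            raise ValueError("empty shared set cannot yield candidates")

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "alpha": float(self.alpha),
            "alpha_threshold_met": self.alpha_threshold_met,
            "alpha_selection": {
                "grid": [float(a) for a in self.alpha_selection.grid],
                "mean_cumvar": [float(v) for v in self.alpha_selection.mean_cumvar],
                "var_cumvar": [float(v) for v in self.alpha_selection.var_cumvar],
                "threshold": float(self.alpha_selection.threshold),
                "chosen": None
                if self.alpha_selection.chosen is None
                else float(self.alpha_selection.chosen),
            },
            "mouse_svm": self.mouse_summary.to_dict(),
            "human_svm": self.human_summary.to_dict(),
            "shared_components": list(self.shared),
            "candidate_pathways": list(self.candidates),
            "translatable_pathways": list(self.translatable),
            "combined_svm": None if self.combined_summary is None else self.combined_summary.to_dict(),
            "mouse_variance_fractions": [float(v) for v in self.mouse_variance_fractions],
            "human_variance_fractions": [float(v) for v in self.human_variance_fractions],
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def shared_components(mouse_set, human_set) -> list[str]:
    """Components used (nonzero weight) by both species' SVMs."""
    return sorted(set(mouse_set) & set(human_set))


def candidate_pathways(model: SparsePCModel, shared, tol: float = 1e-8) -> list[str]:
    """Pathways with |loading| > tol in at least one shared component."""
    names = list(model.component_names)
    indices = []
    for c in shared:
        indices.append(names.index(c) if isinstance(c, str) else int(c))
    return model.nonzero_pathways(indices, tol=tol)


def _loocv_metrics(X: np.ndarray, y: np.ndarray, C: float) -> ClassificationMetrics:
    """Metrics on pooled leave-one-out held-out predictions at a fixed C."""
    n = len(y)
    preds, decs, truths = [], [], []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            continue
        model = fit_l1_svm(X[mask], y[mask], C)
        lab, dec = predict(model, X[i][None, :])
        preds.append(int(lab[0]))
        decs.append(float(dec[0]))
        truths.append(int(y[i]))
    return evaluate(truths, preds, decs)


def _fit_species_svm(
    scores: pd.DataFrame, y: np.ndarray, species: str, cfg: WorkflowConfig
) -> SpeciesClassifierSummary:
    X = scores.to_numpy(dtype=float)
    cv = select_C(X, y, cfg.c_grid)
    model = fit_l1_svm(scores, y, cv.chosen_C)
    train_lab, train_dec = predict(model, scores)
    return SpeciesClassifierSummary(
        species=species,
        chosen_C=cv.chosen_C,
        cv_report=cv,
        loocv_metrics=_loocv_metrics(X, y, cv.chosen_C),
        training_metrics=evaluate(y, train_lab, train_dec),
        nonzero_components=sorted(nonzero_features(model, cfg.feature_tol)),
        model=model,
    )


def refine_translatable(
    mouse_nes: EnrichmentMatrix,
    human_nes: EnrichmentMatrix,
    candidates: list[str],
    cfg: WorkflowConfig | None = None,
) -> tuple[list[str], SpeciesClassifierSummary | None]:
    """Species-blind combined SVM over the candidate pathways' raw NES.

    Samples of both species, restricted to the candidate pathways, are pooled
    (raw NES, not the species-specific transformed values), jointly power
    transformed, and classified on phenotype only - the feature matrix
    carries no species information.  Pathways the combined SVM leaves at
    nonzero weight are the translatable set.
    """
    cfg = cfg or WorkflowConfig()
    if not candidates:
        return [], None
    missing = [
        p
        for p in candidates
        if p not in mouse_nes.nes.index or p not in human_nes.nes.index
    ]
    if missing:
        raise WorkflowError("refine", f"candidates absent from NES matrices: {missing}")
    pooled = pd.concat(
        [mouse_nes.nes.loc[candidates], human_nes.nes.loc[candidates]], axis=1
    )
    phenotype = pd.concat([mouse_nes.phenotype, human_nes.phenotype])
    pooled_matrix = EnrichmentMatrix(
        nes=pooled,
        species="combined",
        phenotype=phenotype,
        params=mouse_nes.params,
    )
    _, transformed = fit_power_transform(pooled_matrix, tag="combined")
    X = transformed.T  # samples x pathways
    y = phenotype.reindex(X.index).to_numpy(dtype=int)
    summary = _fit_species_svm(X, y, "combined", cfg)
    translatable = sorted(nonzero_features(summary.model, cfg.feature_tol))
    return translatable, summary


def _prepare_matrices(
    mouse_ds: ExpressionDataset,
    human_ds: ExpressionDataset,
    mouse_sets: GeneSetCollection,
    human_sets: GeneSetCollection,
    cfg: WorkflowConfig,
):
    """Stages 1-3: harmonize, NES, per-species power transform, alignment."""
    try:
        mouse_ds.validate(require_groups=True)
        human_ds.validate(require_groups=True)
    except ValueError as exc:
        raise WorkflowError("validate", str(exc)) from exc
    try:
        m_sets, h_sets = harmonize_gene_sets(
            mouse_sets, human_sets, cfg.min_gene_set_size, cfg.max_gene_set_size
        )
    except ValueError as exc:
        raise WorkflowError("harmonize", str(exc)) from exc
    try:
        mouse_nes = build_enrichment_matrix(mouse_ds, m_sets, cfg.enrichment)
        human_nes = build_enrichment_matrix(human_ds, h_sets, cfg.enrichment)
    except ValueError as exc:
        raise WorkflowError("enrichment", str(exc)) from exc

    # pathways must survive in both species; drops propagate to both matrices
    common = sorted(set(mouse_nes.nes.index) & set(human_nes.nes.index))
    if not common:
        raise WorkflowError("enrichment", "no pathway defined in both species")
    mouse_nes.nes = mouse_nes.nes.loc[common]
    human_nes.nes = human_nes.nes.loc[common]

    try:
        mouse_pt, mouse_t = fit_power_transform(mouse_nes, tag=mouse_ds.species)
        human_pt, human_t = fit_power_transform(human_nes, tag=human_ds.species)
    except ValueError as exc:
        raise WorkflowError("transform", str(exc)) from exc
    kept = sorted(set(mouse_t.index) & set(human_t.index))
    if not kept:
        raise WorkflowError("transform", "no pathway survived power transformation")
    mouse_t, human_t = mouse_t.loc[kept], human_t.loc[kept]
    return mouse_nes, human_nes, mouse_pt, human_pt, mouse_t, human_t


def _fit_models_at_alpha(
    alpha: float,
    mouse_t: pd.DataFrame,
    human_t: pd.DataFrame,
    mouse_y: np.ndarray,
    human_y: np.ndarray,
    k: int,
    cfg: WorkflowConfig,
):
    """Stages 4-6 at a fixed alpha: sPCA fit, projection, per-species SVMs."""
    Xm = mouse_t.T  # samples x pathways
    model = fit_spca(
        Xm, k=k, alpha=alpha, beta=cfg.beta, tol=cfg.spca_tol, max_iter=cfg.spca_max_iter
    )
    mouse_proj = project(model, Xm)
    human_proj = project(model, human_t.T)
    mouse_summary = _fit_species_svm(mouse_proj.scores, mouse_y, "mouse", cfg)
    human_summary = _fit_species_svm(human_proj.scores, human_y, "human", cfg)
    shared = shared_components(
        mouse_summary.nonzero_components, human_summary.nonzero_components
    )
    return model, mouse_proj, human_proj, mouse_summary, human_summary, shared


def run_workflow(
    mouse_ds: ExpressionDataset,
    human_ds: ExpressionDataset,
    mouse_sets: GeneSetCollection,
    human_sets: GeneSetCollection,
    cfg: WorkflowConfig | None = None,
) -> TranslatabilityReport:
    """Execute the full two-species workflow and assemble the report.

    The sparse PC model is always built on ``mouse_ds`` (the model species);
    ``human_ds`` is projected into it.  The workflow is deliberately
    asymmetric in its two inputs.
    """
    cfg = cfg or WorkflowConfig()
    mouse_nes, human_nes, mouse_pt, human_pt, mouse_t, human_t = _prepare_matrices(
        mouse_ds, human_ds, mouse_sets, human_sets, cfg
    )
    mouse_y = mouse_nes.phenotype.reindex(mouse_t.columns).to_numpy(dtype=int)
    human_y = human_nes.phenotype.reindex(human_t.columns).to_numpy(dtype=int)

    n_mouse = mouse_t.shape[1]
    k = cfg.k if cfg.k is not None else n_mouse - 1
    k = min(k, n_mouse - 1, mouse_t.shape[0])

    try:
        selection = select_alpha(
            mouse_t.T,
            cfg.alpha_grid,
            k=k,
            threshold=cfg.variance_threshold,
            n_components_criterion=cfg.n_components_criterion,
            beta=cfg.beta,
            tol=cfg.spca_tol,
            max_iter=cfg.spca_max_iter,
        )
    except ValueError as exc:
        raise WorkflowError("select_alpha", str(exc)) from exc
    if selection.chosen is not None:
        alpha, threshold_met = selection.chosen, True
    elif cfg.strict_alpha:
        raise WorkflowError(
            "select_alpha",
            f"no grid alpha reached mean cumulative variance >= {cfg.variance_threshold}",
        )
    else:
        # fallback: the absolute variance floor is unattainable on this data
        # (possible whenever samples are many relative to the floor, since
        # variance then spreads over many comparable directions).  Apply the
        # same floor *relative to the attainable maximum*: the largest grid
        # alpha whose mean LOOCV cumulative variance is >= threshold * best.
        # This keeps the selection in the sparse regime the workflow's
        # candidate-filtering step depends on; a dense fallback would make
        # the shared-component restriction vacuous.
        best = float(selection.mean_cumvar.max())
        ok = np.flatnonzero(selection.mean_cumvar >= cfg.variance_threshold * best)
        alpha, threshold_met = float(selection.grid[ok[0]]), False
        logger.warning(
            "alpha threshold %.2f unmet (best mean cumvar %.3f); relative-floor "
            "fallback picks alpha=%g",
            cfg.variance_threshold, best, alpha,
        )

    try:
        model, mouse_proj, human_proj, mouse_summary, human_summary, shared = (
            _fit_models_at_alpha(alpha, mouse_t, human_t, mouse_y, human_y, k, cfg)
        )
    except ValueError as exc:
        raise WorkflowError("spca", str(exc)) from exc

    candidates = candidate_pathways(model, shared, tol=cfg.loading_tol) if shared else []
    translatable, combined_summary = refine_translatable(
        mouse_nes, human_nes, candidates, cfg
    )
    status = "ok" if translatable else NO_TRANSLATABLE

    provenance = {
        "seed": cfg.enrichment.seed,
        "enrichment_params": cfg.enrichment.to_dict(),
        "alpha_grid": [float(a) for a in cfg.alpha_grid],
        "c_grid": [float(c) for c in cfg.c_grid],
        "k": int(k),
        "variance_threshold": cfg.variance_threshold,
        "n_components_criterion": cfg.n_components_criterion,
        "dropped_pathways": {
            "mouse_enrichment": mouse_nes.dropped,
            "human_enrichment": human_nes.dropped,
            "mouse_transform": mouse_pt.dropped,
            "human_transform": human_pt.dropped,
        },
    }
    return TranslatabilityReport(
        status=status,
        alpha=alpha,
        alpha_threshold_met=threshold_met,
        alpha_selection=selection,
        mouse_summary=mouse_summary,
        human_summary=human_summary,
        shared=shared,
        candidates=candidates,
        translatable=translatable,
        combined_summary=combined_summary,
        mouse_variance_fractions=list(mouse_proj.variance_fractions),
        human_variance_fractions=list(human_proj.variance_fractions),
        provenance=provenance,
        spca_model=model,
        mouse_transform=mouse_pt,
        human_transform=human_pt,
    )


def relax_alpha(
    mouse_ds: ExpressionDataset,
    human_ds: ExpressionDataset,
    mouse_sets: GeneSetCollection,
    human_sets: GeneSetCollection,
    cfg: WorkflowConfig | None = None,
    alpha_grid=None,
) -> TranslatabilityReport:
    """Walk alpha downward until the two species' SVMs share a component.

    Starts from the originally selected alpha; the default relaxation grid is
    20 log-spaced points per decade down to 1e-6.  Stops at the first alpha
    with a nonempty shared-component set; exhaustion is a reported outcome
    (status ``"no translatable pathways"``), never an exception.
    """
    cfg = cfg or WorkflowConfig()
    report = run_workflow(mouse_ds, human_ds, mouse_sets, human_sets, cfg)
    if report.shared:
        return report

    start_alpha = report.alpha
    if alpha_grid is None:
        lo = 1e-6
        if start_alpha <= lo:
            alpha_grid = [start_alpha]
        else:
            decades = np.log10(start_alpha) - np.log10(lo)
            n_points = max(2, int(round(20 * decades)) + 1)
            alpha_grid = np.logspace(np.log10(start_alpha), np.log10(lo), n_points)
    alpha_grid = sorted({float(a) for a in alpha_grid}, reverse=True)
    if alpha_grid and not np.isclose(alpha_grid[0], start_alpha):
        raise ValueError("relaxation grid must start at the selected alpha")

    mouse_nes, human_nes, mouse_pt, human_pt, mouse_t, human_t = _prepare_matrices(
        mouse_ds, human_ds, mouse_sets, human_sets, cfg
    )
    mouse_y = mouse_nes.phenotype.reindex(mouse_t.columns).to_numpy(dtype=int)
    human_y = human_nes.phenotype.reindex(human_t.columns).to_numpy(dtype=int)
    k = report.provenance["k"]

    trace = []
    for alpha in alpha_grid:
        model, mouse_proj, human_proj, mouse_summary, human_summary, shared = (
            _fit_models_at_alpha(float(alpha), mouse_t, human_t, mouse_y, human_y, k, cfg)
        )
        trace.append({"alpha": float(alpha), "shared_components": list(shared)})
        if shared:
            candidates = candidate_pathways(model, shared, tol=cfg.loading_tol)
            translatable, combined_summary = refine_translatable(
                mouse_nes, human_nes, candidates, cfg
            )
            provenance = dict(report.provenance)
            provenance["alpha_relaxation_trace"] = trace
            return TranslatabilityReport(
                status="ok" if translatable else NO_TRANSLATABLE,
                alpha=float(alpha),
                alpha_threshold_met=report.alpha_threshold_met,
                alpha_selection=report.alpha_selection,
                mouse_summary=mouse_summary,
                human_summary=human_summary,
                shared=shared,
                candidates=candidates,
                translatable=translatable,
                combined_summary=combined_summary,
                mouse_variance_fractions=list(mouse_proj.variance_fractions),
                human_variance_fractions=list(human_proj.variance_fractions),
                provenance=provenance,
                spca_model=model,
                mouse_transform=mouse_pt,
                human_transform=human_pt,
            )
    report.provenance["alpha_relaxation_trace"] = trace
    report.status = NO_TRANSLATABLE
    return report
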