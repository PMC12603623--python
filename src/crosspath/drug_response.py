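"""Classify drug-treated samples through the frozen untreated pipeline.

A treated dataset (treated animals plus their own untreated controls) is
pushed through the transforms learned on the *untreated* study: NES with the
same enrichment parameters (fold change referenced to the treated dataset's
own control group), the frozen per-pathway power transform (no refit), the
fixed sparse PC model, and the already-trained SVM.  Nothing is refit; the
evaluation answers "does the disease signature persist under treatment?"
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LinearL1SVM, predict
from .datasets import ExpressionDataset, GeneSetCollection
from .enrichment import EnrichmentMatrix, EnrichmentParams, build_enrichment_matrix
from .spca import SparsePCModel, project
from .transform import PowerTransformModel, apply_power_transform

logger = logging.getLogger(__name__)

__all__ = ["TreatmentEvaluation", "evaluate_treatment"]


@dataclass
class TreatmentEvaluation:
    sample_ids: list[str]
    predicted: np.ndarray            # per-sample predicted phenotype
    decisions: np.ndarray            # per-sample decision value
    treated_mask: np.ndarray
    control_mask: np.ndarray
    fraction_treated_diseased: float
    fraction_controls_healthy: float
    provenance: dict = field(default_factory=dict)

    @property
    def n_treated(self) -> int:
        return int(self.treated_mask.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_mask.sum())

    def to_dict(self) -> dict:
        return {
            "samples": self.sample_ids,
            "predicted": [int(v) for v in self.predicted],
            "decisions": [float(v) for v in self.decisions],
            "treated": [bool(v) for v in self.treated_mask],
            "fraction_treated_diseased": self.fraction_treated_diseased,
            "fraction_controls_healthy": self.fraction_controls_healthy,
            "provenance": self.provenance,
        }


def evaluate_treatment(
    treated_ds: ExpressionDataset,
    sets: GeneSetCollection,
    frozen_transform: PowerTransformModel,
    spca_model: SparsePCModel,
    svm: LinearL1SVM,
    params: EnrichmentParams | None = None,
) -> TreatmentEvaluation:
    """Frozen-pipeline classification of a treatment arm.

    ``treated_ds`` must contain an untreated control group (the fold-change
    reference) alongside the treated samples.  The frozen artifacts must
    originate from one untreated run over the same pathway collection; a
    pathway of the sparse PC model missing from the treated NES matrix is an
    error, never silently imputed.
    """
    params = params or EnrichmentParams()
    if not treated_ds.healthy_samples():
        raise ValueError("treated dataset has no control (healthy) group")

    nes = build_enrichment_matrix(treated_ds, sets, params)
    needed = spca_model.pathway_names
    missing = [p for p in needed if p not in nes.nes.index]
    if missing:
        raise ValueError(
            f"pathways of the frozen model undefined in the treated data: {missing}"
        )
    nes_needed = EnrichmentMatrix(
        nes=nes.nes.loc[needed],
        species=nes.species,
        phenotype=nes.phenotype,
        params=params,
        dropped=nes.dropped,
    )
    transformed = apply_power_transform(frozen_transform, nes_needed)  # no refit
    proj = project(spca_model, transformed.T)
    labels, decisions = predict(svm, proj.scores)

    treated_mask = treated_ds.treated.reindex(proj.scores.index).to_numpy(dtype=bool)
    control_mask = (~treated_mask) & (
        treated_ds.phenotype.reindex(proj.scores.index).to_numpy(dtype=int) == 0
    )
    if treated_mask.sum() == 0:
        raise ValueError("no treated samples in dataset")
    frac_diseased = float(labels[treated_mask].mean())
    frac_healthy = float(1.0 - labels[control_mask].mean()) if control_mask.sum() else float("nan")
    return TreatmentEvaluation(
        sample_ids=list(proj.scores.index),
        predicted=labels,
        decisions=decisions,
        treated_mask=treated_mask,
        control_mask=control_mask,
        fraction_treated_diseased=frac_diseased,
        fraction_controls_healthy=frac_healthy,
        provenance={
            "svm_C": svm.C,
            "spca_alpha": spca_model.alpha,
            "enrichment_params": params.to_dict(),
        },
    )
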