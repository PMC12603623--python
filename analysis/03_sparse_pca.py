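#!/usr/bin/env python
"""Sparse PC model on the mouse NES matrix; project the human data into it.

The sparsity penalty is chosen by leave-one-out cross-validation (largest
alpha keeping >= 50% of total variance in the first three components; when
that absolute floor is unattainable the same threshold is applied relative
to the attainable maximum); the
human matrix is then projected through the mouse loadings and per-component
variance is attributed sequentially.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from crosspath import EnrichmentParams, fit_spca, project, select_alpha
from crosspath.enrichment import EnrichmentMatrix
from crosspath.transform import fit_power_transform

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1
ALPHA_GRID = tuple(np.logspace(0, -6, 10))


def load_nes(species: str) -> EnrichmentMatrix:
    nes = pd.read_csv(ROOT / "enrichment" / f"{species}_nes.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(ROOT / "study" / f"{species}_metadata.tsv", sep="\t").set_index("sample_id")
    return EnrichmentMatrix(
        nes=nes,
        species=species,
        phenotype=meta["phenotype"].reindex(nes.columns),
        params=EnrichmentParams(seed=SEED),
    )


def main() -> None:
    out = ROOT / "spca"
    out.mkdir(parents=True, exist_ok=True)

    mouse = load_nes("mouse")
    human = load_nes("human")
    _, mouse_t = fit_power_transform(mouse, tag="mouse")
    _, human_t = fit_power_transform(human, tag="human")
    common = sorted(set(mouse_t.index) & set(human_t.index))
    mouse_t, human_t = mouse_t.loc[common], human_t.loc[common]

    X = mouse_t.T
    k = X.shape[0] - 1
    selection = select_alpha(X, ALPHA_GRID, k=k)
    if selection.chosen is not None:
        alpha = selection.chosen
        print(f"alpha = {alpha:g} meets the 50% floor")
    else:
        best = float(selection.mean_cumvar.max())
        ok = np.flatnonzero(selection.mean_cumvar >= 0.5 * best)
        alpha = float(selection.grid[ok[0]])
        print(f"50% floor unattainable (best mean cumvar {best:.3f}); "
              f"relative-floor fallback alpha = {alpha:g}")

    model = fit_spca(X, k=k, alpha=alpha)
    model.to_json(out / "spca_model.json")
    model.loadings.rename_axis("pathway").to_csv(out / "loadings.tsv", sep="\t")
    human_proj = project(model, human_t.T)
    human_proj.scores.rename_axis("sample").to_csv(out / "human_scores.tsv", sep="\t")
    project(model, X).scores.rename_axis("sample").to_csv(out / "mouse_scores.tsv", sep="\t")

    with open(out / "alpha_selection.json", "w") as fh:
        json.dump({
            "grid": [float(a) for a in selection.grid],
            "mean_cumvar": [float(v) for v in selection.mean_cumvar],
            "var_cumvar": [float(v) for v in selection.var_cumvar],
            "chosen": selection.chosen,
            "alpha_used": alpha,
        }, fh, indent=2, sort_keys=True)

    nnz = (model.loadings.abs() > 1e-8).sum()
    print(f"model: k={model.k}; nonzero loadings per component: {list(nnz[:5])} ...")
    print("variance fractions (mouse, first 5): "
          f"{np.round(model.explained_variance_fractions[:5], 3)}")
    print("variance fractions (human projection, first 5): "
          f"{np.round(human_proj.variance_fractions[:5], 3)}")


if __name__ == "__main__":
    main()
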