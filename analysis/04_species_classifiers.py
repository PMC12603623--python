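#!/usr/bin/env python
"""Species-specific sparse SVMs on the component scores.

One L1-regularized linear SVM per species, trained on that species' scores
in the mouse component space, with C chosen by pooled-LOOCV F1.  The
components each classifier actually uses (nonzero weights) are recorded;
their intersection is the candidate source of translatable pathways.
"""

import json
from pathlib import Path

import pandas as pd

from crosspath import evaluate, fit_l1_svm, nonzero_features, predict, select_C

ROOT = Path(__file__).resolve().parent.parent / "results"


def classify(species: str, out: Path) -> set:
    scores = pd.read_csv(ROOT / "spca" / f"{species}_scores.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(ROOT / "study" / f"{species}_metadata.tsv", sep="\t").set_index("sample_id")
    y = meta["phenotype"].reindex(scores.index).to_numpy()
    cv = select_C(scores.to_numpy(), y)
    model = fit_l1_svm(scores, y, cv.chosen_C)
    labels, decisions = predict(model, scores)
    metrics = evaluate(y, labels, decisions)
    used = nonzero_features(model)
    model.to_json(out / f"{species}_svm.json")
    with open(out / f"{species}_cv.json", "w") as fh:
        json.dump(cv.to_dict(), fh, indent=2, sort_keys=True)
    print(f"{species}: C={cv.chosen_C:.4g}, training accuracy {metrics.accuracy:.2f}, "
          f"F1 {metrics.f1:.2f}, AUC {metrics.auc}")
    print(f"  components used: {sorted(used)}")
    return used


def main() -> None:
    out = ROOT / "classifiers"
    out.mkdir(parents=True, exist_ok=True)
    mouse_used = classify("mouse", out)
    human_used = classify("human", out)
    shared = sorted(mouse_used & human_used)
    print(f"shared components: {shared if shared else 'none'}")
    with open(out / "shared_components.json", "w") as fh:
        json.dump({"shared": shared}, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
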