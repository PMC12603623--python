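#!/usr/bin/env python
"""Classify simulated drug-treated arms through the frozen untreated pipeline.

Treatment arms with efficacy 0 (drug does nothing), 0.5 and 1 (disease
signature fully removed) are pushed through the frozen transforms, the fixed
sparse PC model and the trained mouse SVM from the untreated run.  An
ineffective drug should leave treated samples classified diseased; a fully
effective one should move them to the healthy side.
"""

import json
from pathlib import Path

from crosspath import (
    EnrichmentParams,
    SyntheticConfig,
    evaluate_treatment,
    generate_study,
    generate_treatment_arm,
)
from crosspath.classify import LinearL1SVM
from crosspath.spca import SparsePCModel
from crosspath.transform import PowerTransformModel

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    art = ROOT / "translatability"
    out = ROOT / "drug"
    out.mkdir(parents=True, exist_ok=True)

    # regenerate the same study (same seed) to draw matched treatment arms
    study = generate_study(SyntheticConfig(seed=SEED))
    frozen_transform = PowerTransformModel.from_json(art / "mouse_transform.json")
    spca_model = SparsePCModel.from_json(art / "spca_model.json")
    svm = LinearL1SVM.from_json(art / "mouse_svm.json")
    params = EnrichmentParams(seed=SEED)

    results = {}
    for efficacy in (0.0, 0.5, 1.0):
        arm = generate_treatment_arm(
            study, efficacy, n_treated=5, n_control=4, seed=SEED + 100
        )
        ev = evaluate_treatment(
            arm, study.mouse_sets, frozen_transform, spca_model, svm, params
        )
        results[str(efficacy)] = ev.to_dict()
        print(f"efficacy {efficacy:.1f}: "
              f"{ev.fraction_treated_diseased:.2f} of treated classified diseased "
              f"({int(round(ev.fraction_treated_diseased * ev.n_treated))}/{ev.n_treated}); "
              f"{ev.fraction_controls_healthy:.2f} of controls classified healthy")

    with open(out / "treatment_evaluations.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
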