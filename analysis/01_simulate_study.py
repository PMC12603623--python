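#!/usr/bin/env python
"""Draw the synthetic two-species study used throughout the analysis.

Two species with disjoint gene universes share 100 pathway names; three
pathways are dysregulated in the diseased samples of both species (the
planted "translatable" truth), four more in each species alone.  Files are
written in the same TSV/GMT formats the workflow reads from disk.
"""

import json
from pathlib import Path

from crosspath import SyntheticConfig, generate_study
from crosspath.datasets import write_expression_table, write_gmt

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig(seed=SEED)
    study = generate_study(cfg)
    for species, ds, sets in (
        ("mouse", study.mouse, study.mouse_sets),
        ("human", study.human, study.human_sets),
    ):
        write_expression_table(
            ds, OUT / f"{species}_expression.tsv", OUT / f"{species}_metadata.tsv"
        )
        write_gmt(sets, OUT / f"{species}_sets.gmt")
    with open(OUT / "ground_truth.json", "w") as fh:
        json.dump(study.ground_truth(), fh, indent=2, sort_keys=True)

    print(f"study written to {OUT}")
    print(f"  mouse: {study.mouse.n_genes} genes x {study.mouse.n_samples} samples")
    print(f"  human: {study.human.n_genes} genes x {study.human.n_samples} samples")
    print(f"  planted shared pathways: {study.shared_pathways}")
    print(f"  mouse-specific: {study.specific_pathways['mouse']}")
    print(f"  human-specific: {study.specific_pathways['human']}")


if __name__ == "__main__":
    main()
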