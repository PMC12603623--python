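#!/usr/bin/env python
"""Convert each species' expression into a pathway x sample NES matrix.

Each sample is ranked by log2 fold change against its dataset's healthy-group
mean; per pathway the weighted running-sum enrichment score is normalized
against 1000 random gene sets of the same size.  The planted pathways should
stand out as strongly elevated in diseased samples of both species.
"""

import json
from pathlib import Path

from crosspath import EnrichmentParams, build_enrichment_matrix, harmonize_gene_sets
from crosspath.datasets import read_expression_table, read_gmt

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    study_dir = ROOT / "study"
    out = ROOT / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    params = EnrichmentParams(seed=SEED)

    sets = {
        sp: read_gmt(study_dir / f"{sp}_sets.gmt", species=sp) for sp in ("mouse", "human")
    }
    mouse_sets, human_sets = harmonize_gene_sets(sets["mouse"], sets["human"])
    truth = json.loads((study_dir / "ground_truth.json").read_text())

    for species, harmonized in (("mouse", mouse_sets), ("human", human_sets)):
        ds = read_expression_table(
            study_dir / f"{species}_expression.tsv",
            study_dir / f"{species}_metadata.tsv",
            species=species,
        )
        matrix = build_enrichment_matrix(ds, harmonized, params)
        matrix.nes.rename_axis("pathway").to_csv(out / f"{species}_nes.tsv", sep="\t")
        diseased = matrix.phenotype == 1
        planted = truth["shared_pathways"] + truth["specific_pathways"][species]
        shift = (
            matrix.nes.loc[planted, diseased[diseased].index].mean(axis=1)
            - matrix.nes.loc[planted, diseased[~diseased].index].mean(axis=1)
        )
        bg = [p for p in matrix.nes.index if p not in planted]
        bg_shift = (
            matrix.nes.loc[bg, diseased[diseased].index].mean().mean()
            - matrix.nes.loc[bg, diseased[~diseased].index].mean().mean()
        )
        print(f"{species}: NES matrix {matrix.nes.shape[0]} pathways x "
              f"{matrix.nes.shape[1]} samples ({len(matrix.dropped)} dropped)")
        print(f"  mean diseased-healthy NES shift, planted pathways: {shift.mean():.2f}")
        print(f"  mean shift, background pathways: {bg_shift:.2f}")


if __name__ == "__main__":
    main()
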