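"""Synthetic two-species expression studies with planted pathway effects.

The generator emulates the data shapes the workflow is built for: two
species ("mouse" and "human") with completely disjoint gene universes but a
shared pathway nomenclature, small groups of samples per phenotype, and a
planted disease signal - a subset of pathways dysregulated in the diseased
samples of *both* species (the translatable ground truth) plus subsets
dysregulated in one species only.  Expression is log-normal: per-gene
baselines on the log scale, an additive log-scale disease shift of
``effect_size * noise_sd`` for every gene of a dysregulated pathway, and
i.i.d. Gaussian log-scale noise on every entry.  Because the ranking metric
downstream is a log fold change, planted shifts translate monotonically into
enrichment-score shifts.

A treatment arm can be drawn on top of a study: treated samples are
diseased-type samples of the model species whose disease shift is scaled by
``(1 - efficacy)``, alongside fresh healthy controls - the structure of a
drug-qualification dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection

__all__ = ["SyntheticConfig", "SyntheticStudy", "generate_study", "generate_treatment_arm"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs of the synthetic generator.

    ``effect_size`` is the log-scale disease shift in units of the gene-level
    noise sd; ``shared_effect_size`` (default: same as ``effect_size``) lets
    the shared pathways be silenced for null studies while species-specific
    effects stay on.
    """

    n_pathways: int = 100
    genes_per_pathway: int = 12
    n_background_genes: int = 800
    samples_per_group: int = 8
    n_shared_dysregulated: int = 3
    n_species_specific: int = 4
    effect_size: float = 1.5
    shared_effect_size: float | None = None
    noise_sd: float = 1.0
    baseline_location: float = 5.0
    baseline_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        needed = self.n_shared_dysregulated + 2 * self.n_species_specific
        if needed > self.n_pathways:
            raise ValueError("dysregulated pathway counts exceed n_pathways")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")

    @property
    def shared_delta(self) -> float:
        d = self.effect_size if self.shared_effect_size is None else self.shared_effect_size
        return d * self.noise_sd

    @property
    def specific_delta(self) -> float:
        return self.effect_size * self.noise_sd


@dataclass
class SyntheticStudy:
    """Two generated datasets plus the planted ground truth."""

    mouse: ExpressionDataset
    human: ExpressionDataset
    mouse_sets: GeneSetCollection
    human_sets: GeneSetCollection
    shared_pathways: list[str]
    specific_pathways: dict[str, list[str]]
    config: SyntheticConfig
    # per-gene log-scale baselines, needed to draw matched treatment arms
    baselines: dict[str, pd.Series] = field(default_factory=dict, repr=False)

    def ground_truth(self) -> dict:
        return {
            "shared_pathways": list(self.shared_pathways),
            "specific_pathways": {k: list(v) for k, v in self.specific_pathways.items()},
            "effect_size": self.config.effect_size,
            "shared_effect_size": self.config.shared_delta / self.config.noise_sd,
            "seed": self.config.seed,
        }


def _species_genes(prefix: str, pathways: list[str], cfg: SyntheticConfig) -> tuple[list, dict]:
    gene_ids: list[str] = []
    sets: dict[str, frozenset] = {}
    for pw in pathways:
        members = [f"{prefix}_{pw}_g{j:02d}" for j in range(cfg.genes_per_pathway)]
        sets[pw] = frozenset(members)
        gene_ids.extend(members)
    gene_ids.extend(f"{prefix}_bg_{i:04d}" for i in range(cfg.n_background_genes))
    return gene_ids, sets


def _simulate_matrix(
    rng: np.random.Generator,
    gene_ids: list[str],
    baselines: np.ndarray,
    sets: dict[str, frozenset],
    dysregulated: dict[str, float],
    n_healthy: int,
    n_diseased: int,
    cfg: SyntheticConfig,
    sample_prefix: str,
    treated_flag: bool = False,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    n = n_healthy + n_diseased
    sample_ids = [f"{sample_prefix}_h{j:02d}" for j in range(n_healthy)] + [
        f"{sample_prefix}_d{j:02d}" for j in range(n_diseased)
    ]
    logx = baselines[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(gene_ids), n))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for pw, delta in dysregulated.items():
        if delta == 0.0:
            continue
        rows = [gene_pos[g] for g in sets[pw]]
        logx[np.ix_(rows, range(n_healthy, n))] += delta
    values = pd.DataFrame(np.exp(logx), index=gene_ids, columns=sample_ids)
    phenotype = pd.Series([0] * n_healthy + [1] * n_diseased, index=sample_ids)
    treated = pd.Series([False] * n_healthy + [treated_flag] * n_diseased, index=sample_ids)
    return values, phenotype, treated


def generate_study(cfg: SyntheticConfig | None = None) -> SyntheticStudy:
    """Draw a full two-species study; byte-identical under a fixed seed."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    pathways = [f"PW_{i:04d}" for i in range(cfg.n_pathways)]

    n_dys = cfg.n_shared_dysregulated + 2 * cfg.n_species_specific
    picked = rng.choice(cfg.n_pathways, size=n_dys, replace=False)
    shared = sorted(pathways[i] for i in picked[: cfg.n_shared_dysregulated])
    spec_mouse = sorted(
        pathways[i]
        for i in picked[cfg.n_shared_dysregulated : cfg.n_shared_dysregulated + cfg.n_species_specific]
    )
    spec_human = sorted(
        pathways[i] for i in picked[cfg.n_shared_dysregulated + cfg.n_species_specific :]
    )

    datasets: dict[str, ExpressionDataset] = {}
    collections: dict[str, GeneSetCollection] = {}
    baselines: dict[str, pd.Series] = {}
    for species, prefix, specific in (
        ("mouse", "mm", spec_mouse),
        ("human", "hs", spec_human),
    ):
        gene_ids, sets = _species_genes(prefix, pathways, cfg)
        base = rng.normal(cfg.baseline_location, cfg.baseline_scale, size=len(gene_ids))
        dys = {pw: cfg.shared_delta for pw in shared}
        dys.update({pw: cfg.specific_delta for pw in specific})
        values, phenotype, treated = _simulate_matrix(
            rng, gene_ids, base, sets, dys,
            cfg.samples_per_group, cfg.samples_per_group, cfg, sample_prefix=prefix,
        )
        datasets[species] = ExpressionDataset(
            values=values, species=species, phenotype=phenotype, treated=treated
        )
        collections[species] = GeneSetCollection(sets, species=species)
        baselines[species] = pd.Series(base, index=gene_ids)

    return SyntheticStudy(
        mouse=datasets["mouse"],
        human=datasets["human"],
        mouse_sets=collections["mouse"],
        human_sets=collections["human"],
        shared_pathways=shared,
        specific_pathways={"mouse": spec_mouse, "human": spec_human},
        config=cfg,
        baselines=baselines,
    )


def generate_treatment_arm(
    study: SyntheticStudy,
    efficacy: float,
    n_treated: int = 5,
    n_control: int = 4,
    seed: int = 1,
) -> ExpressionDataset:
    """Treated diseased-type samples of the model species plus fresh controls.

    ``efficacy`` in [0, 1] scales the planted disease shift by
    ``(1 - efficacy)``: 0 leaves treated samples distributionally identical
    to diseased samples, 1 makes them identical to healthy ones.
    """
    if not 0.0 <= efficacy <= 1.0:
        raise ValueError("efficacy must lie in [0, 1]")
    cfg = study.config
    rng = np.random.default_rng([cfg.seed, seed, 7])
    gene_ids = study.mouse.gene_ids
    base = study.baselines["mouse"].reindex(gene_ids).to_numpy()
    sets = study.mouse_sets.sets
    dys = {pw: (1.0 - efficacy) * cfg.shared_delta for pw in study.shared_pathways}
    dys.update(
        {pw: (1.0 - efficacy) * cfg.specific_delta for pw in study.specific_pathways["mouse"]}
    )
    values, phenotype, treated = _simulate_matrix(
        rng, gene_ids, base, sets, dys, n_control, n_treated, cfg,
        sample_prefix="mm_trt", treated_flag=True,
    )
    return ExpressionDataset(
        values=values, species=study.mouse.species, phenotype=phenotype, treated=treated
    )
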