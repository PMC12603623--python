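"""Per-sample preranked pathway enrichment (weighted KS running sum, NES).

Every sample is converted to a ranked gene list by its log2 fold change
against the mean of the healthy (control) group of the same dataset.  For
each pathway, the classic weighted Kolmogorov-Smirnov running-sum enrichment
score (ES) is computed on that list, then normalized against a gene-sampling
null: NES = ES / mean |ES| of same-sign random gene sets of the same size.
The result is a pathways x samples NES matrix, the workflow's working
currency.

Notes on conventions (all configurable through :class:`EnrichmentParams`):

* the ranking metric is ``log2((x + eps) / (control_mean + eps))`` with a
  small pseudo-count ``eps``; control samples are ranked against a control
  mean that includes themselves;
* the hit weight exponent ``p`` defaults to 1 (each hit contributes
  ``|r|^p`` to the running sum);
* the null draws ``n_permutations`` uniform position sets per pathway from
  the ranked universe; the draws depend only on the seed and the pathway,
  never on the sample, so permuting samples permutes NES columns identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentParams",
    "RankedGeneList",
    "EnrichmentMatrix",
    "UndefinedEnrichmentError",
    "fold_change_ranking",
    "enrichment_score",
    "normalized_es",
    "build_enrichment_matrix",
]


class UndefinedEnrichmentError(ValueError):
    """ES undefined: no pathway member in the list, or every gene a member."""


#: magnitude ties between the positive and negative running-sum extrema are
#: resolved to the negative side when closer than this
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class EnrichmentParams:
    """Tunable parameters of the enrichment stage.

    weight_exponent
        GSEA hit-weight exponent p >= 0 (default 1).
    n_permutations
        Random gene sets per pathway for NES normalization (>=100 for NES use).
    seed
        Root seed of the permutation null.
    epsilon
        Pseudo-count guarding the fold-change ratio against zeros.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    seed: int = 0
    epsilon: float = 1e-8
    leave_self_out: bool = False

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def to_dict(self) -> dict:
        return {
            "weight_exponent": self.weight_exponent,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "epsilon": self.epsilon,
            "leave_self_out": self.leave_self_out,
        }


@dataclass
class RankedGeneList:
    """Genes sorted by ranking metric, descending; ties broken by gene id."""

    genes: np.ndarray
    metrics: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metrics = np.asarray(self.metrics, dtype=float)
        if len(self.genes) != len(self.metrics):
            raise ValueError("genes and metrics length mismatch")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)

    def positions_of(self, members) -> np.ndarray:
        """0-based positions of the member genes present in the list."""
        members = set(members)
        return np.flatnonzero([g in members for g in self.genes])


@dataclass
class EnrichmentMatrix:
    """Pathways x samples NES matrix with provenance."""

    nes: pd.DataFrame
    species: str
    phenotype: pd.Series
    params: EnrichmentParams
    dropped: list[str] = field(default_factory=list)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.nes.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.nes.columns)


def fold_change_ranking(
    ds: ExpressionDataset, sample_id: str, params: EnrichmentParams | None = None
) -> RankedGeneList:
    """Rank one sample's genes by log2 fold change against the control mean.

    The control mean is the per-gene mean over all healthy samples of the
    dataset; a healthy sample is compared against a mean that includes itself.
    """
    params = params or EnrichmentParams()
    healthy = ds.healthy_samples()
    if not healthy:
        raise ValueError(f"dataset {ds.species!r} has no healthy samples")
    if sample_id not in ds.values.columns:
        raise KeyError(f"sample {sample_id!r} not in dataset")
    if params.leave_self_out and sample_id in healthy and len(healthy) > 1:
        healthy = [s for s in healthy if s != sample_id]
    x = ds.values[sample_id].to_numpy(dtype=float)
    ctrl = ds.values[healthy].to_numpy(dtype=float).mean(axis=1)
    metrics = np.log2((x + params.epsilon) / (ctrl + params.epsilon))
    genes = np.asarray(ds.gene_ids, dtype=object)
    # primary key: metric descending; secondary: gene id ascending
    order = np.lexsort((genes, -metrics))
    return RankedGeneList(genes=genes[order], metrics=metrics[order])


def _es_from_positions(weights: np.ndarray, pos_sets: np.ndarray) -> np.ndarray:
    """Enrichment scores for many hit-position sets on one ranked list.

    ``weights`` is ``|r|^p`` in ranked order (length N); ``pos_sets`` is an
    (M, N_h) array of 0-based hit positions.  Walking the list, a hit adds
    ``w/N_R`` to P_hit and a miss adds ``1/(N-N_h)`` to P_miss; the ES is the
    running deviation P_hit - P_miss of maximal absolute value (signed; an
    exact tie in magnitude resolves to the negative extremum).  The extrema
    can only occur immediately before or after a hit, which is what is
    evaluated here.  When every hit weight is zero the hit increments fall
    back to the unweighted 1/N_h.
    """
    n = len(weights)
    pos = np.sort(np.atleast_2d(pos_sets), axis=1)
    m, n_h = pos.shape
    if n_h == 0 or n_h >= n:
        raise UndefinedEnrichmentError(
            "ES undefined: pathway covers none or all of the ranked universe"
        )
    w = weights[pos]
    n_r = w.sum(axis=1, keepdims=True)
    j = np.arange(1, n_h + 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hit_after = np.where(n_r > 0, np.cumsum(w, axis=1) / n_r, j / n_h)
    miss_den = n - n_h
    dev_after = p_hit_after - (pos + 1 - j) / miss_den
    hit_step = np.where(n_r > 0, w / np.where(n_r > 0, n_r, 1.0), 1.0 / n_h)
    dev_before = (p_hit_after - hit_step) - (pos - (j - 1)) / miss_den
    dev = np.concatenate([dev_after, dev_before], axis=1)
    hi = dev.max(axis=1)
    lo = dev.min(axis=1)
    # signed extremum; a magnitude tie (within rounding) resolves negative so
    # structurally symmetric cases (e.g. deviations of exactly +-1/2) do not
    # flip sign on floating-point noise
    return np.where(hi + lo > _TIE_TOL, hi, lo)


def enrichment_score(ranked: RankedGeneList, members, p: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score of one gene set, in [-1, 1]."""
    pos = ranked.positions_of(members)
    if len(pos) == 0:
        raise UndefinedEnrichmentError("no pathway member present in the ranked list")
    weights = np.abs(ranked.metrics) ** p
    return float(_es_from_positions(weights, pos[None, :])[0])


def _null_position_sets(
    rng: np.random.Generator, n_genes: int, n_hits: int, n_permutations: int
) -> np.ndarray:
    """Uniform size-``n_hits`` position subsets of ``range(n_genes)``.

    Rejection-resamples rows with repeated positions; cheap because
    n_hits << n_genes in practice.
    """
    pos = rng.integers(0, n_genes, size=(n_permutations, n_hits))
    while True:
        s = np.sort(pos, axis=1)
        bad = np.flatnonzero((s[:, 1:] == s[:, :-1]).any(axis=1)) if n_hits > 1 else []
        if len(bad) == 0:
            return pos
        pos[bad] = rng.integers(0, n_genes, size=(len(bad), n_hits))


def normalized_es(
    ranked: RankedGeneList,
    members,
    params: EnrichmentParams | None = None,
    rng: np.random.Generator | None = None,
    null_positions: np.ndarray | None = None,
) -> float:
    """ES normalized by the mean |ES| of same-sign random sets of equal size.

    ``NES = ES / mean(|ES_pi| : sign(ES_pi) = sign(ES))`` over
    ``n_permutations`` random position sets; NES keeps the sign of ES and is
    0 when ES is 0.  If no permutation ES shares the sign, the denominator
    falls back to the mean |ES| over all permutations (logged).
    """
    params = params or EnrichmentParams()
    es = enrichment_score(ranked, members, params.weight_exponent)
    weights = np.abs(ranked.metrics) ** params.weight_exponent
    if null_positions is None:
        if rng is None:
            rng = np.random.default_rng([params.seed])
        n_hits = len(ranked.positions_of(members))
        null_positions = _null_position_sets(rng, len(ranked), n_hits, params.n_permutations)
    return _normalize_es(es, weights, null_positions)


def _normalize_es(es: float, weights: np.ndarray, null_positions: np.ndarray) -> float:
    if es == 0.0:
        return 0.0
    es_null = _es_from_positions(weights, null_positions)
    same_sign = es_null * np.sign(es) > 0
    if same_sign.any():
        denom = float(np.abs(es_null[same_sign]).mean())
    else:
        denom = float(np.abs(es_null).mean())
        logger.warning("NES fallback: no same-sign permutation ES; using all-permutation mean")
    if denom == 0.0:
        return 0.0
    return es / denom


def build_enrichment_matrix(
    ds: ExpressionDataset, sets: GeneSetCollection, params: EnrichmentParams | None = None
) -> EnrichmentMatrix:
    """NES for every (pathway, sample) of a dataset.

    Pathways whose ES is undefined for any sample (no member gene in the
    dataset, or the set covers the whole universe) are dropped from the whole
    matrix and logged, so the output has no missing values.  Pathway rows are
    in the canonical (input) order; null draws are seeded per pathway from
    ``params.seed`` independent of sample order.
    """
    params = params or EnrichmentParams()
    ds.validate()
    n_genes = ds.n_genes
    genes = np.asarray(ds.gene_ids, dtype=object)
    gene_row = {g: i for i, g in enumerate(genes)}

    # per sample: ranked |metric|^p weights plus the row -> rank-position map
    weights: dict[str, np.ndarray] = {}
    rank_position: dict[str, np.ndarray] = {}
    for s in ds.sample_ids:
        ranked = fold_change_ranking(ds, s, params)
        weights[s] = np.abs(ranked.metrics) ** params.weight_exponent
        order = np.array([gene_row[g] for g in ranked.genes])
        inv = np.empty(n_genes, dtype=int)
        inv[order] = np.arange(n_genes)
        rank_position[s] = inv

    rows: dict[str, list[float]] = {}
    dropped: list[str] = []
    for path_idx, name in enumerate(sets.pathway_names):
        member_rows = np.array([gene_row[g] for g in sets[name] if g in gene_row], dtype=int)
        if member_rows.size == 0 or member_rows.size >= n_genes:
            dropped.append(name)
            logger.info("dropping pathway %s: ES undefined in dataset %s", name, ds.species)
            continue
        rng = np.random.default_rng([params.seed, path_idx])
        null_pos = _null_position_sets(rng, n_genes, member_rows.size, params.n_permutations)
        row = []
        for s in ds.sample_ids:
            w = weights[s]
            es = float(_es_from_positions(w, rank_position[s][member_rows][None, :])[0])
            row.append(_normalize_es(es, w, null_pos))
        rows[name] = row
    if not rows:
        raise ValueError("all pathways dropped; no enrichment matrix")
    nes = pd.DataFrame.from_dict(rows, orient="index", columns=ds.sample_ids)
    return EnrichmentMatrix(
        nes=nes, species=ds.species, phenotype=ds.phenotype.copy(), params=params,
        dropped=dropped,
    )
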