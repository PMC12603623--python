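"""Expression tables, sample metadata and GMT gene-set collections.

The workflow consumes already-normalized gene-level intensity matrices
(genes x samples) with a per-sample phenotype label (0 healthy, 1 diseased)
and an optional treated flag, plus pathway gene sets in GMT format.  Gene-set
collections for the two species share pathway *names* while their gene
universes may be completely disjoint - the workflow never maps homologs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "read_expression_table",
    "write_expression_table",
    "collapse_duplicates",
    "read_gmt",
    "write_gmt",
    "harmonize_gene_sets",
]


@dataclass
class ExpressionDataset:
    """A genes x samples intensity matrix with per-sample labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative intensity matrix, index = gene ids, columns = sample ids.
    species : str
        Free-form species / dataset tag (e.g. ``"mouse"``).
    phenotype : pandas.Series
        Per-sample label, 0 = healthy, 1 = diseased; index = sample ids.
    treated : pandas.Series
        Per-sample treatment flag; defaults to all-False.
    """

    values: pd.DataFrame
    species: str
    phenotype: pd.Series
    treated: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.treated is None:
            self.treated = pd.Series(False, index=self.values.columns)
        self.phenotype = self.phenotype.reindex(self.values.columns)
        self.treated = self.treated.reindex(self.values.columns).fillna(False).astype(bool)
        if self.phenotype.isna().any():
            missing = list(self.phenotype.index[self.phenotype.isna()])
            raise ValueError(f"samples missing from metadata: {missing}")
        self.phenotype = self.phenotype.astype(int)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def healthy_samples(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == 0])

    def diseased_samples(self) -> list[str]:
        return list(self.phenotype.index[self.phenotype == 1])

    def validate(self, require_groups: bool = False) -> None:
        """Check the dataset invariants; raise ``ValueError`` on violation.

        ``require_groups=True`` additionally enforces the workflow-entry
        condition of >=2 samples per phenotype.
        """
        if self.values.columns.duplicated().any():
            dups = list(self.values.columns[self.values.columns.duplicated()])
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.index.duplicated().any():
            dups = sorted(set(self.values.index[self.values.index.duplicated()]))
            raise ValueError(f"duplicate gene ids (collapse first): {dups}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("non-finite expression values")
        if (arr < 0).any():
            raise ValueError("negative expression values")
        if not self.phenotype.isin([0, 1]).all():
            raise ValueError("phenotype labels must be 0 or 1")
        if require_groups:
            counts = self.phenotype.value_counts()
            for label in (0, 1):
                if counts.get(label, 0) < 2:
                    raise ValueError(
                        f"need >=2 samples with phenotype {label}, got {counts.get(label, 0)}"
                    )


@dataclass
class GeneSetCollection:
    """Named pathway gene sets for one species."""

    sets: dict[str, frozenset[str]]
    species: str = ""

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def subset(self, names: list[str]) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names}, species=self.species)


def read_expression_table(
    path, metadata_path, species: str = "", sep: str | None = None
) -> ExpressionDataset:
    """Read an expression table plus its sample-metadata sidecar.

    The table has a header row of sample ids and a first column of gene ids
    (column name ``gene_id``).  Metadata is a table with columns
    ``sample_id``, ``phenotype`` and optionally ``treated``.  Duplicate gene
    ids are permitted here; :func:`collapse_duplicates` resolves them.
    """
    sep = sep if sep is not None else _sniff_sep(path)
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)][1:]
    dups = sorted({c for c in header if header.count(c) > 1})
    if dups:
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    table = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    table.index = table.index.astype(str).str.strip()
    table.index.name = None
    table.columns = table.columns.astype(str).str.strip()
    try:
        table = table.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression cell in {path}: {exc}") from exc

    meta = pd.read_csv(metadata_path, sep=_sniff_sep(metadata_path))
    meta.columns = [c.strip() for c in meta.columns]
    meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
    meta = meta.set_index("sample_id")
    missing = [s for s in table.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata {metadata_path}: {missing}")
    phenotype = meta["phenotype"].astype(int)
    treated = (
        meta["treated"].astype(int).astype(bool)
        if "treated" in meta.columns
        else pd.Series(False, index=meta.index)
    )
    return ExpressionDataset(
        values=table,
        species=species,
        phenotype=phenotype.reindex(table.columns),
        treated=treated.reindex(table.columns),
    )


def write_expression_table(ds: ExpressionDataset, path, metadata_path) -> None:
    """Write the dataset and its metadata sidecar as TSV (lossless round-trip)."""
    out = ds.values.copy()
    out.index.name = "gene_id"
    # %.17g keeps every float64 bit-exact through the text round-trip
    out.to_csv(path, sep="\t", float_format="%.17g")
    meta = pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "phenotype": ds.phenotype.to_numpy(),
            "treated": ds.treated.astype(int).to_numpy(),
        }
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def collapse_duplicates(ds: ExpressionDataset) -> ExpressionDataset:
    """Resolve duplicated gene ids, keeping the repeat with the greatest value.

    "Greatest value" is taken as the greatest mean intensity across samples -
    one deterministic summary that agrees with any per-sample reading when the
    competing rows do not cross.  Row order is otherwise preserved.  Idempotent.
    """
    index = ds.values.index
    if not index.duplicated().any():
        return ds
    means = ds.values.to_numpy().mean(axis=1)
    keep = np.ones(len(index), dtype=bool)
    for gene in index[index.duplicated()].unique():
        pos = np.flatnonzero(index == gene)
        best = pos[np.argmax(means[pos])]
        for p in pos:
            keep[p] = p == best
        logger.info(
            "collapse_duplicates: gene %s had %d repeats, kept row with mean %.6g",
            gene, len(pos), means[best],
        )
    return replace(ds, values=ds.values.iloc[keep])


def read_gmt(path, species: str = "") -> GeneSetCollection:
    """Parse a GMT file: per line a set name, a description, then member genes."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0].strip()
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets, species=species)


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def harmonize_gene_sets(
    a: GeneSetCollection,
    b: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 1000,
) -> tuple[GeneSetCollection, GeneSetCollection]:
    """Restrict both collections to shared pathway names within the size band.

    A pathway is kept when its member count is strictly greater than
    ``min_size`` and strictly less than ``max_size`` in *both* collections and
    the name occurs in both.  Outputs carry the same lexicographic pathway
    order - the canonical order every downstream matrix uses.
    """
    if min_size >= max_size:
        raise ValueError("min_size must be < max_size")

    def ok(c: GeneSetCollection, name: str) -> bool:
        return name in c.sets and min_size < len(c.sets[name]) < max_size

    names = sorted(n for n in a.sets if ok(a, n) and ok(b, n))
    if not names:
        raise ValueError("no shared pathways within the size bounds")
    return a.subset(names), b.subset(names)
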