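"""Reading, writing and harmonizing expression datasets and gene sets.

Expression matrices are plain TSV: first column header ``gene``, remaining
headers sample ids, one gene symbol per row.  Sample metadata is a TSV with a
``sample`` column, a ``group`` column, an optional ``batch`` column, and any
further numeric columns treated as clinical covariates (AST, ALB, INR, ...).
Gene sets use the standard GMT format.

Gene identifiers are HGNC-style symbols matched case-insensitively (upper-cased
on load); no alias resolution is attempted.  Duplicate symbol rows are
collapsed to the row with the highest mean value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTENSITY = "intensity"
COUNTS = "counts"

_RESERVED_META_COLS = {"sample", "group", "batch"}


@dataclass
class ExpressionDataset:
    """One study's gene × sample expression matrix plus sample annotations.

    Parameters
    ----------
    dataset_id : str
        Label for the study (e.g. a GEO-style accession or a fixture name).
    platform : {"intensity", "counts"}
        Microarray-like continuous intensities or RNA-seq integer counts.
    values : pandas.DataFrame
        Genes in rows (index = upper-case symbols), samples in columns.
        Intensity matrices may contain NaN: a gene with missing values in a
        dataset is treated as *unmeasured* there, never imputed.  Count
        matrices must be non-negative integers with no missing values.
    groups : pandas.Series
        Sample → group label; exactly two levels per contrast
        (treated/control or disease/healthy).
    batch : pandas.Series, optional
        Sample → batch label.
    covariates : pandas.DataFrame, optional
        Sample × covariate numeric table (NaN allowed).
    log_scale : bool
        Whether ``values`` are on a log2 scale (set by the transform steps).
    """

    dataset_id: str
    platform: str
    values: pd.DataFrame
    groups: pd.Series
    batch: pd.Series | None = None
    covariates: pd.DataFrame | None = None
    log_scale: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.platform not in (INTENSITY, COUNTS):
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols after collapse: {dups}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        self.groups = self.groups.loc[self.values.columns]
        levels = self.groups.unique()
        if len(levels) > 2:
            raise ValueError(f"more than two group levels: {sorted(levels)}")
        arr = self.values.to_numpy()
        if self.platform == COUNTS:
            if np.isnan(arr).any():
                raise ValueError("counts matrix contains missing values")
            if (arr < 0).any():
                raise ValueError("counts matrix contains negative values")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts platform requires integer values")
        else:
            finite_or_nan = np.isfinite(arr) | np.isnan(arr)
            if not finite_or_nan.all():
                raise ValueError("intensity matrix contains non-finite values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def measured_mask(self) -> pd.Series:
        """Boolean per gene: True when the gene has no missing values."""
        return ~self.values.isna().any(axis=1)

    def group_samples(self, level: str) -> list[str]:
        return list(self.groups.index[self.groups == level])

    def with_values(self, values: pd.DataFrame, **kw) -> "ExpressionDataset":
        return replace(self, values=values, **kw)


@dataclass
class GeneSetCollection:
    """Named gene sets (stress-response modules, pathways) from GMT files."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def genes(self, name: str) -> list[str]:
        return self.sets[name][1]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.sets.values():
            out.update(genes)
        return out


def read_matrix(path, platform: str, metadata_path) -> ExpressionDataset:
    """Load a TSV expression matrix plus its sample metadata.

    Duplicate gene-symbol rows are collapsed to the row with the highest mean
    value; symbols are upper-cased.  Every sample in the matrix must appear in
    the metadata, which supplies group, optional batch, and covariates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad)[0]]
            raise ValueError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced
    df.index = df.index.astype(str).str.upper()
    if df.index.has_duplicates:
        df = _collapse_duplicates(df)

    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str})
    if "sample" not in meta.columns or "group" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata requires 'sample' and 'group' columns")
    meta = meta.set_index("sample")
    missing = [s for s in df.columns if s not in meta.index]
    if missing:
        raise ValueError(f"{metadata_path}: samples missing from metadata: {missing}")
    meta = meta.loc[df.columns]

    batch = meta["batch"].astype(str) if "batch" in meta.columns else None
    cov_cols = [c for c in meta.columns if c not in _RESERVED_META_COLS]
    covariates = meta[cov_cols].apply(pd.to_numeric, errors="coerce") if cov_cols else None

    if platform == COUNTS and df.isna().any().any():
        raise ValueError(f"{path}: counts matrix contains missing values")

    dataset_id = str(path)
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform=platform,
        values=df,
        groups=meta["group"].astype(str),
        batch=batch,
        covariates=covariates,
    )


def _collapse_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated symbol, the row with the highest mean value."""
    means = df.mean(axis=1, skipna=True).to_numpy()
    order = np.argsort(-means, kind="stable")
    keep_pos = (
        pd.Series(order, index=df.index[order]).groupby(level=0, sort=False).first()
    )
    kept = df.iloc[np.sort(keep_pos.to_numpy())]
    return kept


def write_matrix(dataset: ExpressionDataset, path, metadata_path=None) -> None:
    """Write the expression matrix (and optionally metadata) back to TSV."""
    out = dataset.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")
    if metadata_path is not None:
        meta = pd.DataFrame({"sample": dataset.samples, "group": dataset.groups.values})
        if dataset.batch is not None:
            meta["batch"] = dataset.batch.loc[dataset.samples].values
        if dataset.covariates is not None:
            for c in dataset.covariates.columns:
                meta[c] = dataset.covariates.loc[dataset.samples, c].values
        meta.to_csv(metadata_path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene set file: name TAB description TAB gene1 TAB gene2 ..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            name, desc = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip().upper()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = (desc, genes)
    if n_lines == 0:
        warnings.warn(f"{path}: empty GMT file, returning empty collection")
        logger.warning("%s: empty GMT file", path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in collection.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def harmonize_genes(
    datasets: list[ExpressionDataset],
) -> tuple[list[ExpressionDataset], list[str], dict[str, list[str]]]:
    """Union gene symbols across datasets and record where each is measured.

    A gene counts as measured in a dataset when it is present in the matrix
    with no missing values.  Datasets are returned unchanged — they are never
    subset to the intersection, and unmeasured genes are never imputed;
    missingness is carried through to the consensus vote as reduced
    opportunity to be called.
    """
    if not datasets:
        raise ValueError("harmonize_genes requires at least one dataset")
    measured_in: dict[str, list[str]] = {}
    union: list[str] = []
    seen: set[str] = set()
    for ds in datasets:
        mask = ds.measured_mask()
        for gene in ds.genes:
            if gene not in seen:
                seen.add(gene)
                union.append(gene)
                measured_in[gene] = []
            if mask[gene]:
                measured_in[gene].append(ds.dataset_id)
    return datasets, union, measured_in
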