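"""Readers and writers for the pipeline's external formats.

All tabular inputs are tab-separated UTF-8; gene sets use the GMT dialect
(name, description, then member genes); signatures are small JSON files.
Gene symbols are uppercased on load throughout, since case inconsistencies
between expression files and curated gene lists are common.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .pairs import IRGPSignature

__all__ = [
    "GeneSetCollection",
    "load_expression",
    "write_expression",
    "load_clinical",
    "load_gmt",
    "write_gmt",
    "load_immune_gene_list",
    "load_signature",
    "save_signature",
    "check_sample_alignment",
    "packaged_immune_gene_list",
    "packaged_immune_cell_sets",
]


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            self.sets[name] = [str(g).upper() for g in genes]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def keys(self):
        return self.sets.keys()


def load_expression(path, collapse: str = "highest-mean") -> pd.DataFrame:
    """Load a genes x samples expression matrix from TSV.

    First column holds gene symbols (uppercased), the header row sample IDs,
    and the body numeric non-negative values.  Duplicate gene symbols are
    collapsed by keeping the row with the highest mean expression across
    samples.

    Raises
    ------
    FormatError
        Non-numeric cell (named by gene row and sample column), empty
        matrix, duplicate sample IDs, or negative values.
    """
    if collapse not in ("highest-mean",):
        raise ValidationError(f"unknown duplicate-collapse policy {collapse!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample IDs: {', '.join(map(str, dup))}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at gene "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    numeric.index = df.index.astype(str).str.upper()
    numeric.index.name = "gene"
    if (numeric.to_numpy() < 0).any():
        raise FormatError(f"{path}: expression values must be non-negative")
    if numeric.index.duplicated().any():
        order = numeric.mean(axis=1).to_numpy()
        numeric = (
            numeric.assign(_mean=order)
            .sort_values("_mean", ascending=False, kind="stable")
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
        )
        numeric = numeric.loc[sorted(numeric.index)]
    return numeric


def write_expression(expr: pd.DataFrame, path) -> None:
    """Write an expression matrix as TSV (round-trips with load_expression)."""
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


_CLINICAL_REQUIRED = ("time", "event")


def load_clinical(path) -> pd.DataFrame:
    """Load a clinical table: sample, time (days), event, covariates.

    Requires columns ``sample``, ``time`` (> 0) and ``event`` (0/1); keeps
    any further columns (age, gender, radiotherapy, chemotherapy, and
    annotation columns such as IDH or MGMT status) as-is.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "sample" not in cols:
        raise FormatError(f"{path}: clinical table needs a 'sample' column")
    df = df.rename(columns={v: k for k, v in cols.items()})
    missing = [c for c in _CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical columns: {', '.join(missing)}")
    df = df.set_index("sample")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample IDs in clinical table")
    df["time"] = pd.to_numeric(df["time"], errors="raise")
    df["event"] = pd.to_numeric(df["event"], errors="raise")
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0].tolist()
        raise ValidationError(f"non-positive survival time for: {', '.join(map(str, bad))}")
    if not df["event"].isin([0, 1]).all():
        raise ValidationError("event indicator must be 0 or 1")
    return df


def check_sample_alignment(expr: pd.DataFrame, clinical: pd.DataFrame) -> list[str]:
    """Samples usable for analysis (clinical rows present in the expression
    matrix); raises when none overlap."""
    common = [s for s in expr.columns if s in clinical.index]
    if not common:
        raise ValidationError("no sample shared between expression and clinical table")
    return common


def load_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, name TAB description TAB genes...

    Raises
    ------
    FormatError
        A line with fewer than three fields (reported with its line number)
        or a duplicate set name.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def load_immune_gene_list(path) -> pd.Series:
    """Two-column TSV (gene, category) -> Series mapping symbol to category."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: immune gene list needs gene and category columns")
    genes = df.iloc[:, 0].astype(str).str.upper()
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate gene symbols: {', '.join(dup)}")
    out = pd.Series(df.iloc[:, 1].to_numpy(), index=genes, name="category")
    if out.empty:
        raise FormatError(f"{path}: immune gene list is empty")
    return out


def load_signature(path) -> IRGPSignature:
    with open(path, encoding="utf-8") as fh:
        return IRGPSignature.from_dict(json.load(fh))


def save_signature(sig: IRGPSignature, path) -> None:
    Path(path).write_text(json.dumps(sig.to_dict(), indent=2) + "\n", encoding="utf-8")


def packaged_immune_gene_list() -> pd.Series:
    """The immune gene -> category list shipped with the package.

    A synthetic stand-in for a curated immune-gene database: category names
    follow the usual immune-function classifications and the nine signature
    genes carry their published categories, but the remaining membership is
    illustrative, not curated.
    """
    with resources.as_file(
        resources.files("irgpi").joinpath("data/immune_gene_categories.synthetic.tsv")
    ) as p:
        return load_immune_gene_list(p)


def packaged_immune_cell_sets() -> GeneSetCollection:
    """30 immune cell-type marker sets (16 populations) shipped with the package.

    A synthetic stand-in preserving the structure of published immune
    deconvolution panels (30 cell types from 16 parent populations, a few
    canonical markers each); the gene memberships are illustrative.
    """
    with resources.as_file(
        resources.files("irgpi").joinpath("data/immune_cell_sets.synthetic.gmt")
    ) as p:
        return load_gmt(p)
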