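"""Readers and writers for expression atlases, gene-set collections and result tables.

Two atlas dialects are supported:

* ``generic-tsv`` — a directory with ``expression.tsv`` (first column
  ``probe_id``, remaining columns sample ids), ``probes.tsv``
  (``probe_id``, ``gene_symbol``) and ``samples.tsv`` (``sample_id``,
  ``donor_id``, ``region_name``).
* ``allen-csv-triplet`` — the Allen Human Brain Atlas per-donor layout:
  ``MicroarrayExpression.csv`` (probe id in column 1, no header, sample
  columns in ``SampleAnnot.csv`` row order), ``SampleAnnot.csv`` and
  ``Probes.csv``.

Gene sets travel in GMT (tab-separated, one set per line: name,
description, members). Result tables are TSV with a header, UTF-8, and
``NA`` for missing values.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionBundle",
    "GeneSetCollection",
    "AtlasLoadError",
    "AtlasStructureError",
    "GmtParseError",
    "read_expression_bundle",
    "write_expression_bundle",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "write_table",
    "read_table",
]


class AtlasLoadError(IOError):
    """A required atlas file is missing or unreadable."""


class AtlasStructureError(ValueError):
    """The atlas files are present but structurally inconsistent."""


class GmtParseError(ValueError):
    """A GMT line does not follow the name/description/members layout."""


@dataclass
class ExpressionBundle:
    """A probes x samples log2 expression matrix with its annotations.

    Attributes
    ----------
    matrix : pandas.DataFrame
        Probes (rows) by samples (columns), log2 intensity.
    probe_annot : pandas.Series
        Maps probe id -> gene symbol; indexed identically to ``matrix``.
    sample_annot : pandas.DataFrame
        Indexed by sample id with columns ``donor_id`` and ``region_name``;
        index matches ``matrix`` columns.
    """

    matrix: pd.DataFrame
    probe_annot: pd.Series
    sample_annot: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        # normalize index names so round-trips compare equal
        self.matrix.index.name = "probe_id"
        self.matrix.columns.name = None
        self.probe_annot.index.name = "probe_id"
        self.sample_annot.index.name = "sample_id"
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise AtlasStructureError(f"duplicate probe ids: {list(dupes[:5])}")
        if self.matrix.columns.has_duplicates:
            dupes = self.matrix.columns[self.matrix.columns.duplicated()].unique()
            raise AtlasStructureError(f"duplicate sample ids: {list(dupes[:5])}")
        if not self.matrix.index.equals(self.probe_annot.index):
            raise AtlasStructureError("matrix rows do not match probe annotation")
        if not self.matrix.columns.equals(self.sample_annot.index):
            raise AtlasStructureError("matrix columns do not match sample annotation")
        if self.probe_annot.isna().any() or (self.probe_annot.astype(str).str.strip() == "").any():
            raise AtlasStructureError("probe annotation contains empty gene symbols")
        for col in ("donor_id", "region_name"):
            if col not in self.sample_annot.columns:
                raise AtlasStructureError(f"sample annotation lacks column {col!r}")
            vals = self.sample_annot[col]
            if vals.isna().any() or (vals.astype(str).str.strip() == "").any():
                raise AtlasStructureError(f"sample annotation has empty {col}")
        if self.matrix.isna().any().any():
            raise AtlasStructureError("expression matrix contains missing values")

    # -- convenience accessors used throughout the pipeline --------------

    @property
    def n_probes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def regions(self) -> list[str]:
        return sorted(self.sample_annot["region_name"].unique())

    @property
    def donors(self) -> list[str]:
        return sorted(self.sample_annot["donor_id"].unique())

    @property
    def genes(self) -> list[str]:
        return sorted(self.probe_annot.unique())

    def subset_donor(self, donor_id: str) -> "ExpressionBundle":
        keep = self.sample_annot.index[self.sample_annot["donor_id"] == donor_id]
        if len(keep) == 0:
            raise KeyError(f"donor {donor_id!r} has no samples")
        return ExpressionBundle(
            matrix=self.matrix.loc[:, keep],
            probe_annot=self.probe_annot.copy(),
            sample_annot=self.sample_annot.loc[keep].copy(),
        )

    def equals(self, other: "ExpressionBundle") -> bool:
        return (
            self.matrix.equals(other.matrix)
            and self.probe_annot.equals(other.probe_annot)
            and self.sample_annot.equals(other.sample_annot)
        )


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance label per set."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = frozenset(members)
        for name in self.sets:
            self.provenance.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def _strip(symbol: str) -> str:
    return str(symbol).strip()


def read_expression_bundle(path: str | os.PathLike, dialect: str = "generic-tsv") -> ExpressionBundle:
    """Load an :class:`ExpressionBundle` from disk.

    Probes whose gene symbol is blank — or, in the Allen dialect, maps to
    more than one symbol — are dropped; the number dropped is logged.
    """
    path = Path(path)
    if not path.exists():
        raise AtlasLoadError(f"no such path: {path}")
    if dialect == "generic-tsv":
        return _read_generic(path)
    if dialect == "allen-csv-triplet":
        return _read_allen(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _require(path: Path) -> Path:
    if not path.exists():
        raise AtlasLoadError(f"missing file: {path}")
    return path


def _finish_bundle(matrix: pd.DataFrame, probe_annot: pd.Series, sample_annot: pd.DataFrame) -> ExpressionBundle:
    symbols = probe_annot.astype(str).map(_strip)
    # a multi-symbol annotation field is not a unique gene assignment
    bad = symbols.isin(("", "nan")) | symbols.str.contains(r"[;|]")
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.info("dropped %d probes without a unique gene symbol", n_dropped)
    keep = symbols.index[~bad]
    return ExpressionBundle(
        matrix=matrix.loc[keep],
        probe_annot=symbols.loc[keep].rename("gene_symbol"),
        sample_annot=sample_annot,
    )


def _read_generic(directory: Path) -> ExpressionBundle:
    if not directory.is_dir():
        raise AtlasLoadError(f"generic-tsv dialect expects a directory: {directory}")
    expr = pd.read_csv(_require(directory / "expression.tsv"), sep="\t", index_col=0)
    expr.index = expr.index.astype(str)
    expr = expr.astype(float)
    probes = pd.read_csv(_require(directory / "probes.tsv"), sep="\t", dtype=str)
    samples = pd.read_csv(_require(directory / "samples.tsv"), sep="\t", dtype=str)
    for col in ("probe_id", "gene_symbol"):
        if col not in probes.columns:
            raise AtlasStructureError(f"probes.tsv lacks column {col!r}")
    for col in ("sample_id", "donor_id", "region_name"):
        if col not in samples.columns:
            raise AtlasStructureError(f"samples.tsv lacks column {col!r}")
    if probes["probe_id"].duplicated().any():
        raise AtlasStructureError("duplicate probe_id in probes.tsv")
    probe_annot = probes.set_index("probe_id")["gene_symbol"]
    sample_annot = samples.set_index("sample_id")[["donor_id", "region_name"]]
    if set(expr.index) != set(probe_annot.index):
        raise AtlasStructureError("expression rows do not match probes.tsv")
    if list(expr.columns) != list(sample_annot.index):
        raise AtlasStructureError(
            f"expression has {expr.shape[1]} sample columns but samples.tsv "
            f"describes {len(sample_annot)} samples (or order differs)"
        )
    probe_annot = probe_annot.loc[expr.index]
    return _finish_bundle(expr, probe_annot, sample_annot)


def _read_allen(directory: Path) -> ExpressionBundle:
    """Read one donor directory of the Allen three-file CSV layout."""
    if not directory.is_dir():
        raise AtlasLoadError(f"allen-csv-triplet dialect expects a directory: {directory}")
    expr = pd.read_csv(_require(directory / "MicroarrayExpression.csv"), header=None, index_col=0)
    expr.index = expr.index.astype(str)
    expr = expr.astype(float)
    sample_annot_raw = pd.read_csv(_require(directory / "SampleAnnot.csv"))
    probes = pd.read_csv(_require(directory / "Probes.csv"))
    if expr.shape[1] != len(sample_annot_raw):
        raise AtlasStructureError(
            f"MicroarrayExpression.csv has {expr.shape[1]} sample columns but "
            f"SampleAnnot.csv has {len(sample_annot_raw)} rows"
        )
    if "probe_id" not in probes.columns:
        probes = probes.rename(columns={probes.columns[0]: "probe_id"})
    probes["probe_id"] = probes["probe_id"].astype(str)
    if probes["probe_id"].duplicated().any():
        raise AtlasStructureError("duplicate probe_id in Probes.csv")
    symbol_col = "gene_symbol" if "gene_symbol" in probes.columns else "gene-symbol"
    if symbol_col not in probes.columns:
        raise AtlasStructureError("Probes.csv lacks a gene_symbol column")
    probe_annot = probes.set_index("probe_id")[symbol_col]
    if set(expr.index) != set(probe_annot.index):
        raise AtlasStructureError("MicroarrayExpression rows do not match Probes.csv")
    probe_annot = probe_annot.loc[expr.index]
    region_col = next(
        (c for c in ("structure_name", "region_name") if c in sample_annot_raw.columns), None
    )
    if region_col is None:
        raise AtlasStructureError("SampleAnnot.csv lacks a structure_name column")
    donor = directory.name
    sample_ids = [f"{donor}_{i}" for i in range(len(sample_annot_raw))]
    if "donor_id" in sample_annot_raw.columns:
        donors = sample_annot_raw["donor_id"].astype(str).tolist()
    else:
        donors = [donor] * len(sample_annot_raw)
    sample_annot = pd.DataFrame(
        {"donor_id": donors, "region_name": sample_annot_raw[region_col].astype(str).tolist()},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    expr.columns = sample_annot.index
    return _finish_bundle(expr, probe_annot, sample_annot)


def write_expression_bundle(bundle: ExpressionBundle, directory: str | os.PathLike) -> Path:
    """Write a bundle in the generic TSV dialect; returns the directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix = bundle.matrix.copy()
    matrix.index.name = "probe_id"
    matrix.to_csv(directory / "expression.tsv", sep="\t", float_format="%.17g")
    probes = bundle.probe_annot.rename("gene_symbol").to_frame()
    probes.index.name = "probe_id"
    probes.to_csv(directory / "probes.tsv", sep="\t")
    samples = bundle.sample_annot.copy()
    samples.index.name = "sample_id"
    samples.to_csv(directory / "samples.tsv", sep="\t")
    return directory


def read_gene_sets_gmt(path: str | os.PathLike, provenance: str | None = None) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Duplicate member symbols within a line are de-duplicated; duplicate set
    names are an error; a line with fewer than three fields is a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise AtlasLoadError(f"no such file: {path}")
    sets: dict[str, frozenset[str]] = {}
    prov: dict[str, str] = {}
    label = provenance if provenance is not None else path.stem
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, _desc, *members = fields
            name = name.strip()
            if name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            cleaned = frozenset(_strip(m) for m in members if _strip(m))
            if not cleaned:
                raise GmtParseError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = cleaned
            prov[name] = label
    if not sets:
        logger.warning("GMT file %s contained no gene sets", path)
    return GeneSetCollection(sets=sets, provenance=prov)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.provenance.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
    return path


def write_table(records: pd.DataFrame, path: str | os.PathLike) -> Path:
    """Write a result table as TSV: header, full float precision, NaN as NA."""
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    return path


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise AtlasLoadError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
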