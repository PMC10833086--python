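"""Readers and writers for the external file formats of the pipeline.

Input dialects
--------------
* Per-sample SNV call tables in the inStrain ``*_SNVs.tsv`` dialect:
  tab-separated with at least the columns ``scaffold``, ``position``,
  ``ref_base``, ``con_base`` and ``class``.  Positions are 0-based (the
  caller's convention) and kept 0-based internally.
* A scaffold-to-bin map (two tab-separated columns: scaffold, bin id),
  as produced by dRep's ``parse_stb.py``.
* Gene annotations, either GFF3 (CDS features, 1-based inclusive) or a
  tab-separated gene table.  All coordinates are converted to 0-based
  half-open at the boundary and stay that way internally.
* Sample metadata and feature (metabolite / phenotype) tables,
  tab-separated with samples in rows.

Extra columns in any input table are ignored so that real tool output
parses against this minimal schema.  Missing values are accepted as
empty fields or ``NA``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "FormatError",
    "SnvCall",
    "SiteKey",
    "SampleMeta",
    "GeneRecord",
    "FeatureTable",
    "read_snv_table",
    "read_scaffold_to_bin",
    "read_gene_table",
    "read_feature_table",
    "read_sample_metadata",
    "write_feature_table",
    "write_table",
]

log = logging.getLogger("magsnv")

BASES = "ACGT"
_BASE_SET = frozenset(BASES)

#: version string stamped into commented headers of result files
TOOL_TAG = "magsnv 0.1.0"

GROUPS = ("CON", "RMT", "RFT")


class FormatError(ValueError):
    """An input file does not conform to the expected dialect."""


@dataclass(frozen=True)
class SnvCall:
    """One consensus-base call at one site in one sample."""

    scaffold: str
    position: int  # 0-based
    ref_base: str
    con_base: str
    snv_class: str = "SNV"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise FormatError(f"negative position {self.position} on {self.scaffold}")

    @property
    def site_key(self) -> "SiteKey":
        return SiteKey(self.scaffold, self.position, self.ref_base)


@dataclass(frozen=True, order=True)
class SiteKey:
    """Scaffold + position + reference base: the unique site identifier."""

    scaffold: str
    position: int
    ref_base: str

    def __str__(self) -> str:  # serialized form used in exported tables
        return f"{self.scaffold}:{self.position}:{self.ref_base}"

    @classmethod
    def parse(cls, text: str) -> "SiteKey":
        scaffold, pos, ref = text.rsplit(":", 2)
        return cls(scaffold, int(pos), ref)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    animal_id: str
    group: str
    day: int


@dataclass
class GeneRecord:
    """A CDS interval, stored 0-based half-open."""

    gene_id: str
    scaffold: str
    start: int
    end: int
    strand: str = "+"
    cog_id: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


class FeatureTable:
    """Samples x features numeric table with per-feature kind.

    ``kinds[f]`` is ``"binary"`` when the observed values of feature ``f``
    form a subset of {0, 1} (missing allowed), else ``"continuous"``;
    binary traits are modelled with logistic regression downstream,
    continuous ones with ordinary least squares.
    """

    def __init__(self, data: pd.DataFrame, kinds: Mapping[str, str] | None = None):
        if data.index.duplicated().any():
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate sample_id {dup!r} in feature table")
        self.data = data.astype(float)
        if kinds is None:
            kinds = {f: infer_feature_kind(self.data[f]) for f in self.data.columns}
        self.kinds = dict(kinds)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, feature: str) -> pd.Series:
        return self.data[feature]

    def __len__(self) -> int:
        return self.data.shape[1]


def infer_feature_kind(values: pd.Series) -> str:
    observed = set(values.dropna().unique())
    return "binary" if observed <= {0.0, 1.0} else "continuous"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_SNV_REQUIRED = ("scaffold", "position", "ref_base", "con_base", "class")


def read_snv_table(
    path: str | Path, keep_class: str = "SNV", strict: bool = False
) -> list[SnvCall]:
    """Read one per-sample SNV table, keeping rows of class ``keep_class``.

    Rows whose ref/consensus base is not one of A, C, G, T are dropped
    with a warning (``strict=True`` raises instead).  Row order is
    preserved.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _SNV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    df = df[df["class"] == keep_class]
    calls: list[SnvCall] = []
    n_bad = 0
    for scaffold, pos, ref, con, cls in zip(
        df["scaffold"], df["position"], df["ref_base"], df["con_base"], df["class"]
    ):
        if ref not in _BASE_SET or con not in _BASE_SET:
            if strict:
                raise FormatError(
                    f"{path}: malformed base ({ref!r}/{con!r}) at {scaffold}:{pos}"
                )
            n_bad += 1
            continue
        calls.append(SnvCall(scaffold, int(pos), ref, con, cls))
    if n_bad:
        warnings.warn(f"{path}: dropped {n_bad} rows with non-ACGT bases")
    return calls


def read_scaffold_to_bin(path: str | Path) -> dict[str, str]:
    """Read a two-column scaffold -> bin map.

    Duplicate identical lines are idempotent; conflicting assignments of
    one scaffold to two bins raise :class:`FormatError`.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            scaffold, bin_id = parts[0], parts[1]
            if lineno == 1 and scaffold.lower() in ("scaffold", "contig"):
                continue  # tolerate a header line
            if scaffold in mapping and mapping[scaffold] != bin_id:
                raise FormatError(
                    f"{path}:{lineno}: scaffold {scaffold!r} assigned to both "
                    f"{mapping[scaffold]!r} and {bin_id!r}"
                )
            mapping[scaffold] = bin_id
    if not mapping:
        warnings.warn(f"{path}: empty scaffold-to-bin map")
    return mapping


_GENE_TSV_REQUIRED = ("gene_id", "scaffold", "start", "end", "strand")


def read_gene_table(path: str | Path, dialect: str = "auto") -> list[GeneRecord]:
    """Read gene annotations from GFF3 (CDS features) or a gene TSV.

    Input coordinates are 1-based inclusive and converted to 0-based
    half-open.  A record with start >= end on input is a record-level
    error reported with its line number.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if dialect == "gff3":
        return _read_genes_gff3(path)
    if dialect == "tsv":
        return _read_genes_tsv(path)
    raise ValueError(f"unknown gene dialect {dialect!r}")


def _read_genes_gff3(path: Path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        if feat.start > feat.end:
            raise FormatError(f"{path}: CDS {feat.id}: start > end")
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        cog = feat.attributes.get("cog_id", [None])[0]
        product = feat.attributes.get("product", [None])[0]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                scaffold=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                cog_id=cog,
                product=product,
            )
        )
    return records


def _read_genes_tsv(path: Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _GENE_TSV_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    has_cog = "cog_id" in df.columns
    has_product = "product" in df.columns
    records: list[GeneRecord] = []
    for i, row in enumerate(df.itertuples(index=False), 2):  # line 1 is the header
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise FormatError(f"{path}:{i}: gene {row.gene_id}: start >= end")
        cog = getattr(row, "cog_id", None) if has_cog else None
        product = getattr(row, "product", None) if has_product else None
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                scaffold=row.scaffold,
                start=start - 1,
                end=end,
                strand=row.strand,
                cog_id=None if pd.isna(cog) else cog,
                product=None if pd.isna(product) else product,
            )
        )
    return records


def read_feature_table(
    path: str | Path, kinds: Mapping[str, str] | None = None
) -> FeatureTable:
    """Read a samples x features table (first column = sample_id).

    Feature kind is inferred per column (values within {0,1} -> binary)
    unless overridden through ``kinds``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""], comment="#")
    table = FeatureTable(df)
    if kinds:
        table.kinds.update(kinds)
    return table


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata (sample_id, animal_id, group, day)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ("sample_id", "animal_id", "group", "day")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    seen: dict[tuple[str, int], str] = {}
    meta: list[SampleMeta] = []
    for row in df.itertuples(index=False):
        day = int(row.day)
        key = (row.animal_id, day)
        if key in seen:
            raise FormatError(
                f"{path}: duplicate (animal_id, day) = {key} "
                f"({seen[key]} vs {row.sample_id})"
            )
        seen[key] = row.sample_id
        meta.append(SampleMeta(row.sample_id, row.animal_id, row.group, day))
    return meta


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _header_comment(params: Mapping[str, object] | None) -> str:
    items = "" if not params else " | " + " ".join(f"{k}={v}" for k, v in params.items())
    return f"# {TOOL_TAG}{items}\n"


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    params: Mapping[str, object] | None = None,
    index: bool = False,
    float_format: str = "%.10g",
) -> None:
    """Write a result table as TSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(params))
        df.to_csv(fh, sep="\t", index=index, na_rep="NA", float_format=float_format)


def write_feature_table(
    table: FeatureTable, path: str | Path, params: Mapping[str, object] | None = None
) -> None:
    df = table.data.copy()
    df.index.name = "sample_id"
    write_table(df, path, params=params, index=True, float_format="%.17g")
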