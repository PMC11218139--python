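"""Reading, validating and writing the toolkit's tabular and tree inputs.

All downstream modules assume the canonical layout established here:
feature tables are samples-in-rows with unique string identifiers on both
axes, metadata rows are keyed by sample id, trees are rooted with
non-negative branch lengths, and every multi-table analysis first passes
through :func:`harmonize_samples` so that all inputs describe the same
samples in the same (lexicographic) order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .errors import ParseError, ValidationError

__all__ = [
    "FeatureTable",
    "SampleMetadata",
    "MappingTable",
    "FEATURE_KINDS",
    "TRANSFORM_TAGS",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "read_mapping",
    "read_newick_tree",
    "write_newick_tree",
    "harmonize_samples",
]

FEATURE_KINDS = ("taxon_cluster", "metabolite", "gene_function", "generic")
#: "log" marks a log-transformed raw table; "log_relative" a log of proportions.
TRANSFORM_TAGS = ("raw", "relative", "log", "log_relative", "pareto", "centered")


@dataclass
class FeatureTable:
    """A samples x features numeric matrix with provenance tags.

    Parameters
    ----------
    data:
        DataFrame with sample ids as the index and feature ids as columns.
        Values must be finite; raw tables must be non-negative.
    feature_kind:
        What the features are: ``taxon_cluster`` (genome bins), ``metabolite``,
        ``gene_function`` (e.g. KEGG orthologs) or ``generic``.
    transform_tag:
        Which transform has been applied (see :data:`TRANSFORM_TAGS`).
    """

    data: pd.DataFrame
    feature_kind: str = "generic"
    transform_tag: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.transform_tag not in TRANSFORM_TAGS:
            raise ValidationError(f"unknown transform_tag {self.transform_tag!r}")
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("feature table is empty")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        self.data = df = df.astype(float)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        vals = df.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("feature table contains NaN or infinite values")
        if self.transform_tag == "raw" and (vals < 0).any():
            raise ValidationError("raw feature table contains negative values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, transform_tag: str | None = None,
                  feature_kind: str | None = None) -> "FeatureTable":
        """Return a new table with replaced values, inheriting tags by default."""
        return FeatureTable(
            data,
            feature_kind=feature_kind or self.feature_kind,
            transform_tag=transform_tag or self.transform_tag,
        )


@dataclass
class SampleMetadata:
    """Per-sample covariates, each tagged categorical or continuous.

    Missing values are allowed and kept as NaN; analyses drop the affected
    samples explicitly rather than imputing.
    """

    data: pd.DataFrame
    column_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        self.data.index = self.data.index.astype(str)
        for col in self.data.columns:
            kind = self.column_types.get(col)
            if kind not in ("categorical", "continuous"):
                raise ValidationError(f"column {col!r} has no type tag")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def categorical(self, name: str) -> pd.Series:
        if self.column_types.get(name) != "categorical":
            raise ValidationError(f"{name!r} is not a categorical column")
        return self.data[name]

    def continuous(self, name: str) -> pd.Series:
        if self.column_types.get(name) != "continuous":
            raise ValidationError(f"{name!r} is not a continuous column")
        return pd.to_numeric(self.data[name])


@dataclass
class MappingTable:
    """Element-to-group pairs (contig->cluster, feature->KO, KO->pathway)."""

    pairs: pd.DataFrame  # columns: element_id, group_id
    role: str = "generic"

    ROLES = ("contig_to_cluster", "ko_to_pathway", "feature_to_ko", "generic")

    def __post_init__(self) -> None:
        if self.role not in self.ROLES:
            raise ValidationError(f"unknown mapping role {self.role!r}")
        df = self.pairs
        if list(df.columns) != ["element_id", "group_id"]:
            df = df.copy()
            df.columns = ["element_id", "group_id"]
        df = df.astype(str).drop_duplicates(ignore_index=True)
        if self.role == "contig_to_cluster":
            counts = df["element_id"].value_counts()
            multi = counts[counts > 1]
            if len(multi):
                raise ValidationError(
                    f"contigs assigned to more than one cluster: {list(multi.index)}"
                )
        self.pairs = df

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict_of_sets(self, by: str = "group") -> dict[str, set[str]]:
        """group -> set of elements (``by='group'``) or element -> set of groups."""
        if by == "group":
            key, val = "group_id", "element_id"
        else:
            key, val = "element_id", "group_id"
        out: dict[str, set[str]] = {}
        for k, v in zip(self.pairs[key], self.pairs[val]):
            out.setdefault(k, set()).add(v)
        return out


def _sniff_delimiter(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".tab"):
        return "\t"
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_feature_table(path, orientation: str = "samples_in_rows",
                       feature_kind: str = "generic") -> FeatureTable:
    """Load a delimited feature table into canonical samples-in-rows layout.

    The first row and first column are headers; the delimiter is chosen from
    the file extension (.csv / .tsv) with a fallback sniff of the header line.
    Lines starting with ``#`` are ignored, so tables written by
    :func:`write_feature_table` round-trip.
    """
    path = Path(path)
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    sep = _sniff_delimiter(path)
    # tables written by write_feature_table carry their tags in the header
    transform_tag = "raw"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# mgomics"):
        for token in first.split():
            if token.startswith("transform="):
                transform_tag = token.split("=", 1)[1]
            elif token.startswith("feature_kind="):
                feature_kind = token.split("=", 1)[1]
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"{path}: empty table")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        if coerced.isna().any():
            row = df.index[coerced.isna().to_numpy().argmax()]
            raise ParseError(f"{path}: missing value at row {row!r}, column {col!r}")
        df[col] = coerced
    if orientation == "features_in_rows":
        df = df.T
    return FeatureTable(df, feature_kind=feature_kind,
                        transform_tag=transform_tag)


def write_feature_table(table: FeatureTable, path, header_comment: str | None = None) -> None:
    """Write a table as TSV with a commented provenance header.

    Floats are written with 17 significant digits so values round-trip exactly.
    """
    from . import __version__

    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mgomics {__version__} feature_kind={table.feature_kind} "
                 f"transform={table.transform_tag}\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        table.data.to_csv(fh, sep="\t", float_format="%.17g")


def read_sample_metadata(path, type_hints: dict[str, str] | None = None) -> SampleMetadata:
    """Load sample metadata; untyped columns are auto-typed.

    A column is continuous when every non-missing cell parses as a number,
    otherwise categorical. Hints override auto-typing; a numeric column hinted
    categorical keeps the distinct string forms as its levels.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#", dtype=str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated sample ids {dups}")
    type_hints = dict(type_hints or {})
    out = pd.DataFrame(index=df.index.astype(str))
    types: dict[str, str] = {}
    for col in df.columns:
        raw = df[col]
        hint = type_hints.get(col)
        coerced = pd.to_numeric(raw, errors="coerce")
        numeric = (coerced.notna() | raw.isna()).all()
        kind = hint or ("continuous" if numeric else "categorical")
        if kind == "continuous":
            if not numeric:
                bad = raw[coerced.isna() & raw.notna()].iloc[0]
                raise ValidationError(
                    f"{path}: column {col!r} hinted continuous but holds {bad!r}")
            out[col] = coerced
        else:
            out[col] = raw  # distinct string forms are the levels; NaN = missing
        types[col] = kind
    return SampleMetadata(out, types)


def read_mapping(path, role: str = "generic", header: bool = False) -> MappingTable:
    """Load a two-column element->group mapping (TSV or CSV)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, header=0 if header else None,
                     comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns, found {df.shape[1]}")
    df.columns = ["element_id", "group_id"]
    return MappingTable(df, role=role)


def _check_parentheses(text: str, name: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ParseError(f"{name}: unbalanced ')' at character {offset}")
    if depth != 0:
        raise ParseError(f"{name}: {depth} unclosed '(' at end of input")


def read_newick_tree(path) -> TreeNode:
    """Parse a rooted newick tree; edges without lengths get 0 with a warning."""
    path = Path(path)
    text = path.read_text().strip()
    _check_parentheses(text, str(path))
    try:
        tree = TreeNode.read([text])
    except Exception as exc:  # skbio NewickFormatError
        raise ParseError(f"{path}: {exc}") from exc
    missing = [n for n in tree.traverse(include_self=False) if n.length is None]
    if missing:
        warnings.warn(f"{path}: {len(missing)} edges without branch lengths set to 0")
        for node in missing:
            node.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length < 0:
            raise ValidationError(f"{path}: negative branch length on {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError(f"{path}: duplicate tip labels")
    return tree


def write_newick_tree(tree: TreeNode, path) -> None:
    Path(path).write_text(str(tree).strip() + "\n")


def harmonize_samples(
    tables: list[FeatureTable],
    metadata: SampleMetadata | None = None,
):
    """Restrict all inputs to their common samples in lexicographic order.

    Returns ``(tables, metadata, report)`` where ``report`` maps each input
    (``table_0``, ..., ``metadata``) to the sample ids it lost.
    """
    if not tables:
        raise ValidationError("harmonize_samples needs at least one table")
    common = set(tables[0].sample_ids)
    for t in tables[1:]:
        common &= set(t.sample_ids)
    if metadata is not None:
        common &= set(metadata.sample_ids)
    if not common:
        raise ValidationError("no samples shared across all inputs")
    order = sorted(common)
    report: dict[str, list[str]] = {}
    out_tables = []
    for i, t in enumerate(tables):
        report[f"table_{i}"] = sorted(set(t.sample_ids) - common)
        out_tables.append(t.with_data(t.data.loc[order]))
    out_meta = None
    if metadata is not None:
        report["metadata"] = sorted(set(metadata.sample_ids) - common)
        out_meta = SampleMetadata(metadata.data.loc[order].copy(),
                                  dict(metadata.column_types))
    return out_tables, out_meta, report
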