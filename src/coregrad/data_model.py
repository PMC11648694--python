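"""Domain types and file I/O for amplicon analysis artifacts.

Feature (ASV × sample) count tables, sample metadata, 7-rank taxonomy maps,
rooted phylogenies and distance matrices, all in plain-text interchange
formats: tab-separated tables (UTF-8, ``#`` comment lines ignored, feature
ids in the first column) and Newick trees.  Also the taxonomy-driven table
operations: contaminant filtering (chloroplast/mitochondria), rank collapsing,
and family-level composition summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
STAGES = ("larva", "female", "male", "pulp")
TRANSECTS = ("latitudinal", "altitudinal")

DEFAULT_EXCLUDE_TERMS = ("chloroplast", "mitochondria")

METADATA_COLUMNS = (
    "sample_id",
    "stage",
    "site",
    "latitude_deg_n",
    "altitude_masl",
    "transect",
)


class FormatError(ValueError):
    """A file does not conform to the expected plain-text format."""


@dataclass(frozen=True)
class FeatureTable:
    """Non-negative integer count matrix, features (ASVs) × samples.

    The central object every pipeline stage consumes.  Backed by a pandas
    DataFrame with feature ids as the index and sample ids as columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                raise ValueError("counts must be finite integers")
            object.__setattr__(self, "data", df.astype(np.int64))
            values = self.data.to_numpy()
        if values.size and values.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)


def _read_tsv_rows(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise FormatError(f"{path}: empty file")
    return rows


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature-table TSV: header row = sample ids, first column = feature ids."""
    rows = _read_tsv_rows(path)
    header = rows[0]
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise FormatError(f"{path}: duplicate sample id '{s}'")
        seen.add(s)
    n_cols = len(header)
    feature_ids: list[str] = []
    counts: list[list[int]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise FormatError(
                f"{path}: line {i} has {len(row)} fields, expected {n_cols} (ragged row)"
            )
        feature_ids.append(row[0])
        parsed = []
        for s, cell in zip(sample_ids, row[1:]):
            try:
                value = int(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-integer count '{cell}' at feature '{row[0]}', sample '{s}'"
                ) from exc
            if value < 0:
                raise ValueError(
                    f"{path}: negative count {value} at feature '{row[0]}', sample '{s}'"
                )
            parsed.append(value)
        counts.append(parsed)
    if len(set(feature_ids)) != len(feature_ids):
        dups = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise FormatError(f"{path}: duplicate feature ids: {dups}")
    df = pd.DataFrame(
        np.asarray(counts, dtype=np.int64).reshape(len(feature_ids), len(sample_ids)),
        index=feature_ids,
        columns=sample_ids,
    )
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    df = table.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV; returns a DataFrame indexed by sample_id.

    Required columns: sample_id, stage, site, latitude_deg_n, altitude_masl,
    transect.  Stage must be one of larva/female/male/pulp; transect one of
    latitudinal/altitudinal; latitude within [-90, 90]; altitude >= 0 when
    present (empty cells are allowed and read as NaN).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required metadata columns: {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample ids: {dups}")
    bad_stage = sorted(set(df["stage"]) - set(STAGES))
    if bad_stage:
        raise ValueError(
            f"{path}: invalid stage values {bad_stage}; allowed stages are {list(STAGES)}"
        )
    bad_transect = sorted(set(df["transect"].dropna()) - set(TRANSECTS))
    if bad_transect:
        raise ValueError(
            f"{path}: invalid transect values {bad_transect}; allowed: {list(TRANSECTS)}"
        )
    lat = pd.to_numeric(df["latitude_deg_n"], errors="raise")
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError(f"{path}: latitude_deg_n outside [-90, 90]")
    alt = pd.to_numeric(df["altitude_masl"], errors="raise")
    if (alt.dropna() < 0).any():
        raise ValueError(f"{path}: negative altitude_masl")
    df = df.assign(latitude_deg_n=lat, altitude_masl=alt)
    return df.set_index("sample_id")


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    out = metadata.reset_index()
    if out.columns[0] != "sample_id":
        out = out.rename(columns={out.columns[0]: "sample_id"})
    out.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV (feature_id <TAB> semicolon-joined 7-rank lineage).

    Returns a DataFrame indexed by feature_id with one column per rank
    (domain..species).  Lineages shorter than 7 ranks are right-padded with
    empty strings; a filled rank below an empty one is a format error
    (lineages must be left-filled).
    """
    rows = _read_tsv_rows(path)
    start = 0
    if rows and rows[0][0].lower() in ("feature_id", "feature id", "asv", "otu"):
        start = 1
    records = {}
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2:
            raise FormatError(f"{path}: line {i}: expected feature_id<TAB>lineage")
        fid, lineage = row[0], row[1]
        if fid in records:
            raise FormatError(f"{path}: duplicate feature id '{fid}'")
        ranks = [r.strip() for r in lineage.split(";")]
        if len(ranks) > len(RANKS):
            raise FormatError(
                f"{path}: feature '{fid}' has {len(ranks)} ranks, more than {len(RANKS)}"
            )
        ranks += [""] * (len(RANKS) - len(ranks))
        filled = [bool(r) for r in ranks]
        if any(filled[j] and not filled[j - 1] for j in range(1, len(ranks))):
            raise FormatError(
                f"{path}: feature '{fid}' lineage has a gap below a filled rank"
            )
        records[fid] = ranks
    df = pd.DataFrame.from_dict(records, orient="index", columns=list(RANKS))
    df.index.name = "feature_id"
    return df


def write_taxonomy(taxonomy: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tlineage\n")
        for fid, row in taxonomy.iterrows():
            lineage = ";".join(str(row[r]) for r in RANKS)
            fh.write(f"{fid}\t{lineage}\n")


def read_tree(path: str | Path) -> skbio.TreeNode:
    """Read a rooted Newick tree with branch lengths over feature-id leaves.

    Rejects unrooted trees (a trifurcating root): rooting changes UniFrac and
    must be an explicit user action upstream.
    """
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"{path}: unparsable Newick: {exc}") from exc
    return validate_tree(tree, source=str(path))


def validate_tree(tree: skbio.TreeNode, source: str = "tree") -> skbio.TreeNode:
    if len(tree.children) != 2:
        raise ValueError(
            f"{source}: tree root has {len(tree.children)} children; provide a rooted "
            "(bifurcating-root) tree — auto-rooting would change UniFrac distances"
        )
    names = [leaf.name for leaf in tree.tips()]
    if len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"{source}: duplicate leaf labels: {dups}")
    for node in tree.postorder(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"{source}: negative branch length on '{node.name}'")
    return tree


def write_tree(tree: skbio.TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_distance_matrix(path: str | Path) -> skbio.DistanceMatrix:
    """Read a square distance-matrix TSV with a header row/column of sample ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column sample ids differ")
    values = df.to_numpy(dtype=float)
    values = (values + values.T) / 2.0  # absorb round-tripped formatting noise
    return skbio.DistanceMatrix(values, ids=[str(i) for i in df.index])


def write_distance_matrix(dm: skbio.DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


# ---------------------------------------------------------------------------
# taxonomy-driven table operations


def _check_taxonomy_covers(table: FeatureTable, taxonomy: pd.DataFrame) -> None:
    orphans = [f for f in table.feature_ids if f not in taxonomy.index]
    if orphans:
        raise ValueError(f"features lacking a taxonomy entry: {orphans}")


def filter_taxa(
    table: FeatureTable,
    taxonomy: pd.DataFrame,
    exclude_terms: Iterable[str] = DEFAULT_EXCLUDE_TERMS,
) -> FeatureTable:
    """Drop features whose lineage matches any exclusion term at any rank.

    Matching is substring and case-insensitive at every rank: reference
    taxonomies place "Chloroplast" at order and "Mitochondria" at family, so
    rank-specific matching would silently miss dialects.  Counts of retained
    features are unchanged; samples are never dropped.
    """
    _check_taxonomy_covers(table, taxonomy)
    terms = [t.lower() for t in exclude_terms]
    if not terms:
        return table
    tax = taxonomy.loc[table.feature_ids]
    lineage_lower = tax.apply(lambda col: col.str.lower())
    matched = pd.Series(False, index=tax.index)
    for term in terms:
        matched |= lineage_lower.apply(lambda col: col.str.contains(term, regex=False)).any(
            axis=1
        )
    kept = table.data.loc[~matched.to_numpy()]
    if kept.shape[0] == 0:
        warnings.warn("filter_taxa removed every feature; returning an empty table")
    return FeatureTable(kept)


def _collapse_labels(
    taxonomy: pd.DataFrame, feature_ids: Sequence[str], rank: str
) -> tuple[list[tuple[str, ...]], dict[tuple[str, ...], str]]:
    """Group key (lineage prefix through rank) and display label per group."""
    depth = RANKS.index(rank) + 1
    keys: list[tuple[str, ...]] = []
    labels: dict[tuple[str, ...], str] = {}
    for fid in feature_ids:
        lineage = [str(taxonomy.at[fid, r]) for r in RANKS[:depth]]
        key = tuple(lineage)
        keys.append(key)
        if key not in labels:
            if lineage[-1]:
                labels[key] = lineage[-1]
            else:
                parents = [p for p in lineage if p]
                parent = parents[-1] if parents else ""
                labels[key] = f"Unclassified {parent}".strip()
    # disambiguate identical display labels from distinct prefixes
    by_label: dict[str, list[tuple[str, ...]]] = {}
    for key, label in labels.items():
        by_label.setdefault(label, []).append(key)
    for label, key_list in by_label.items():
        if len(key_list) > 1:
            for j, key in enumerate(key_list, start=1):
                labels[key] = f"{label} ({j})"
    return keys, labels


def collapse_taxonomy(
    table: FeatureTable, taxonomy: pd.DataFrame, rank: str
) -> FeatureTable:
    """Sum features sharing the lineage prefix through `rank`.

    Column totals are preserved exactly.  Features unclassified at `rank`
    are labeled "Unclassified <nearest filled parent>"; distinct prefixes
    that would collide on a display label are disambiguated.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {list(RANKS)}, got '{rank}'")
    _check_taxonomy_covers(table, taxonomy)
    keys, labels = _collapse_labels(taxonomy, table.feature_ids, rank)
    grouped = table.data.groupby([labels[k] for k in keys], sort=True).sum()
    grouped.index.name = "feature_id"
    return FeatureTable(grouped)


def family_composition(
    table: FeatureTable,
    taxonomy: pd.DataFrame,
    min_mean_abundance: float = 0.05,
    other_label: str = "Others",
    rank: str = "family",
) -> pd.DataFrame:
    """Per-sample relative abundance at family rank, rare families pooled.

    Families whose mean relative abundance across the samples is strictly
    below `min_mean_abundance` are summed into `other_label`.  Every output
    column sums to 1.
    """
    totals = table.sample_totals()
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"samples with zero total counts: {list(zero.index)}")
    collapsed = collapse_taxonomy(table, taxonomy, rank)
    rel = collapsed.data / totals
    means = rel.mean(axis=1)
    rare = means < min_mean_abundance
    kept = rel.loc[~rare]
    if rare.any():
        others = rel.loc[rare].sum(axis=0).to_frame(other_label).T
        kept = pd.concat([kept, others])
    kept.index.name = "family"
    return kept
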