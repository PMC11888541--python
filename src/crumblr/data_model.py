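"""Containers and I/O for cell-cluster counts, sample metadata, model formulas
and cell-lineage hierarchies.

The central container is :class:`CompositionMatrix`, a samples x clusters
matrix of non-negative integer cell counts.  Counts can be read from a
delimited table (first column = sample id, header = cluster ids), from a
Matrix Market triplet with sidecar row/column name files, or aggregated from
a per-cell annotation table.  Hierarchies are Newick trees whose leaves are
cluster ids.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from formulaic import model_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "CompositionMatrix",
    "SampleMetadata",
    "ModelSpec",
    "ClusterTree",
    "read_counts",
    "write_counts",
    "read_metadata",
    "aggregate_cells",
    "read_tree",
]


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what}: {x!r}")
        seen.add(x)
    return ids


@dataclass
class CompositionMatrix:
    """Samples x clusters matrix of non-negative integer cell counts."""

    counts: np.ndarray
    sample_ids: list[str]
    cluster_ids: list[str]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("non-integer count entries")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            raise ValueError("negative count entries")
        self.counts = arr.astype(np.int64)
        self.sample_ids = _check_unique(self.sample_ids, "sample id")
        self.cluster_ids = _check_unique(self.cluster_ids, "cluster id")
        if len(self.sample_ids) != arr.shape[0]:
            raise ValueError("sample_ids length does not match matrix rows")
        if len(self.cluster_ids) != arr.shape[1]:
            raise ValueError("cluster_ids length does not match matrix columns")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.counts.shape[1]

    @property
    def totals(self) -> np.ndarray:
        """Per-sample total cell count (row sums)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.cluster_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CompositionMatrix":
        return cls(df.to_numpy(), list(map(str, df.index)), list(map(str, df.columns)))

    def subset_clusters(self, cluster_ids: Sequence[str]) -> "CompositionMatrix":
        idx = [self.cluster_ids.index(c) for c in cluster_ids]
        return CompositionMatrix(self.counts[:, idx], list(self.sample_ids), list(cluster_ids))


@dataclass
class SampleMetadata:
    """Covariate table keyed by sample id.

    Columns are typed numeric or categorical; non-numeric columns become
    categoricals unless overridden with ``type_map`` ("numeric"/"categorical").
    """

    table: pd.DataFrame
    type_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        df.index = df.index.astype(str)
        for col in df.columns:
            kind = self.type_map.get(col)
            if kind == "numeric":
                df[col] = pd.to_numeric(df[col])
            elif kind == "categorical":
                df[col] = df[col].astype("category")
            elif not pd.api.types.is_numeric_dtype(df[col]):
                df[col] = df[col].astype("category")
        self.table = df

    def align(self, counts: CompositionMatrix) -> pd.DataFrame:
        """Return rows ordered to match ``counts.sample_ids``.

        Metadata may be a superset of the count samples (extras are dropped
        with a warning); samples missing from metadata are an error.
        """
        missing = [s for s in counts.sample_ids if s not in self.table.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        extra = self.table.index.difference(counts.sample_ids)
        if len(extra):
            logger.warning("ignoring %d metadata samples absent from counts", len(extra))
        return self.table.loc[counts.sample_ids]


_RANDOM_TERM = re.compile(r"\(\s*1\s*\|\s*([A-Za-z_][A-Za-z0-9_.]*)\s*\)")


@dataclass
class ModelSpec:
    """A model formula, the coefficient to test, and any random intercepts.

    ``formula`` is a right-hand-side formula; random intercepts are written
    ``(1|group)`` and stripped before the fixed part is expanded.
    """

    formula: str
    coef_of_interest: str
    random_terms: list[str] = field(default_factory=list)

    @classmethod
    def parse(cls, formula: str, coef_of_interest: str) -> "ModelSpec":
        random_terms = _RANDOM_TERM.findall(formula)
        fixed = _RANDOM_TERM.sub("", formula)
        fixed = re.sub(r"\+\s*(\+|$)", r"\1", fixed.strip())
        fixed = fixed.rstrip("+ ").strip()
        if not fixed.lstrip("~ ").strip():
            fixed = "~ 1"
        if not fixed.startswith("~"):
            fixed = "~ " + fixed
        return cls(fixed, coef_of_interest, random_terms)

    def design(self, metadata: pd.DataFrame) -> pd.DataFrame:
        """Expand the fixed part into a design matrix (samples x c)."""
        X = model_matrix(self.formula, metadata)
        return pd.DataFrame(np.asarray(X), index=metadata.index, columns=list(X.columns))

    def resolve_coef(self, columns: Sequence[str]) -> str:
        """Match ``coef_of_interest`` to exactly one design-matrix column."""
        cols = list(columns)
        if self.coef_of_interest in cols:
            return self.coef_of_interest
        hits = [c for c in cols if c.startswith(self.coef_of_interest + "[")]
        if len(hits) == 1:
            return hits[0]
        raise ValueError(
            f"coefficient {self.coef_of_interest!r} matches {len(hits)} design columns "
            f"(available: {cols})"
        )


class ClusterTree:
    """Rooted cell-lineage hierarchy with leaves labelled by cluster ids."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            name = leaf.taxon.label if leaf.taxon is not None else leaf.label
            if not name:
                raise ValueError("unlabeled leaf in tree")
            labels.append(str(name))
        self.leaf_labels = _check_unique(labels, "leaf label")
        # assign stable ids to internal nodes (preorder)
        k = 0
        self._internal: list[tuple[str, list[str]]] = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            label = node.label
            if not label:
                k += 1
                label = f"node{k}"
                node.label = label
            members = sorted(
                str(l.taxon.label if l.taxon is not None else l.label)
                for l in node.leaf_iter()
            )
            self._internal.append((str(label), members))
        names = [n for n, _ in self._internal]
        _check_unique(names + self.leaf_labels, "node label")

    @classmethod
    def from_newick(cls, newick: str) -> "ClusterTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.utility.error.DataParseError as err:
            if "Duplicate taxon" in str(err):
                raise ValueError(f"duplicate leaf label in tree: {err}") from err
            raise ValueError(f"could not parse Newick tree: {err}") from err
        return cls(tree)

    def internal_nodes(self) -> list[tuple[str, list[str]]]:
        """(node_id, descendant leaf labels) for every internal node, preorder."""
        return list(self._internal)

    def validate_against(self, cluster_ids: Sequence[str]) -> None:
        missing = sorted(set(self.leaf_labels) - set(cluster_ids))
        if missing:
            raise ValueError(f"tree leaves missing from fitted clusters: {missing}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"ClusterTree({len(self.leaf_labels)} leaves, {len(self._internal)} internal nodes)"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_counts(path: str | Path, format: str | None = None) -> CompositionMatrix:
    """Read a counts matrix from a delimited table or Matrix Market triplet.

    Delimited: header row of cluster ids, first column of sample ids;
    comma/tab auto-detected from the extension.  Matrix Market: ``<path>``
    plus sidecar ``<path>.rows.txt`` / ``<path>.cols.txt`` name files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format is None:
        format = "matrix-market" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "matrix-market":
        mat = scipy.io.mmread(str(path))
        arr = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
        rows = Path(str(path) + ".rows.txt").read_text().split()
        cols = Path(str(path) + ".cols.txt").read_text().split()
        return CompositionMatrix(arr, rows, cols)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric count entries in column {col!r}")
    return CompositionMatrix.from_dataframe(df)


def write_counts(cm: CompositionMatrix, path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "matrix-market" if path.suffix.lower() == ".mtx" else "delimited"
    if format == "matrix-market":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        Path(str(path) + ".rows.txt").write_text("\n".join(cm.sample_ids) + "\n")
        Path(str(path) + ".cols.txt").write_text("\n".join(cm.cluster_ids) + "\n")
    else:
        cm.to_dataframe().to_csv(path, sep=_sep_for(path))


def read_metadata(
    path: str | Path, type_map: dict[str, str] | None = None
) -> SampleMetadata:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return SampleMetadata(df, type_map or {})


def aggregate_cells(cell_table: pd.DataFrame) -> CompositionMatrix:
    """Tabulate a per-cell annotation table into a CompositionMatrix.

    ``cell_table`` needs columns ``cell_id``, ``sample_id``, ``cluster_label``;
    samples and clusters are ordered by first appearance.
    """
    required = {"cell_id", "sample_id", "cluster_label"}
    missing_cols = required - set(cell_table.columns)
    if missing_cols:
        raise ValueError(f"cell table missing columns: {sorted(missing_cols)}")
    if len(cell_table) == 0:
        raise ValueError("no cells in table")
    if cell_table[["sample_id", "cluster_label"]].isna().any().any():
        raise ValueError("missing sample_id or cluster_label")
    if cell_table["cell_id"].duplicated().any():
        dup = cell_table["cell_id"][cell_table["cell_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate cell_id: {dup!r}")
    samples = list(dict.fromkeys(cell_table["sample_id"].astype(str)))
    clusters = list(dict.fromkeys(cell_table["cluster_label"].astype(str)))
    counts = np.zeros((len(samples), len(clusters)), dtype=np.int64)
    si = {s: i for i, s in enumerate(samples)}
    ci = {c: j for j, c in enumerate(clusters)}
    grouped = cell_table.groupby(
        [cell_table["sample_id"].astype(str), cell_table["cluster_label"].astype(str)]
    ).size()
    for (s, c), n in grouped.items():
        counts[si[s], ci[c]] = n
    return CompositionMatrix(counts, samples, clusters)


def read_tree(path: str | Path) -> ClusterTree:
    """Read a Newick hierarchy whose leaves are cluster ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return ClusterTree.from_newick(path.read_text())
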