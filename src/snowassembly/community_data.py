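"""Reading, validation, filtering and alignment of the three core inputs.

A dataset consists of a taxa-by-samples integer count table (TSV), a rooted
phylogeny with branch lengths (Newick) whose tips are the taxa, and a sample
metadata table (CSV/TSV) carrying site, sampling date, snow colour and
nutrient covariates.  ``align_dataset`` reconciles the three into a
consistent triple: the tree is pruned to the taxa of the count table, taxa
missing from the tree are dropped with a warning, and every sample must
have exactly one metadata row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

SNOW_COLORS = ("white", "light-green", "green", "red", "mixed")


class CommunityDataError(ValueError):
    """Raised when an input table or tree violates its contract."""


@dataclass
class CommunityMatrix:
    """Non-negative integer read counts, taxa as rows, samples as columns.

    ``counts`` is a pandas DataFrame indexed by taxon id with sample ids as
    columns.  Identifiers must be unique; cells must be non-negative
    integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CommunityDataError(f"duplicate taxon identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CommunityDataError(f"duplicate sample identifiers: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            # accept float columns that are exactly integral (pandas may
            # promote on read); anything else is a parse error
            if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
                bad = np.argwhere(~np.isfinite(values) | (values != np.floor(values)))[0]
                raise CommunityDataError(
                    f"non-integer count at taxon {df.index[bad[0]]!r}, "
                    f"sample {df.columns[bad[1]]!r}"
                )
            df = df.astype(np.int64)
            object.__setattr__(self, "counts", df)
            values = df.to_numpy()
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)[0]
            raise CommunityDataError(
                f"negative count at taxon {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )

    @property
    def taxon_ids(self) -> list:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class AlignedDataset:
    """Consistent triple produced by :func:`align_dataset`."""

    cm: CommunityMatrix
    tree: TreeNode
    meta: pd.DataFrame
    dropped_taxa: list = field(default_factory=list)


def read_counts(path, orientation: str = "taxa-rows") -> CommunityMatrix:
    """Read a tab-separated count table into a :class:`CommunityMatrix`.

    Parameters
    ----------
    path : str or Path
        TSV file; first header cell names the row-identifier column.
    orientation : {"taxa-rows", "samples-rows"}
        Layout of the file.  ``samples-rows`` tables are transposed on read
        so the in-memory orientation is always taxa-as-rows.
    """
    if orientation not in ("taxa-rows", "samples-rows"):
        raise CommunityDataError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "samples-rows":
        df = df.T
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise CommunityDataError(
                f"non-numeric count at taxon {bad.index[0]!r}, sample {col!r}"
            )
    return CommunityMatrix(df)


def write_counts(cm: CommunityMatrix, path) -> None:
    """Write a count table as TSV (taxa rows); inverse of :func:`read_counts`."""
    out = cm.counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def filter_rare_taxa(cm: CommunityMatrix) -> CommunityMatrix:
    """Drop singleton taxa and taxa present in only one sample.

    Removes every taxon whose total count is <= 1 and every taxon with
    nonzero counts in exactly one sample (or none).  The surviving taxon
    order is preserved.  Idempotent.
    """
    totals = cm.counts.sum(axis=1)
    occupancy = (cm.counts > 0).sum(axis=1)
    keep = (totals > 1) & (occupancy > 1)
    if not keep.any():
        raise CommunityDataError("no taxa survive the rare-taxon filter")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("filter_rare_taxa: dropped %d of %d taxa", n_dropped, cm.n_taxa)
    return CommunityMatrix(cm.counts.loc[keep])


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree; every non-root branch must have a length."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise CommunityDataError(
                f"branch leading to {node.name or '<internal>'} has no length"
            )
        if node.length < 0:
            raise CommunityDataError(
                f"negative branch length on {node.name or '<internal>'}"
            )
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise CommunityDataError("duplicate tip labels in tree")
    return tree


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata table (CSV or TSV, sniffed by extension).

    Expected columns: sample_id, site, date (ISO-8601), snow_color, nh4,
    no3, po4, doc and optionally chla.  Nutrient concentrations are in
    mg/L, chlorophyll a in ug/L.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    meta = pd.read_csv(path, sep=sep)
    required = ["sample_id", "site", "date", "snow_color", "nh4", "no3", "po4", "doc"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise CommunityDataError(f"metadata missing columns: {missing}")
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise CommunityDataError("duplicate sample_id in metadata")
    meta["date"] = pd.to_datetime(meta["date"])
    bad_color = set(meta["snow_color"]) - set(SNOW_COLORS)
    if bad_color:
        raise CommunityDataError(f"unknown snow colours: {sorted(bad_color)}")
    for col in ("nh4", "no3", "po4", "doc"):
        if (meta[col] < 0).any():
            raise CommunityDataError(f"negative concentration in column {col!r}")
    return meta.set_index("sample_id", drop=False)


def align_dataset(cm: CommunityMatrix, tree: TreeNode, meta: pd.DataFrame) -> AlignedDataset:
    """Reconcile counts, tree and metadata into a consistent dataset.

    The tree is pruned to the taxa of the count table (extra tips removed
    silently); count-table taxa absent from the tree are dropped with a
    warning; samples without a metadata row are a fatal error.
    """
    tip_names = {t.name for t in tree.tips()}
    taxa = list(cm.counts.index)
    shared = [t for t in taxa if t in tip_names]
    if not shared:
        raise CommunityDataError("no taxa shared between count table and tree")
    dropped = [t for t in taxa if t not in tip_names]
    if dropped:
        warnings.warn(
            f"{len(dropped)} taxa absent from the tree were dropped: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
        cm = CommunityMatrix(cm.counts.loc[shared])
    if set(shared) != tip_names:
        tree = tree.shear(shared)
        tree.prune()
    missing_meta = [s for s in cm.sample_ids if s not in meta.index]
    if missing_meta:
        raise CommunityDataError(f"samples without metadata: {missing_meta}")
    meta = meta.loc[cm.sample_ids]
    logger.info(
        "align_dataset: %d taxa, %d samples after alignment (%d taxa dropped)",
        cm.n_taxa,
        cm.n_samples,
        len(dropped),
    )
    return AlignedDataset(cm=cm, tree=tree, meta=meta, dropped_taxa=dropped)


def relative_abundance(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-sample relative abundances; each column sums to 1."""
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise CommunityDataError(f"samples with zero total count: {list(zero.index)}")
    return cm.counts / totals
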