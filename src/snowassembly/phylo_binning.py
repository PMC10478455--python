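"""Partitioning taxa into phylogenetic bins.

Per-bin null models assume that taxa within a bin are close enough on the
tree for within-bin phylogenetic turnover to be ecologically interpretable.
Bins are built by single-linkage clustering of the cophenetic (tip-to-tip
path length) distance matrix cut at a distance threshold ``ds``; clusters
smaller than ``nmin`` taxa are then merged into their nearest neighbouring
cluster (smallest average inter-cluster distance) so every final bin has at
least ``min(nmin, n_taxa)`` members.  The procedure is deterministic and
invariant to taxon input order: bins are canonically renumbered by their
lexicographically smallest member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from snowassembly.community_data import CommunityMatrix, relative_abundance


@dataclass
class BinSet:
    """A partition of the taxon set into phylogenetic bins.

    ``bins`` maps 1-based contiguous bin index -> list of taxon ids;
    ``assignment`` is the inverse map taxon id -> bin index.
    """

    bins: dict
    params: dict = field(default_factory=dict)

    @property
    def assignment(self) -> dict:
        return {t: b for b, taxa in self.bins.items() for t in taxa}

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def taxa(self) -> list:
        return [t for taxa in self.bins.values() for t in taxa]


def cophenetic_distances(tree) -> pd.DataFrame:
    """Tip-to-tip path-length matrix as a DataFrame indexed by tip name."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def _canonical(bins_raw: list[list[str]], params: dict) -> BinSet:
    ordered = sorted(bins_raw, key=lambda taxa: min(taxa))
    return BinSet(
        bins={i + 1: sorted(taxa) for i, taxa in enumerate(ordered)}, params=params
    )


def assign_bins(dist: pd.DataFrame, ds: float = 0.2, nmin: int = 12) -> BinSet:
    """Cluster taxa into bins from a cophenetic distance matrix.

    Single-linkage clusters at height ``ds``; clusters with fewer than
    ``nmin`` taxa are merged iteratively into the cluster at the smallest
    average inter-cluster distance (ties broken toward the lower bin
    index).  With ``nmin=1`` and ``ds`` above the tree diameter a single
    bin results.
    """
    if ds <= 0:
        raise ValueError("ds must be > 0")
    if nmin < 1:
        raise ValueError("nmin must be >= 1")
    taxa = list(dist.index)
    n = len(taxa)
    if n < 1:
        raise ValueError("need at least one taxon")
    # canonical taxon order so the clustering is input-order invariant
    order = np.argsort(np.asarray(taxa, dtype=object))
    taxa_sorted = [taxa[i] for i in order]
    D = dist.to_numpy()[np.ix_(order, order)].astype(float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    params = {"ds": ds, "nmin": nmin}
    if n == 1:
        return _canonical([taxa_sorted], params)
    Z = linkage(squareform(D, checks=False), method="single")
    labels = fcluster(Z, t=ds, criterion="distance")
    clusters = [list(np.flatnonzero(labels == lab)) for lab in np.unique(labels)]
    clusters.sort(key=lambda idx: taxa_sorted[min(idx)])

    target = min(nmin, n)
    while len(clusters) > 1:
        sizes = [len(c) for c in clusters]
        small = [i for i, s in enumerate(sizes) if s < target]
        if not small:
            break
        # smallest cluster first; ties -> lower index
        i = min(small, key=lambda k: (sizes[k], k))
        best_j, best_d = None, np.inf
        for j in range(len(clusters)):
            if j == i:
                continue
            d = D[np.ix_(clusters[i], clusters[j])].mean()
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and (best_j is None or j < best_j)):
                best_j, best_d = j, d
        a, b = sorted((i, best_j))
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.insert(a, merged)
    return _canonical([[taxa_sorted[i] for i in c] for c in clusters], params)


def bin_weights(cm: CommunityMatrix, bins: BinSet, pair: tuple) -> dict:
    """Relative-abundance weight of each bin for one sample pair.

    weight(b) = mean over the two samples of the summed relative abundance
    of b's taxa.  Weights sum to 1.
    """
    a, b = pair
    for s in (a, b):
        if s not in cm.counts.columns:
            raise KeyError(f"unknown sample id {s!r}")
    if set(bins.taxa()) != set(cm.taxon_ids):
        raise ValueError("bins do not partition the count table's taxa")
    rel = relative_abundance(cm)[[a, b]]
    return {
        bid: float(rel.loc[taxa].sum(axis=0).mean()) for bid, taxa in bins.bins.items()
    }


def bin_summary(cm: CommunityMatrix, bins: BinSet) -> pd.DataFrame:
    """Per-bin taxon count and mean relative abundance across all samples."""
    rel = relative_abundance(cm)
    rows = []
    for bid, taxa in bins.bins.items():
        rows.append(
            {
                "bin_id": bid,
                "n_taxa": len(taxa),
                "mean_relative_abundance": float(rel.loc[taxa].sum(axis=0).mean()),
            }
        )
    return pd.DataFrame(rows).set_index("bin_id")
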