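"""Classification of pair x bin metrics into ecological processes and
aggregation to community-level, interval-level and bin-level summaries.

The decision rules follow the bin-based null-model framework: selection is
inferred from the phylogenetic index alone (bNRI < -1.96 homogeneous,
bNRI > +1.96 heterogeneous, strict inequalities); among the remaining
comparisons the taxonomic index decides (RC < -0.95 homogenizing
dispersal, RC > +0.95 dispersal limitation); everything else is the
"drift" bucket, which aggregates drift, diversification, weak selection
and weak dispersal.  Community-level fractions weight each bin by the
mean relative abundance of its taxa in the two samples compared; bins
with undefined metrics are excluded and their weight is redistributed
proportionally so fractions always sum to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from snowassembly.phylo_binning import BinSet, bin_weights

logger = logging.getLogger(__name__)


class ProcessLabel(str, Enum):
    HeS = "HeS"  # heterogeneous selection
    HoS = "HoS"  # homogeneous selection
    DL = "DL"  # dispersal limitation
    HD = "HD"  # homogenizing dispersal
    DR = "DR"  # drift & others

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PROCESSES = [ProcessLabel.HeS, ProcessLabel.HoS, ProcessLabel.DL, ProcessLabel.HD, ProcessLabel.DR]


@dataclass
class PartitionThresholds:
    """Significance cut-offs for the two standardized indices."""

    bnri_crit: float = 1.96
    rc_crit: float = 0.95

    def __post_init__(self) -> None:
        if self.bnri_crit <= 0 or self.rc_crit <= 0:
            raise ValueError("thresholds must be > 0")


def classify_pair(bnri: float, rc: float, th: PartitionThresholds | None = None) -> ProcessLabel:
    """Map one (bNRI, RC) pair to its ecological process.

    bNRI < -crit -> homogeneous selection; bNRI > +crit -> heterogeneous
    selection; otherwise RC < -rc_crit -> homogenizing dispersal,
    RC > +rc_crit -> dispersal limitation, else drift.  The selection
    branches are strict, so bNRI = +/-1.96 falls through to the RC rules.
    """
    th = th or PartitionThresholds()
    if not (np.isfinite(bnri) and np.isfinite(rc)):
        raise ValueError("classify_pair requires finite bnri and rc")
    if bnri < -th.bnri_crit:
        return ProcessLabel.HoS
    if bnri > th.bnri_crit:
        return ProcessLabel.HeS
    if rc < -th.rc_crit:
        return ProcessLabel.HD
    if rc > th.rc_crit:
        return ProcessLabel.DL
    return ProcessLabel.DR


def pair_fractions(
    metrics: pd.DataFrame,
    weights: dict,
    th: PartitionThresholds | None = None,
) -> dict:
    """Community-level process fractions for one sample pair.

    ``metrics`` holds this pair's rows of the pair x bin table; ``weights``
    maps bin_id -> relative-abundance weight.  Bins with undefined (NaN)
    metrics are dropped and the surviving weights renormalized; the
    returned fractions sum to 1.
    """
    th = th or PartitionThresholds()
    ok = metrics.dropna(subset=["bnri", "rc"])
    if ok.empty:
        raise ValueError("no bin with defined metrics for this pair")
    w = np.array([weights[b] for b in ok["bin_id"]], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("defined bins carry zero weight")
    w = w / total
    out = {p: 0.0 for p in PROCESSES}
    for wi, bnri, rc in zip(w, ok["bnri"], ok["rc"]):
        out[classify_pair(bnri, rc, th)] += wi
    return out


def interval_series(meta: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-date comparison series: one row per (site, interval, pair).

    Intervals are numbered on the global sorted date grid: IntN compares
    global sampling date N with date N+1 within a site.  A site lacking a
    sample at either date contributes no pair for that interval; sites
    with fewer than two dates are excluded with a warning.
    """
    dates = sorted(meta["date"].unique())
    date_index = {d: i + 1 for i, d in enumerate(dates)}  # 1-based
    rows = []
    for site, grp in meta.groupby("site"):
        grp = grp.sort_values("date")
        if grp["date"].duplicated().any():
            raise ValueError(f"site {site} has duplicate sampling dates")
        if len(grp) < 2:
            warnings.warn(f"site {site} has fewer than two dates; excluded", stacklevel=2)
            continue
        by_date = {d: s for d, s in zip(grp["date"], grp["sample_id"])}
        for d in grp["date"]:
            n = date_index[d]
            nxt = dates[n] if n < len(dates) else None
            if nxt is not None and nxt in by_date:
                rows.append(
                    {
                        "site": site,
                        "interval": n,
                        "sample_a": by_date[d],
                        "sample_b": by_date[nxt],
                    }
                )
    return pd.DataFrame(rows, columns=["site", "interval", "sample_a", "sample_b"])


def _per_pair_fraction_table(metrics, cm, bins, series, th):
    """Fractions for every pair in the series, joined with site/interval."""
    grouped = metrics.groupby(["sample_a", "sample_b"])
    rows = []
    for rec in series.itertuples(index=False):
        pair = (rec.sample_a, rec.sample_b)
        try:
            pair_rows = grouped.get_group(pair)
        except KeyError:
            raise KeyError(f"metrics table lacks pair {pair}") from None
        w = bin_weights(cm, bins, pair)
        try:
            frac = pair_fractions(pair_rows, w, th)
        except ValueError:
            logger.warning("pair %s has no defined bins; skipped", pair)
            continue
        row = {"site": rec.site, "interval": rec.interval, "sample_a": rec.sample_a, "sample_b": rec.sample_b}
        row.update({p.value: frac[p] for p in PROCESSES})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_intervals(
    metrics: pd.DataFrame,
    cm,
    bins: BinSet,
    series: pd.DataFrame,
    th: PartitionThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interval summary table: per-process mean and sample sd across sites.

    Returns ``(summary, per_pair)`` where ``summary`` has one row per
    (interval, process) with mean_pct, sd_pct (ddof=1; 0 when a single
    site contributes) and n_sites, and ``per_pair`` is the underlying
    per-pair fraction table.
    """
    th = th or PartitionThresholds()
    per_pair = _per_pair_fraction_table(metrics, cm, bins, series, th)
    rows = []
    for interval, grp in per_pair.groupby("interval"):
        for p in PROCESSES:
            vals = grp[p.value].to_numpy(dtype=float)
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "interval": int(interval),
                    "process": p.value,
                    "mean_pct": 100.0 * float(vals.mean()),
                    "sd_pct": 100.0 * sd,
                    "n_sites": int(grp["site"].nunique()),
                }
            )
    return pd.DataFrame(rows), per_pair


def bin_process_contribution(
    metrics: pd.DataFrame,
    cm,
    bins: BinSet,
    series: pd.DataFrame,
    th: PartitionThresholds | None = None,
) -> pd.DataFrame:
    """Per-bin, per-process, per-interval contribution table.

    contribution(bin, P, IntN) = mean over the interval's pairs of
    weight(bin) * 1[bin labelled P], with the same exclusion and weight
    redistribution as :func:`pair_fractions`, so summing over bins
    reproduces the community-level fractions.
    """
    th = th or PartitionThresholds()
    grouped = metrics.groupby(["sample_a", "sample_b"])
    acc: dict = {}
    npairs: dict = {}
    for rec in series.itertuples(index=False):
        pair = (rec.sample_a, rec.sample_b)
        pair_rows = grouped.get_group(pair)
        ok = pair_rows.dropna(subset=["bnri", "rc"])
        if ok.empty:
            continue
        w = bin_weights(cm, bins, pair)
        wv = np.array([w[b] for b in ok["bin_id"]], dtype=float)
        wv = wv / wv.sum()
        npairs[rec.interval] = npairs.get(rec.interval, 0) + 1
        for wi, bid, bnri, rc in zip(wv, ok["bin_id"], ok["bnri"], ok["rc"]):
            label = classify_pair(bnri, rc, th)
            key = (rec.interval, bid, label.value)
            acc[key] = acc.get(key, 0.0) + wi
    rows = [
        {
            "interval": interval,
            "bin_id": bid,
            "process": proc,
            "contribution": total / npairs[interval],
        }
        for (interval, bid, proc), total in sorted(acc.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2]))
    ]
    return pd.DataFrame(rows, columns=["interval", "bin_id", "process", "contribution"])


def top_bins_report(cm, bins: BinSet, taxonomy: dict | None = None, k: int = 10) -> pd.DataFrame:
    """Bins ranked by mean relative abundance across all samples (top ``k``).

    ``taxonomy`` optionally maps taxon_id -> taxonomy string; each bin is
    annotated with the taxonomy of its most abundant member.
    """
    from snowassembly.community_data import relative_abundance

    rel = relative_abundance(cm)
    rows = []
    for bid, taxa in bins.bins.items():
        share = rel.loc[taxa].sum(axis=0).mean()
        rep = rel.loc[taxa].sum(axis=1).idxmax()
        rows.append(
            {
                "bin_id": bid,
                "relative_abundance_pct": 100.0 * float(share),
                "representative_taxon": rep,
                "taxonomy": (taxonomy or {}).get(rep, ""),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["relative_abundance_pct", "bin_id"], ascending=[False, True], kind="mergesort"
    )
    out.insert(0, "rank", range(1, len(out) + 1))
    return out.head(k).reset_index(drop=True)
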