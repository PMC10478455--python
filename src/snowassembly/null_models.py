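"""Observed and null beta-diversity per sample pair per phylogenetic bin.

Two indices are computed within each bin for each sample pair:

* beta Net Relatedness Index (bNRI): the abundance-weighted beta mean
  pairwise phylogenetic distance (bMPD) between the two communities,
  standardized against a null distribution obtained by shuffling which tip
  of the bin each taxon's abundance belongs to.  bNRI below -1.96 indicates
  phylogenetic turnover smaller than chance (consistent environmental
  filtering); above +1.96, larger than chance (divergent filtering).

* modified Raup-Crick index (RC): the Bray-Curtis dissimilarity between
  the two communities, rescaled to [-1, 1] by its rank within a null
  distribution of randomly reassembled communities.  Each null community
  preserves the sample's observed within-bin richness (taxa drawn with
  probability proportional to regional occurrence frequency) and its
  observed within-bin read total (filled proportionally to regional
  relative abundance); ties between null and observed dissimilarity count
  half.

Both nulls respect bin membership: taxa are only shuffled or redrawn
within the bin, never across bins, so per-bin inference remains valid.
All randomness flows from a single integer seed; streams are keyed by
(pair, bin) so results do not depend on evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from snowassembly.community_data import CommunityMatrix
from snowassembly.phylo_binning import BinSet

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@dataclass
class NullConfig:
    """Randomization settings shared by both null models.

    n_rand : number of null randomizations (1000 gives stable +/-1.96
        standardized effect sizes).
    seed : master seed; identical seed and inputs give identical output.
    abundance_weighted : weight bMPD by relative abundances (True) or by
        presence/absence (False).
    metric : "bmpd" (beta mean pairwise distance, the basis of the net
        relatedness index) or "bmntd" (beta mean nearest taxon distance).
    """

    n_rand: int = 1000
    seed: int = 0
    abundance_weighted: bool = True
    metric: str = "bmpd"

    def __post_init__(self) -> None:
        if self.n_rand < 1:
            raise ValueError("n_rand must be >= 1")
        if self.metric not in ("bmpd", "bmntd"):
            raise ValueError(f"unknown metric {self.metric!r}")


def beta_mpd(pA, pB, d) -> float:
    """Abundance-weighted mean pairwise phylogenetic distance between two
    communities: sum_i sum_j pA_i pB_j d_ij.

    ``pA`` and ``pB`` are abundance vectors over the bin's taxa,
    renormalized to sum to 1 (taxa absent from both samples may carry
    weight 0).  Returns NaN when either vector is all zero.
    """
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    d = np.asarray(d, dtype=float)
    if pA.sum() == 0 or pB.sum() == 0:
        return float("nan")
    return float(pA @ d @ pB)


def beta_mntd(pA, pB, d) -> float:
    """Abundance-weighted mean nearest taxon distance between communities."""
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    d = np.asarray(d, dtype=float)
    if pA.sum() == 0 or pB.sum() == 0:
        return float("nan")
    inB = pB > 0
    inA = pA > 0
    near_a = d[:, inB].min(axis=1)
    near_b = d[inA, :].min(axis=0)
    return float(0.5 * (pA @ near_a + pB @ near_b))


def bray_curtis(cA, cB) -> float:
    """Bray-Curtis dissimilarity on count vectors: sum|a-b| / sum(a+b)."""
    cA = np.asarray(cA, dtype=float)
    cB = np.asarray(cB, dtype=float)
    denom = (cA + cB).sum()
    if denom == 0:
        raise ValueError("both count vectors are all zero")
    return float(np.abs(cA - cB).sum() / denom)


def _renorm(v: np.ndarray) -> np.ndarray:
    s = v.sum()
    return v / s if s > 0 else v


def _phylo_metric(pA, pB, d, metric: str) -> float:
    return beta_mpd(pA, pB, d) if metric == "bmpd" else beta_mntd(pA, pB, d)


def null_bnri(pA, pB, d, cfg: NullConfig, rng=None):
    """Standardized effect size of the within-bin phylogenetic distance.

    The null shuffles the bin's taxon labels across the bin's tip
    positions: one permutation relabels both samples consistently, so the
    abundance structure is kept while the phylogenetic placement is
    randomized.  Returns ``(null_mean, null_sd, bnri)``; ``bnri`` is NaN
    when the null has zero spread.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pA = _renorm(np.asarray(pA, dtype=float))
    pB = _renorm(np.asarray(pB, dtype=float))
    d = np.asarray(d, dtype=float)
    k = len(pA)
    obs = _phylo_metric(pA, pB, d, cfg.metric)
    if not np.isfinite(obs):
        return float("nan"), float("nan"), float("nan")
    perms = np.argsort(rng.random((cfg.n_rand, k)), axis=1)
    if cfg.metric == "bmpd":
        V = pA[perms]  # (n_rand, k)
        W = pB[perms]
        null = np.einsum("ni,ij,nj->n", V, d, W, optimize=True)
    else:
        null = np.empty(cfg.n_rand)
        for r in range(cfg.n_rand):
            null[r] = beta_mntd(pA[perms[r]], pB[perms[r]], d)
    mean = float(null.mean())
    sd = float(null.std(ddof=1)) if cfg.n_rand > 1 else 0.0
    if sd <= 1e-12 * max(abs(mean), 1.0):
        logger.warning("null distribution has zero spread; bnri undefined")
        return mean, sd, float("nan")
    return mean, sd, float((obs - mean) / sd)


def rc_score(n_below: float, n_ties: float, n_rand: int) -> float:
    """Rank-rescale an observed dissimilarity against its null sample:
    rc = 2 [(#null < obs) + 0.5 (#null = obs)] / n_rand - 1, in [-1, 1]."""
    return float(2.0 * (n_below + 0.5 * n_ties) / n_rand - 1.0)


def _null_assemble(rng, n_rand, richness, total, occ_w, abund_w):
    """Assemble ``n_rand`` null communities over ``k`` taxa.

    Membership: ``richness`` taxa drawn without replacement with
    probability proportional to ``occ_w`` (Gumbel top-k trick, vectorized
    over randomizations).  Abundance: ``total`` individuals distributed
    multinomially over the drawn members proportionally to ``abund_w``.
    """
    k = len(occ_w)
    keys = np.log(occ_w)[None, :] + rng.gumbel(size=(n_rand, k))
    member = np.zeros((n_rand, k), dtype=bool)
    top = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    np.put_along_axis(member, top, True, axis=1)
    p = member * abund_w[None, :]
    p /= p.sum(axis=1, keepdims=True)
    return rng.multinomial(total, p)


def null_rc(cA, cB, occ_freq, regional_abund, cfg: NullConfig, rng=None) -> float:
    """Modified Raup-Crick index for one pair within one bin.

    ``cA``/``cB`` are the pair's within-bin count vectors; ``occ_freq`` is
    each taxon's occurrence frequency across all samples; ``regional_abund``
    its regional relative abundance.  rc = 2 * [(#null < obs) +
    0.5 * (#null = obs)] / n_rand - 1, bounded in [-1, 1].
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    cA = np.asarray(cA, dtype=np.int64)
    cB = np.asarray(cB, dtype=np.int64)
    k = len(cA)
    if k == 1:
        logger.warning("degenerate bin with a single taxon; rc set to 0")
        return 0.0
    obs = bray_curtis(cA, cB)
    occ_w = np.asarray(occ_freq, dtype=float)
    ab_w = np.asarray(regional_abund, dtype=float)
    if np.all(occ_w <= 0) or np.all(ab_w <= 0):
        logger.warning("degenerate regional pool; rc set to 0")
        return 0.0
    occ_w = np.clip(occ_w, 1e-12, None)
    ab_w = np.clip(ab_w, 1e-12, None)
    nullA = _null_assemble(rng, cfg.n_rand, int((cA > 0).sum()), int(cA.sum()), occ_w, ab_w)
    nullB = _null_assemble(rng, cfg.n_rand, int((cB > 0).sum()), int(cB.sum()), occ_w, ab_w)
    diff = np.abs(nullA - nullB).sum(axis=1)
    tot = (nullA + nullB).sum(axis=1)
    null = diff / tot
    below = float(np.sum(null < obs - _TIE_TOL))
    ties = float(np.sum(np.abs(null - obs) <= _TIE_TOL))
    return rc_score(below, ties, cfg.n_rand)


def pair_bin_metrics(
    cm: CommunityMatrix,
    dist: pd.DataFrame,
    bins: BinSet,
    pairs: list,
    cfg: NullConfig,
) -> pd.DataFrame:
    """Observed and null metrics for every sample pair x bin.

    Returns a DataFrame with columns sample_a, sample_b, bin_id,
    beta_mpd_obs, null_mean, null_sd, bnri, bray_obs, rc.  A pair x bin
    where either sample has no reads in the bin, or where the pair spans
    fewer than two taxa, is reported with NaN metrics and excluded from
    downstream fractions.
    """
    counts = cm.counts
    n_samples = cm.n_samples
    sample_pos = {s: i for i, s in enumerate(counts.columns)}
    X = counts.to_numpy()
    taxon_pos = {t: i for i, t in enumerate(counts.index)}

    bin_cache = {}
    for bid, taxa in bins.bins.items():
        idx = np.array([taxon_pos[t] for t in taxa])
        sub = X[idx]
        occ = (sub > 0).sum(axis=1) / n_samples
        tot = sub.sum(axis=1).astype(float)
        reg = tot / tot.sum() if tot.sum() > 0 else tot
        D = dist.loc[taxa, taxa].to_numpy()
        bin_cache[bid] = (idx, sub, occ, reg, D)

    rows = []
    for i_pair, (a, b) in enumerate(pairs):
        ia, ib = sample_pos[a], sample_pos[b]
        for bid in bins.bins:
            idx, sub, occ, reg, D = bin_cache[bid]
            cA = sub[:, ia]
            cB = sub[:, ib]
            row = {
                "sample_a": a,
                "sample_b": b,
                "bin_id": bid,
                "beta_mpd_obs": np.nan,
                "null_mean": np.nan,
                "null_sd": np.nan,
                "bnri": np.nan,
                "bray_obs": np.nan,
                "rc": np.nan,
            }
            union_richness = int(((cA > 0) | (cB > 0)).sum())
            if cA.sum() == 0 or cB.sum() == 0 or union_richness < 2:
                rows.append(row)
                continue
            pA = cA / cA.sum() if cfg.abundance_weighted else (cA > 0).astype(float)
            pB = cB / cB.sum() if cfg.abundance_weighted else (cB > 0).astype(float)
            rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, i_pair, bid])
            obs = _phylo_metric(_renorm(pA), _renorm(pB), D, cfg.metric)
            null_mean, null_sd, bnri = null_bnri(pA, pB, D, cfg, rng=rng)
            row["beta_mpd_obs"] = obs
            row["null_mean"] = null_mean
            row["null_sd"] = null_sd
            row["bnri"] = bnri
            row["bray_obs"] = bray_curtis(cA, cB)
            row["rc"] = null_rc(cA, cB, occ, reg, cfg, rng=rng)
            rows.append(row)
    return pd.DataFrame(rows)
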