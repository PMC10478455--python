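"""Supporting community statistics.

Alpha diversity (Shannon-Wiener in nats by default, bias-corrected Chao1,
analytic rarefaction), the Hellinger transformation, redundancy analysis
(RDA) constrained on environmental covariates with marginal ANOVA-like
permutation tests, the Mantel correlation between Hellinger distances and
biplot distances, and Pearson co-occurrence matrices with two-sided
t-test p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.spatial.distance import pdist
from scipy import stats

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(counts, base: float | None = None) -> float:
    """Shannon-Wiener index H = -sum p_i log p_i over nonzero proportions.

    Natural log (nats) by default; pass ``base`` for another logarithm.
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("community has zero total count")
    if (c < 0).any():
        raise ValueError("negative counts")
    p = c[c > 0] / c.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(base) if base is not None else h


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1 (F1 - 1) / (2 (F2 + 1))."""
    c = np.asarray(counts)
    if np.any(c != np.floor(c)):
        raise ValueError("chao1 requires integer counts")
    c = c.astype(np.int64)
    s_obs = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def observed_richness(counts) -> int:
    return int((np.asarray(counts) > 0).sum())


def diversity_table(cm) -> pd.DataFrame:
    """Per-sample Shannon (nats), Chao1 and observed richness."""
    rows = []
    for s in cm.sample_ids:
        c = cm.counts[s].to_numpy()
        rows.append(
            {
                "sample_id": s,
                "shannon": shannon(c),
                "chao1": chao1(c),
                "observed": observed_richness(c),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected richness at each subsampling depth (analytic hypergeometric).

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] for total N and taxon
    counts N_i; computed with log-gamma for numerical stability.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    N = int(c.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if np.any(depths > N):
        raise ValueError("depth exceeds total count")
    if np.any(depths < 0):
        raise ValueError("negative depth")

    def _log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(len(depths), dtype=float)
    for k, n in enumerate(depths):
        if n == 0:
            out[k] = 0.0
            continue
        keep = (N - c) >= n
        miss = np.zeros(len(c))
        miss[keep] = np.exp(_log_choose(N - c[keep], n) - _log_choose(N, n))
        out[k] = float((1.0 - miss).sum())
    return out


# ---------------------------------------------------------------------------
# ordination


def hellinger_transform(cm) -> pd.DataFrame:
    """Square-root of within-sample relative abundances, samples as rows.

    Euclidean distance between transformed rows equals the Hellinger
    distance between samples.
    """
    counts = cm.counts if hasattr(cm, "counts") else pd.DataFrame(cm)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total sample")
    return np.sqrt(counts / totals).T


@dataclass
class OrdinationResult:
    site_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    eigenvalues: np.ndarray
    constrained_variance_fraction: float
    terms: pd.DataFrame = field(default_factory=pd.DataFrame)
    rm: float = float("nan")


def _centered_design(X: pd.DataFrame):
    """Centered constraint matrix with collinear columns dropped."""
    Xc = X - X.mean(axis=0)
    mat = Xc.to_numpy(dtype=float)
    q = np.linalg.matrix_rank(mat)
    if q < mat.shape[1]:
        keep, cols = [], []
        for j, name in enumerate(Xc.columns):
            trial = cols + [mat[:, j]]
            if np.linalg.matrix_rank(np.column_stack(trial)) == len(trial):
                keep.append(name)
                cols.append(mat[:, j])
        dropped = [c for c in Xc.columns if c not in keep]
        warnings.warn(f"rank-deficient constraints; dropped {dropped}", stacklevel=3)
        Xc = Xc[keep]
    return Xc


def rda(Y: pd.DataFrame, X: pd.DataFrame) -> OrdinationResult:
    """Redundancy analysis of response matrix Y constrained on X.

    Y (samples x taxa, typically Hellinger-transformed) is centered and
    regressed on the centered constraints; the fitted values are
    eigen-decomposed to give the constrained axes.  The constrained
    variance fraction is the fitted sum of squares over the total sum of
    squares.
    """
    Y = pd.DataFrame(Y)
    X = pd.DataFrame(X)
    if len(Y) != len(X):
        raise ValueError("Y and X must have the same samples")
    n = len(Y)
    if n <= X.shape[1] + 1:
        raise ValueError("need n samples > n variables + 1")
    Yc = (Y - Y.mean(axis=0)).to_numpy(dtype=float)
    Xc = _centered_design(X)
    Xm = Xc.to_numpy(dtype=float)
    B, *_ = np.linalg.lstsq(Xm, Yc, rcond=None)
    Yfit = Xm @ B
    ss_tot = float((Yc**2).sum())
    ss_fit = float((Yfit**2).sum())
    U, S, Vt = np.linalg.svd(Yfit, full_matrices=False)
    n_axes = min(Xm.shape[1], int((S > 1e-10 * max(S[0], 1e-300)).sum()))
    n_axes = max(n_axes, 1)
    axes = [f"RDA{i + 1}" for i in range(n_axes)]
    site_scores = pd.DataFrame(U[:, :n_axes] * S[:n_axes], index=Y.index, columns=axes)
    # biplot scores: correlations of constraints with the site scores
    var_scores = pd.DataFrame(index=Xc.columns, columns=axes, dtype=float)
    for ax in axes:
        sc = site_scores[ax].to_numpy()
        for v in Xc.columns:
            x = Xc[v].to_numpy()
            denom = x.std() * sc.std()
            var_scores.loc[v, ax] = float(np.cov(x, sc, bias=True)[0, 1] / denom) if denom > 0 else 0.0
    return OrdinationResult(
        site_scores=site_scores,
        variable_scores=var_scores,
        eigenvalues=(S[:n_axes] ** 2) / (n - 1),
        constrained_variance_fraction=ss_fit / ss_tot if ss_tot > 0 else 0.0,
    )


def _residual_projector(Xm: np.ndarray) -> np.ndarray:
    """I - H for a centered design matrix (via thin QR)."""
    n = Xm.shape[0]
    if Xm.size == 0:
        return np.eye(n)
    Q, _ = np.linalg.qr(Xm)
    return np.eye(n) - Q @ Q.T


def permutation_anova(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    term: str,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Marginal ANOVA-like permutation test for one constraint of an RDA.

    F = (SS_term / 1) / (SS_residual / (n - q - 1)) with q constraints;
    significance is assessed by permuting the residuals of the reduced
    model (the model without ``term``):
    p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = pd.DataFrame(Y)
    X = pd.DataFrame(X)
    if term not in X.columns:
        raise KeyError(f"term {term!r} not among constraints")
    rng = np.random.default_rng(seed)
    n = len(Y)
    Yc = (Y - Y.mean(axis=0)).to_numpy(dtype=float)
    Xc = _centered_design(X)
    q = Xc.shape[1]
    Xfull = Xc.to_numpy(dtype=float)
    Xred = Xc.drop(columns=[term]).to_numpy(dtype=float) if term in Xc.columns else Xfull
    A_full = _residual_projector(Xfull)
    A_red = _residual_projector(Xred)
    df_res = n - q - 1

    ss_res_full = float(((A_full @ Yc) ** 2).sum())
    ss_res_red = float(((A_red @ Yc) ** 2).sum())
    ss_term = ss_res_red - ss_res_full
    f_obs = (ss_term / 1.0) / (ss_res_full / df_res)

    # reduced-model residual permutation: Y* = fit_red + R_red[perm]; since
    # the reduced columns lie in the full column space, A_full fit_red = 0
    # and both sums of squares depend only on the permuted residuals.
    R_red = A_red @ Yc
    count = 0
    for _ in range(n_perm):
        Rp = R_red[rng.permutation(n)]
        ss_full_p = float(((A_full @ Rp) ** 2).sum())
        ss_red_p = float(((A_red @ Rp) ** 2).sum())
        f_p = ((ss_red_p - ss_full_p) / 1.0) / (ss_full_p / df_res)
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return float(f_obs), float(p)


def mantel_rm(hell_dist, biplot_dist) -> float:
    """Pearson correlation between two condensed distance vectors.

    Used to report how faithfully the first constrained axes of the RDA
    biplot preserve the Hellinger distances among samples.
    """
    a = np.asarray(hell_dist, dtype=float)
    b = np.asarray(biplot_dist, dtype=float)
    if a.shape != b.shape:
        raise ValueError("distance vectors must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 samples (3 pairwise distances)")
    return float(stats.pearsonr(a, b)[0])


def rda_with_tests(
    Y: pd.DataFrame,
    X: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> OrdinationResult:
    """RDA plus marginal permutation tests for every constraint and the
    Mantel correlation between Hellinger and 2-axis biplot distances."""
    res = rda(Y, X)
    rows = []
    for j, term in enumerate(pd.DataFrame(X).columns):
        f, p = permutation_anova(Y, X, term, n_perm=n_perm, seed=seed + j)
        rows.append({"term": term, "F": f, "p": p})
    res.terms = pd.DataFrame(rows)
    k = min(2, res.site_scores.shape[1])
    hd = pdist(pd.DataFrame(Y).to_numpy(dtype=float))
    bd = pdist(res.site_scores.to_numpy()[:, :k])
    res.rm = mantel_rm(hd, bd)
    return res


# ---------------------------------------------------------------------------
# co-occurrence


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True where p < alpha (off-diagonal, defined)


def correlation_matrix(profiles: pd.DataFrame, alpha: float = 0.05) -> CorrelationMatrix:
    """Pairwise Pearson correlations between abundance profiles.

    ``profiles`` has one row per feature (e.g., phylogenetic bin) and one
    column per sample.  p-values are two-sided t-tests; entries with
    p < ``alpha`` are flagged in ``mask``.  Zero-variance profiles yield
    undefined correlations, reported as NaN and masked out.
    """
    profiles = pd.DataFrame(profiles)
    n = profiles.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance profiles; correlations undefined",
            stacklevel=2,
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.outer(sd, sd) * n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ Xc.T) / denom
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, np.where(degenerate, np.nan, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[np.isnan(r)] = np.nan
    np.fill_diagonal(p, np.nan)
    idx = profiles.index
    rdf = pd.DataFrame(r, index=idx, columns=idx)
    pdf = pd.DataFrame(p, index=idx, columns=idx)
    mask = (pdf < alpha).fillna(False)
    return CorrelationMatrix(r=rdf, p=pdf, mask=mask)
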