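"""Synthetic multi-site time-series communities with known assembly processes.

The generator emulates the sampling design of an Antarctic snow-algae
bloom survey: four sites sampled on twelve dates, sparse count communities
of amplicon taxa over a phylogeny, with phylogenetically conserved
environmental optima.  Each scenario assembles communities under one
dominant ecological process:

homogeneous_selection
    Every site shares one environmental value; taxon sampling
    probabilities follow a Gaussian niche filter around phylogenetically
    conserved trait optima, so all communities converge on the same
    clades.
heterogeneous_selection
    Sites have distinct environmental values far apart relative to the
    niche width, selecting different clades at different sites.
dispersal_limitation
    Sites are founded by disjoint taxon subsets and evolve by zero-sum
    Wright-Fisher drift with no migration, so between-site turnover
    exceeds random reassembly.
homogenizing_dispersal
    Full migration (m = 1): every generation each site is resampled from
    the pooled metacommunity, keeping sites far more similar than random
    reassembly while the pool itself drifts through time.
drift
    Sites are founded by independent weighted-random subsets of the
    regional pool (random assembly, the null's own notion of chance) and
    drift without migration; neither index should be extreme.
mixture
    Taxon sampling probabilities mix the homogeneous niche filter with
    the neutral regional pool at configurable weights.

Simulated metadata carries site, date, snow colour, chlorophyll a and
nutrient covariates; nutrient concentrations are drawn from lognormal
distributions whose mean/sd match field measurements of green and red
blooms (NH4 3.7/3.9, NO3 1.0/1.0, PO4 4.3/3.6 mg/L for green;
5.4/8.5, 0.5/0.5, 6.2/6.6 for red).  For selection scenarios DOC is
linearly coupled to the site environment so that a constrained
ordination has one truly active covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from snowassembly.community_data import CommunityMatrix, write_counts

SCENARIOS = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "mixture",
)

# lognormal (mean, sd) in mg/L per nutrient for green-stage and red-stage snow
_NUTRIENTS_GREEN = {"nh4": (3.7, 3.9), "no3": (1.0, 1.0), "po4": (4.3, 3.6)}
_NUTRIENTS_RED = {"nh4": (5.4, 8.5), "no3": (0.5, 0.5), "po4": (6.2, 6.6)}


@dataclass
class ScenarioConfig:
    scenario: str = "drift"
    n_taxa: int = 60
    n_sites: int = 4
    n_dates: int = 12
    J: int = 2000  # local community size (individuals per sample)
    sigma_w: float = 0.2  # niche width, trait units (traits standardized)
    sigma_bm: float = 1.0  # Brownian-motion rate for trait evolution
    m: float | None = None  # migration probability; scenario default if None
    T: int | None = None  # generations between sampling dates
    richness: int | None = None  # founder subset size for neutral scenarios
    pool_sigma: float = 1.0  # lognormal spread of regional abundances
    mixture_weights: dict = field(
        default_factory=lambda: {"selection": 0.5, "drift": 0.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.J < 10:
            raise ValueError("J must be >= 10")
        if self.n_dates < 2:
            raise ValueError("n_dates must be >= 2")
        if self.m is not None and not (0.0 <= self.m <= 1.0):
            raise ValueError("m must lie in [0, 1]")


@dataclass
class SyntheticDataset:
    cm: CommunityMatrix
    tree: TreeNode
    meta: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# tree and traits


def _yule(n_tips: int, rng, height: float) -> TreeNode:
    """Pure-birth tree with ``n_tips`` tips, every tip at depth ``height``
    below the root node (the root splits at time zero)."""
    root = TreeNode()
    if n_tips == 1:
        root.length = height
        return root
    birth = {}
    active = []
    for _ in range(2):
        child = TreeNode(parent=root)
        root.children.append(child)
        birth[id(child)] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)]
        for _ in range(2):
            child = TreeNode(parent=node)
            node.children.append(child)
            birth[id(child)] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth[id(node)]
    scale = height / t_end
    for node in root.traverse(include_self=False):
        node.length *= scale
    return root


def simulate_tree(
    n_taxa: int,
    seed: int = 0,
    height: float = 1.0,
    bush_size: int = 10,
    bush_height: float = 0.1,
    backbone_height: float = 0.5,
) -> TreeNode:
    """Random two-level pure-birth tree: deep clades carrying tight bushes.

    A pure-birth backbone of ``ceil(n_taxa / bush_size)`` lineages spans
    the first ``backbone_height`` of the tree; each backbone lineage then
    runs down a bare stem and radiates into a tight pure-birth bush
    occupying the last ``bush_height``.  The result is ultrametric (all
    tips at distance ``height`` from the root) and mirrors the shape of
    amplicon phylogenies, where sequence variants form tight clusters
    inside deeply separated clades: tip pairs within a bush are at most
    ``2 * bush_height`` apart while tips of different bushes are at least
    ``2 * (height - backbone_height)`` apart, so distance-threshold
    binning has an unambiguous scale to cut at.  Reproducible: the same
    seed yields an identical Newick string.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if not 0 < bush_height < height or not 0 < backbone_height < height - bush_height:
        raise ValueError("need 0 < bush_height and backbone_height with room for stems")
    rng = np.random.default_rng([seed, 11])
    n_bushes = max(2, int(np.ceil(n_taxa / bush_size)))
    n_bushes = min(n_bushes, n_taxa)
    sizes = np.full(n_bushes, n_taxa // n_bushes)
    sizes[: n_taxa % n_bushes] += 1
    root = _yule(n_bushes, rng, backbone_height)
    stem = height - backbone_height - bush_height
    for backbone_tip, size in zip(list(root.tips() if n_bushes > 1 else [root]), sizes):
        bush = _yule(int(size), rng, bush_height)
        if bush.is_tip():
            # single-taxon bush: extend the stem all the way to the present
            backbone_tip.length += stem + bush_height
        else:
            backbone_tip.length += stem
            for child in bush.children:
                child.parent = backbone_tip
                backbone_tip.children.append(child)
    width = len(str(n_taxa))
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:0{width}d}"
    root.length = None
    return root


def simulate_traits(tree: TreeNode, sigma_bm: float = 1.0, seed: int = 0) -> dict:
    """Brownian-motion trait evolution along the tree; returns tip -> optimum.

    Trait covariance between two tips equals sigma_bm^2 times their shared
    root-to-ancestor path length, so closer relatives have more similar
    environmental optima.
    """
    rng = np.random.default_rng([seed, 23])
    values = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        step = rng.standard_normal() * sigma_bm * np.sqrt(node.length)
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = float(values[id(node)])
    return out


# ---------------------------------------------------------------------------
# assembly processes


def selection_probabilities(
    traits: np.ndarray,
    env: float,
    sigma_w: float,
    background: float = 0.05,
    sigma_bg: float = 1.0,
) -> np.ndarray:
    """Gaussian niche filter: p_i proportional to exp(-(trait_i - env)^2 / (2 sigma_w^2)).

    A ``background`` fraction of each community follows the same filter at
    the broad niche width ``sigma_bg``: the everything-is-everywhere rare
    biosphere, still mildly ordered by the environment.  It keeps every
    clade represented at trace abundance, as in real amplicon surveys.
    """
    if not sigma_w > 0:
        raise ValueError("sigma_w must be > 0")

    def _filter(width):
        if np.isinf(width):
            w = np.ones_like(traits, dtype=float)
        else:
            w = np.exp(-((traits - env) ** 2) / (2.0 * width**2))
        return w / w.sum()

    core = _filter(sigma_w)
    if background <= 0:
        return core
    return (1.0 - background) * core + background * _filter(sigma_bg)


def simulate_selection(
    taxa: list,
    traits: dict,
    env_per_sample: dict,
    J: int,
    sigma_w: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Niche-filtered multinomial communities, one column per sample."""
    rng = np.random.default_rng([seed, 37])
    tr = np.array([traits[t] for t in taxa], dtype=float)
    cols = {}
    for s, env in env_per_sample.items():
        p = selection_probabilities(tr, env, sigma_w)
        cols[s] = rng.multinomial(J, p)
    return pd.DataFrame(cols, index=taxa)


def simulate_neutral(
    founders: dict,
    J: int,
    m: float,
    T: int,
    n_dates: int,
    seed: int = 0,
) -> dict:
    """Zero-sum Wright-Fisher metacommunity dynamics.

    ``founders`` maps site -> integer count vector summing to J.  Each
    generation every site is replaced by J multinomial draws from
    (1 - m) * own frequencies + m * pooled metacommunity frequencies.
    Snapshots are taken every ``T`` generations starting at the founders;
    returns {(site, date_index): count vector} with date_index 0-based.
    """
    rng = np.random.default_rng([seed, 53])
    sites = sorted(founders)
    state = {s: np.asarray(founders[s], dtype=np.int64).copy() for s in sites}
    for s in sites:
        if state[s].sum() != J:
            raise ValueError(f"founder counts for site {s} do not sum to J")
    out = {}
    for d in range(n_dates):
        if d > 0:
            for _ in range(T):
                pool = np.mean([state[s] / J for s in sites], axis=0)
                new = {}
                for s in sites:
                    p = (1.0 - m) * (state[s] / J) + m * pool
                    new[s] = rng.multinomial(J, p)
                state = new
        for s in sites:
            out[(s, d)] = state[s].copy()
    return out


def _weighted_subset(rng, weights: np.ndarray, size: int) -> np.ndarray:
    """Indices of a weighted sample without replacement (Gumbel top-k)."""
    keys = np.log(np.clip(weights, 1e-300, None)) + rng.gumbel(size=len(weights))
    return np.sort(np.argpartition(-keys, size - 1)[:size])


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _snow_color(site: int, d: int, n_dates: int) -> str:
    f = d / max(n_dates - 1, 1)
    if f < 0.25:
        return "white"
    if f < 0.5:
        return "light-green"
    if f >= 0.75 and site % 2 == 1:
        return "red"
    return "green"


def _simulate_metadata(cfg: ScenarioConfig, sample_index: list, site_env: dict, rng) -> pd.DataFrame:
    start = pd.Timestamp("2019-11-25")
    rows = []
    for site, d, sample_id in sample_index:
        color = _snow_color(site, d, cfg.n_dates)
        pars = _NUTRIENTS_RED if color == "red" else _NUTRIENTS_GREEN
        row = {"sample_id": sample_id, "site": site, "date": (start + pd.Timedelta(days=3 * d)).date().isoformat(), "snow_color": color}
        for nut, (mean, sd) in pars.items():
            mu, sig = _lognormal_params(mean, sd)
            row[nut] = float(rng.lognormal(mu, sig))
        env = site_env.get(site, 0.0)
        if site_env:
            doc = 8.0 + 2.0 * env + rng.normal(0.0, 1.0)
        else:
            doc = float(rng.lognormal(*_lognormal_params(8.0, 4.0)))
        row["doc"] = float(np.clip(doc, 0.0, 20.0))
        # chlorophyll a rises as the bloom develops (2 -> ~900 ug/L)
        f = d / max(cfg.n_dates - 1, 1)
        row["chla"] = float(rng.lognormal(np.log(2.4) + f * (np.log(870.0) - np.log(2.4)), 0.6))
        rows.append(row)
    meta = pd.DataFrame(rows)
    meta["date"] = pd.to_datetime(meta["date"])
    return meta.set_index("sample_id", drop=False)


def build_dataset(cfg: ScenarioConfig) -> SyntheticDataset:
    """Wire tree, traits, scenario generator and metadata into one dataset."""
    tree = simulate_tree(cfg.n_taxa, seed=cfg.seed)
    taxa = [t.name for t in tree.tips()]
    traits_raw = simulate_traits(tree, cfg.sigma_bm, seed=cfg.seed)
    vals = np.array([traits_raw[t] for t in taxa])
    sd = vals.std()
    traits = {t: float((traits_raw[t] - vals.mean()) / (sd if sd > 0 else 1.0)) for t in taxa}

    sites = list(range(1, cfg.n_sites + 1))
    sample_index = [
        (site, d, f"S{site}D{d + 1:02d}") for d in range(cfg.n_dates) for site in sites
    ]
    rng = np.random.default_rng([cfg.seed, 71])

    site_env: dict = {}
    truth: dict = {"scenario": cfg.scenario, "params": asdict(cfg)}

    trait_vals = np.array([traits[t] for t in taxa])
    # selection environments sit in the tails of the trait distribution:
    # under Brownian evolution extreme trait values are clade-concentrated,
    # whereas middle values occur convergently across the whole tree
    env_low = float(np.quantile(trait_vals, 0.10))
    env_high = float(np.quantile(trait_vals, 0.90))
    if cfg.scenario in ("homogeneous_selection", "heterogeneous_selection", "mixture"):
        if cfg.scenario == "heterogeneous_selection":
            site_env = {s: (env_low if s % 2 == 1 else env_high) for s in sites}
        else:
            site_env = {s: env_high for s in sites}
        env_per_sample = {sid: site_env[site] for site, d, sid in sample_index}
        if cfg.scenario == "mixture":
            tr = np.array([traits[t] for t in taxa])
            pool = rng.lognormal(0.0, cfg.pool_sigma, cfg.n_taxa)
            pool /= pool.sum()
            w = cfg.mixture_weights
            wt = w["selection"] + w["drift"]
            cols = {}
            for site, d, sid in sample_index:
                p = (
                    w["selection"] * selection_probabilities(tr, env_per_sample[sid], cfg.sigma_w)
                    + w["drift"] * pool
                ) / wt
                cols[sid] = rng.multinomial(cfg.J, p)
            counts = pd.DataFrame(cols, index=taxa)
            truth["component_weights"] = {k: v / wt for k, v in w.items()}
        else:
            counts = simulate_selection(taxa, traits, env_per_sample, cfg.J, cfg.sigma_w, seed=cfg.seed)
        truth["site_env"] = {str(s): site_env[s] for s in sites}
    else:
        pool = rng.lognormal(0.0, cfg.pool_sigma, cfg.n_taxa)
        pool /= pool.sum()
        richness = cfg.richness or cfg.n_taxa // 2
        founders = {}
        if cfg.scenario == "dispersal_limitation":
            # short inter-date drift keeps the cross-site trickle of shared
            # taxa alive, so observed dissimilarity stays strictly below 1
            # and the Raup-Crick null retains resolution
            m, T = (cfg.m if cfg.m is not None else 0.0), (cfg.T if cfg.T is not None else 5)
            # each site is dominated (90% of individuals) by its own block of
            # taxa but retains a trickle of the rest, so between-site turnover
            # is high while per-sample richness stays comparable to the null's
            perm = rng.permutation(cfg.n_taxa)
            block = cfg.n_taxa // cfg.n_sites
            for i, s in enumerate(sites):
                idx = perm[i * block : (i + 1) * block]
                own = np.zeros(cfg.n_taxa)
                own[idx] = pool[idx]
                p = 0.9 * own / own.sum() + 0.1 * pool
                founders[s] = rng.multinomial(cfg.J, p)
        elif cfg.scenario == "homogenizing_dispersal":
            m, T = (cfg.m if cfg.m is not None else 1.0), (cfg.T if cfg.T is not None else 100)
            for s in sites:
                founders[s] = rng.multinomial(cfg.J, pool)
        else:  # drift
            m, T = (cfg.m if cfg.m is not None else 0.0), (cfg.T if cfg.T is not None else 30)
            for s in sites:
                idx = _weighted_subset(rng, pool, richness)
                p = np.zeros(cfg.n_taxa)
                p[idx] = pool[idx]
                founders[s] = rng.multinomial(cfg.J, p / p.sum())
        series = simulate_neutral(founders, cfg.J, m, T, cfg.n_dates, seed=cfg.seed)
        counts = pd.DataFrame(
            {sid: series[(site, d)] for site, d, sid in sample_index}, index=taxa
        )
        truth["m"], truth["T"] = float(m), int(T)

    meta = _simulate_metadata(cfg, sample_index, site_env, rng)
    truth["traits"] = traits
    return SyntheticDataset(cm=CommunityMatrix(counts), tree=tree, meta=meta, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write counts.tsv, tree.nwk, metadata.csv and truth.json; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    write_counts(ds.cm, paths["counts"])
    ds.tree.write(str(paths["tree"]), format="newick")
    meta = ds.meta.copy()
    meta["date"] = meta["date"].dt.date.astype(str)
    meta.to_csv(paths["metadata"], index=False)
    truth = dict(ds.truth)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return paths
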