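"""Alpha diversity, distance matrices, ordination and permutation tests.

Alpha metrics follow the QIIME-1 conventions of the upstream tool family:
observed species, bias-corrected Chao1 (``S + F1(F1-1)/(2(F2+1))``), Shannon
in bits (log base 2 by default), and Faith's phylogenetic diversity. Distances
are Bray-Curtis on relative abundances and binary Jaccard. PERMANOVA supports
one- and two-factor crossed designs with interaction (distance-based
sum-of-squares partition, free raw-data permutation); ANOSIM and the Mantel
test use explicit seeds so every p-value is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.diversity import alpha as skbio_alpha
from sklearn.manifold import MDS

from .data import OtuTable
from .synthetic import child_rng

__all__ = [
    "ALPHA_METRICS",
    "PermTestResult",
    "alpha_diversity",
    "distance_matrix",
    "nmds",
    "permanova",
    "anosim",
    "mantel",
]

ALPHA_METRICS = ("observed_species", "chao1", "shannon", "faith_pd")


@dataclass
class PermTestResult:
    """Outcome of one permutation test."""

    name: str
    statistic: float
    p_value: float
    n_perm: int
    seed: int

    def __post_init__(self):
        lo = 1.0 / (self.n_perm + 1)
        if not (np.isnan(self.p_value) or lo - 1e-12 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [{lo}, 1]")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: OtuTable, metric: str, tree=None, log_base: float = 2.0,
                    ) -> pd.Series:
    """Per-sample alpha diversity.

    ``faith_pd`` requires a tree covering every observed OTU; its value is the
    total branch length of the minimal subtree spanning the root and the
    sample's observed tips.
    """
    if metric not in ALPHA_METRICS:
        raise ValueError(f"unknown alpha metric {metric!r}; expected one of {ALPHA_METRICS}")
    counts = table.counts
    if metric == "observed_species":
        values = (counts > 0).sum(axis=1).astype(float)
    elif metric == "chao1":
        values = counts.apply(
            lambda row: skbio_alpha.chao1(row.to_numpy(), bias_corrected=True), axis=1
        )
    elif metric == "shannon":
        values = counts.apply(
            lambda row: skbio_alpha.shannon(row.to_numpy(), base=log_base), axis=1
        )
    else:  # faith_pd
        if tree is None:
            raise ValueError("faith_pd requires a phylogenetic tree")
        otu_ids = list(counts.columns)
        values = counts.apply(
            lambda row: skbio_alpha.faith_pd(row.to_numpy(), otu_ids, tree), axis=1
        )
    values.name = metric
    return values.astype(float)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def distance_matrix(table: OtuTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise sample distances.

    ``bray_curtis`` is computed on relative abundances
    (``sum|p-q| / sum(p+q)``); ``jaccard`` on presence/absence
    (``1 - |A&B| / |A|B|``).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    if metric == "bray_curtis":
        props = table.to_relative_abundance().proportions.to_numpy()
        condensed = pdist(props, metric="braycurtis")
    elif metric == "jaccard":
        presence = (table.counts.to_numpy() > 0)
        condensed = pdist(presence, metric="jaccard")
    else:
        raise ValueError(f"unknown distance metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def nmds(dm: DistanceMatrix, k: int = 2, seed: int = 0, n_restarts: int = 8,
         max_iter: int = 500) -> tuple[pd.DataFrame, float]:
    """Non-metric multidimensional scaling (Kruskal stress-1, best of restarts)."""
    n = dm.shape[0]
    if n < k + 2:
        raise ValueError(f"NMDS in {k} dimensions needs at least {k + 2} samples")
    d = np.asarray(dm.data, dtype=float)
    if np.allclose(d, 0):
        raise ValueError("degenerate distance matrix (all zeros)")
    seeds = np.random.SeedSequence(entropy=int(seed), spawn_key=(0x6E6D6473,)).spawn(n_restarts)
    best_stress, best_coords = np.inf, None
    for ss in seeds:
        rs = int(ss.generate_state(1)[0] % (2**31))
        model = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",
            max_iter=max_iter,
            eps=1e-9,
            random_state=rs,
            normalized_stress=True,
        )
        coords = model.fit_transform(d)
        if model.stress_ < best_stress:
            best_stress, best_coords = float(model.stress_), coords
    frame = pd.DataFrame(
        best_coords, index=list(dm.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return frame, best_stress


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    return a - a.mean(axis=0) - a.mean(axis=1, keepdims=True) + a.mean()


def _dummy(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values.astype(str)).to_numpy(dtype=float)


def _projection(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection matrix onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def permanova(dm: DistanceMatrix, metadata: pd.DataFrame, factors: list[str] | str,
              n_perm: int = 999, seed: int = 0) -> dict[str, PermTestResult]:
    """Distance-based multivariate ANOVA (pseudo-F, free raw-data permutation).

    One factor gives the classic one-way partition; two factors give a crossed
    design with sequential (type-I) sums of squares for the two main effects
    and their interaction. Permutations shuffle whole samples, so all terms
    share one permutation scheme (documented limitation for interactions).
    """
    if isinstance(factors, str):
        factors = [factors]
    if not 1 <= len(factors) <= 2:
        raise ValueError("permanova supports one or two factors")
    meta = metadata.loc[list(dm.ids)]
    for f in factors:
        counts = meta[f].value_counts()
        if (counts < 2).any():
            raise ValueError(f"factor {f!r} has levels with fewer than 2 samples")
    n = dm.shape[0]
    d = np.asarray(dm.data, dtype=float)
    g = _gower_center(d)
    ss_total = np.trace(g)

    ones = np.ones((n, 1))
    blocks = [ones]
    term_names = list(factors)
    for f in factors:
        blocks.append(_dummy(meta[f]))
    if len(factors) == 2:
        a, b = _dummy(meta[factors[0]]), _dummy(meta[factors[1]])
        inter = np.einsum("ij,ik->ijk", a, b).reshape(n, -1)
        blocks.append(inter)
        term_names.append(f"{factors[0]}:{factors[1]}")

    # sequential projections: H_0 (mean), then adding each term
    projections, ranks = [], []
    x = np.empty((n, 0))
    for block in blocks:
        x = np.hstack([x, block])
        h, r = _projection(x)
        projections.append(h)
        ranks.append(r)
    h_full, rank_full = projections[-1], ranks[-1]
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (saturated design)")

    term_dfs = [ranks[i + 1] - ranks[i] for i in range(len(term_names))]
    hat_diffs = [projections[i + 1] - projections[i] for i in range(len(term_names))]
    resid_hat = np.eye(n) - h_full

    def all_f(gm: np.ndarray) -> np.ndarray:
        ss_res = float(np.sum(resid_hat * gm.T))
        stats = []
        for hd, df in zip(hat_diffs, term_dfs):
            ss = float(np.sum(hd * gm.T))
            stats.append((ss / df) / (ss_res / df_res))
        return np.array(stats)

    f_obs = all_f(g)
    rng = child_rng(seed, "permanova")
    exceed = np.zeros(len(term_names))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        exceed += all_f(g[np.ix_(perm, perm)]) >= f_obs - 1e-12
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    return {
        name: PermTestResult(name=name, statistic=float(f), p_value=float(p),
                             n_perm=n_perm, seed=seed)
        for name, f, p in zip(term_names, f_obs, pvals)
    }


def anosim(dm: DistanceMatrix, grouping, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """Analysis of similarities: R = (mean between rank - mean within rank) / (n(n-1)/4)."""
    groups = np.asarray(
        grouping.loc[list(dm.ids)] if isinstance(grouping, pd.Series) else grouping
    )
    levels, counts = np.unique(groups, return_counts=True)
    if len(levels) < 2 or (counts < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 samples each")
    n = dm.shape[0]
    d = squareform(np.asarray(dm.data, dtype=float), checks=False)
    ranks = rankdata(d)
    iu = np.triu_indices(n, k=1)

    def r_stat(g: np.ndarray) -> float:
        within = g[iu[0]] == g[iu[1]]
        denom = n * (n - 1) / 4.0
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(groups)
    rng = child_rng(seed, "anosim")
    exceed = sum(
        r_stat(groups[rng.permutation(n)]) >= r_obs - 1e-12 for _ in range(n_perm)
    )
    return PermTestResult(name="anosim", statistic=r_obs,
                          p_value=(1.0 + exceed) / (n_perm + 1.0),
                          n_perm=n_perm, seed=seed)


def mantel(dm1: DistanceMatrix, dm2: DistanceMatrix, n_perm: int = 999,
           seed: int = 0) -> PermTestResult:
    """Mantel test: Pearson correlation of off-diagonal distances, p by
    simultaneous row/column permutation of the second matrix."""
    if list(dm1.ids) != list(dm2.ids):
        if set(dm1.ids) != set(dm2.ids):
            raise ValueError("distance matrices cover different sample sets")
        dm2 = dm2.filter(dm1.ids)
    n = dm1.shape[0]
    a = np.asarray(dm1.data, dtype=float)
    b = np.asarray(dm2.data, dtype=float)
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    xc = x - x.mean()
    xn = np.sqrt((xc**2).sum())

    def corr(bm: np.ndarray) -> float:
        y = bm[iu]
        yc = y - y.mean()
        yn = np.sqrt((yc**2).sum())
        if xn == 0 or yn == 0:
            return np.nan
        return float((xc @ yc) / (xn * yn))

    r_obs = corr(b)
    rng = child_rng(seed, "mantel")
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if abs(corr(b[np.ix_(perm, perm)])) >= abs(r_obs) - 1e-12:
            exceed += 1
    return PermTestResult(name="mantel", statistic=r_obs,
                          p_value=(1.0 + exceed) / (n_perm + 1.0),
                          n_perm=n_perm, seed=seed)
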