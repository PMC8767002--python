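"""Co-occurrence network construction and analysis.

Pipeline: prevalence-filter and log-transform relative abundances, compute
pairwise Pearson correlations between OTUs, pick the correlation threshold by
the random-matrix-theory criterion (smallest cutoff at which the
nearest-neighbour eigenvalue spacing distribution of the thresholded matrix
follows the Poisson form ``exp(-s)`` rather than the Wigner-Dyson form of
correlated noise), then build the signed graph, split it into modules with
fast-greedy modularity maximization, and characterize topology, node roles
(Zi-Pi) and taxonomic composition against degree-preserving random baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .data import OtuTable
from .synthetic import child_rng

__all__ = [
    "NODE_ROLES",
    "EcoNetwork",
    "NetworkTopology",
    "prepare_abundance_matrix",
    "correlation_matrix",
    "rmt_threshold",
    "build_network",
    "detect_modules",
    "topology_indices",
    "random_network_baseline",
    "node_roles",
    "classify_role",
    "network_composition",
]

NODE_ROLES = ("peripheral", "module_hub", "connector", "network_hub")


# ---------------------------------------------------------------------------
# preparation and correlation
# ---------------------------------------------------------------------------

def prepare_abundance_matrix(table: OtuTable, min_prevalence: float = 0.5,
                             zero_fill_factor: float = 0.01) -> pd.DataFrame:
    """Prevalence-filter and log10-transform relative abundances.

    OTUs present in at least ``min_prevalence`` of samples are kept; zeros
    are filled with ``zero_fill_factor`` times the smallest nonzero relative
    abundance before the log transform.
    """
    props = table.to_relative_abundance().proportions
    prevalence = (props > 0).mean(axis=0)
    kept = props.loc[:, prevalence >= min_prevalence]
    if kept.shape[1] == 0:
        raise ValueError("no OTU survives the prevalence filter")
    arr = kept.to_numpy(dtype=float)
    nonzero_min = arr[arr > 0].min()
    arr = np.where(arr > 0, arr, zero_fill_factor * nonzero_min)
    return pd.DataFrame(np.log10(arr), index=kept.index, columns=kept.columns)


def correlation_matrix(prepared: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between OTU profiles (columns of the prepared matrix).

    Zero-variance OTUs have no defined correlation and are dropped with a
    warning.
    """
    if prepared.shape[0] < 3:
        raise ValueError("need at least 3 samples for correlations")
    variances = prepared.var(axis=0)
    flat = variances.index[variances == 0]
    if len(flat):
        warnings.warn(f"dropping {len(flat)} zero-variance OTUs", stacklevel=2)
        prepared = prepared.drop(columns=flat)
    corr = np.corrcoef(prepared.to_numpy().T)
    return pd.DataFrame(corr, index=prepared.columns, columns=prepared.columns)


# ---------------------------------------------------------------------------
# RMT threshold
# ---------------------------------------------------------------------------

def _spacing_poisson_pvalue(matrix: np.ndarray, n_bins: int = 20,
                            spacing_max: float = 3.0) -> float | None:
    """Chi-square goodness of fit of unfolded eigenvalue spacings to exp(-s).

    Spectral unfolding fits a cubic smoothing spline to the cumulative
    eigenvalue density; returns None when the spectrum is too small to test.
    """
    eigs = np.sort(np.linalg.eigvalsh(matrix))
    lam, counts = np.unique(np.round(eigs, 10), return_counts=True)
    cum = np.cumsum(counts).astype(float)
    if len(lam) < 20:
        return None
    with warnings.catch_warnings():
        # the smoothing target need not be met exactly for unfolding
        warnings.simplefilter("ignore")
        spline = UnivariateSpline(lam, cum, k=3, s=len(lam))
    unfolded = spline(lam)
    spacings = np.diff(unfolded)
    # duplicate eigenvalues contribute zero spacings
    zeros = np.concatenate([np.zeros(c - 1) for c in counts]) if (counts > 1).any() else []
    spacings = np.concatenate([spacings, zeros])
    spacings = spacings[np.isfinite(spacings)]
    spacings = np.clip(spacings, 0.0, None)
    mean = spacings.mean()
    if mean <= 0 or len(spacings) < 30:
        return None
    spacings = spacings / mean
    in_range = spacings[spacings <= spacing_max]
    if len(in_range) < 30:
        return None
    edges = np.linspace(0.0, spacing_max, n_bins + 1)
    observed, _ = np.histogram(in_range, bins=edges)
    cdf = 1.0 - np.exp(-edges)
    probs = np.diff(cdf) / cdf[-1]
    expected = len(in_range) * probs
    keep = expected >= 1.0
    if keep.sum() < 3:
        return None
    chi2 = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    dof = int(keep.sum()) - 1
    return float(stats.chi2.sf(chi2, dof))


def rmt_threshold(corr: pd.DataFrame, start: float = 0.30, stop: float = 0.90,
                  step: float = 0.01, p_threshold: float = 0.05,
                  consecutive: int = 3, min_nodes: int = 25) -> tuple[float, pd.DataFrame]:
    """Scan correlation cutoffs for the RMT transition to Poisson spacing.

    Returns the smallest cutoff whose Poisson goodness-of-fit p-value exceeds
    ``p_threshold`` and persists for ``consecutive`` steps, together with the
    per-threshold fit trace.
    """
    if not (0.0 < start < stop < 1.0):
        raise ValueError("scan range must lie within (0, 1)")
    arr = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, 0.0)
    thresholds = np.arange(start, stop + step / 2, step)
    trace = []
    pvals = []
    for t in thresholds:
        mask = np.abs(arr) >= t
        sub = np.where(mask, arr, 0.0)
        degree = mask.sum(axis=0)
        keep = degree > 0
        n_nodes = int(keep.sum())
        n_edges = int(mask[np.ix_(keep, keep)].sum() // 2)
        p = None
        if n_nodes >= min_nodes:
            p = _spacing_poisson_pvalue(sub[np.ix_(keep, keep)])
        trace.append({"threshold": float(t), "n_nodes": n_nodes, "n_edges": n_edges,
                      "poisson_p": np.nan if p is None else p})
        pvals.append(p)
    trace_df = pd.DataFrame(trace)
    ok = [p is not None and p > p_threshold for p in pvals]
    for i in range(len(ok) - consecutive + 1):
        if all(ok[i : i + consecutive]):
            return float(thresholds[i]), trace_df
    raise ValueError(
        "no threshold in the scan range achieves a stable Poisson spacing fit; "
        "widen the scan or check the correlation matrix"
    )


# ---------------------------------------------------------------------------
# graph construction and modules
# ---------------------------------------------------------------------------

@dataclass
class EcoNetwork:
    """Signed co-occurrence graph with an optional module partition."""

    graph: nx.Graph
    threshold: float
    modules: dict | None = None  # node -> module id
    modularity: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(corr: pd.DataFrame, st: float) -> EcoNetwork:
    """Edges between distinct OTUs with ``|corr| >= st``; sign from correlation.

    Isolated nodes are dropped; an empty edge set is an error.
    """
    if not 0.0 < st < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    arr = corr.to_numpy(dtype=float)
    ids = list(corr.index)
    g = nx.Graph()
    n = len(ids)
    iu, ju = np.nonzero(np.triu(np.abs(arr) >= st, k=1))
    for i, j in zip(iu, ju):
        r = float(arr[i, j])
        g.add_edge(ids[i], ids[j], weight=r, sign=1 if r > 0 else -1)
    if g.number_of_edges() == 0:
        raise ValueError("empty edge set at this threshold")
    return EcoNetwork(graph=g, threshold=float(st))


def detect_modules(net: EcoNetwork) -> tuple[dict, float]:
    """Fast-greedy modularity maximization on the unsigned skeleton.

    Modules are numbered by decreasing size; the result and the modularity M
    are stored on the network.
    """
    g = net.graph
    if g.number_of_nodes() < 2:
        raise ValueError("cannot partition a single-node network")
    communities = nx.community.greedy_modularity_communities(g, weight=None)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    modules = {node: i for i, comm in enumerate(communities) for node in comm}
    m = nx.community.modularity(g, communities, weight=None)
    net.modules = modules
    net.modularity = float(m)
    return modules, float(m)


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    avg_connectivity: float  # 2E / N
    avg_clustering: float
    avg_path_length: float  # over the largest connected component
    power_law_r2: float
    modularity: float
    n_modules: int
    largest_module_size: int
    extras: dict = field(default_factory=dict)


def power_law_fit_r2(degrees: list[int]) -> float:
    """R^2 of the log10(frequency) ~ log10(degree) regression (degrees >= 1)."""
    degs = np.asarray([d for d in degrees if d >= 1])
    values, freqs = np.unique(degs, return_counts=True)
    if len(values) < 2:
        return np.nan
    slope, intercept, r, *_ = stats.linregress(np.log10(values), np.log10(freqs))
    return float(r**2)


def topology_indices(net: EcoNetwork) -> NetworkTopology:
    """Node/edge counts, avgK, clustering, geodesics, power-law fit, modules."""
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if net.modules is None:
        detect_modules(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    largest_cc = max(nx.connected_components(g), key=len)
    apl = (
        nx.average_shortest_path_length(g.subgraph(largest_cc))
        if len(largest_cc) > 1
        else 0.0
    )
    module_sizes = pd.Series(net.modules).value_counts()
    return NetworkTopology(
        n_nodes=n,
        n_edges=e,
        avg_connectivity=2.0 * e / n,
        avg_clustering=float(nx.average_clustering(g)),
        avg_path_length=float(apl),
        power_law_r2=power_law_fit_r2([d for _, d in g.degree()]),
        modularity=float(net.modularity),
        n_modules=int(module_sizes.size),
        largest_module_size=int(module_sizes.max()),
    )


# ---------------------------------------------------------------------------
# random baselines (Maslov-Sneppen)
# ---------------------------------------------------------------------------

def _double_edge_swap(g: nx.Graph, rng: np.random.Generator, target_swaps: int,
                      max_tries: int) -> nx.Graph:
    """Degree-preserving rewiring; returns the graph unchanged if no swap is
    possible (e.g. a clique)."""
    h = g.copy()
    edges = list(h.edges())
    swaps = tries = 0
    while swaps < target_swaps and tries < max_tries:
        tries += 1
        i, j = rng.integers(len(edges)), rng.integers(len(edges))
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if len({a, b, c, d}) < 4:
            continue
        if h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, d)
        h.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        swaps += 1
    return h


def random_network_baseline(net: EcoNetwork, n_random: int = 100, seed: int = 0,
                            swaps_per_edge: int = 10) -> pd.DataFrame:
    """Topology indices over Maslov-Sneppen rewired replicates.

    Each replicate performs up to ``swaps_per_edge * E`` successful double
    edge swaps (degree sequence preserved exactly). Returns per-index mean,
    sd, and the z-score of the empirical value.
    """
    g = net.graph
    if g.number_of_edges() < 2:
        raise ValueError("graph too sparse to rewire")
    empirical = topology_indices(net)
    rng = child_rng(seed, "rewire")
    records = []
    for _ in range(n_random):
        h = _double_edge_swap(g, rng, swaps_per_edge * g.number_of_edges(),
                              max_tries=100 * g.number_of_edges())
        rnet = EcoNetwork(graph=h, threshold=net.threshold)
        t = topology_indices(rnet)
        records.append(
            {
                "avg_clustering": t.avg_clustering,
                "avg_path_length": t.avg_path_length,
                "modularity": t.modularity,
            }
        )
    frame = pd.DataFrame(records)
    emp = {
        "avg_clustering": empirical.avg_clustering,
        "avg_path_length": empirical.avg_path_length,
        "modularity": empirical.modularity,
    }
    out = pd.DataFrame(
        {
            "empirical": pd.Series(emp),
            "random_mean": frame.mean(),
            "random_sd": frame.std(ddof=1),
        }
    )
    out["z_score"] = (out["empirical"] - out["random_mean"]) / out["random_sd"].replace(0, np.nan)
    return out


# ---------------------------------------------------------------------------
# node roles (Zi-Pi)
# ---------------------------------------------------------------------------

def classify_role(zi: float, pi: float) -> str:
    """Role from within-module degree z (Zi) and among-module connectivity (Pi).

    Values exactly at a threshold fall to the peripheral side (the quoted
    rules are strict inequalities).
    """
    if zi > 2.5:
        return "network_hub" if pi > 0.6 else "module_hub"
    return "connector" if pi > 0.6 else "peripheral"


def node_roles(net: EcoNetwork) -> pd.DataFrame:
    """Zi, Pi and role per node.

    Zi is the z-score of the node's within-module degree relative to its
    module (0 when the module's degrees have zero spread); Pi is
    ``1 - sum_s (k_is / k_i)^2`` over modules s.
    """
    if net.modules is None:
        detect_modules(net)
    g, modules = net.graph, net.modules
    within = {}
    per_module_links: dict = {}
    for node in g:
        counts: dict = {}
        for nb in g[node]:
            counts[modules[nb]] = counts.get(modules[nb], 0) + 1
        per_module_links[node] = counts
        within[node] = counts.get(modules[node], 0)
    module_stats = {}
    for m in set(modules.values()):
        vals = np.array([within[n] for n in g if modules[n] == m], dtype=float)
        module_stats[m] = (vals.mean(), vals.std(ddof=0))
    rows = []
    for node in g:
        k = g.degree(node)
        mean, sd = module_stats[modules[node]]
        zi = 0.0 if sd == 0 else (within[node] - mean) / sd
        pi = 1.0 - sum((c / k) ** 2 for c in per_module_links[node].values())
        rows.append(
            {"node": node, "module": modules[node], "degree": k,
             "zi": zi, "pi": pi, "role": classify_role(zi, pi)}
        )
    return pd.DataFrame(rows).set_index("node")


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def network_composition(net: EcoNetwork, taxonomy: pd.DataFrame | None = None,
                        rank: str = "phylum") -> dict:
    """Node fractions per taxon, edge-sign tally, largest-module breakdown."""
    if net.modules is None:
        detect_modules(net)
    g = net.graph
    if taxonomy is not None:
        lineage = taxonomy[rank] if rank in taxonomy.columns else taxonomy.iloc[:, 0]
        labels = pd.Series(
            {n: lineage.get(n, "Unclassified") for n in g}, name=rank
        ).fillna("Unclassified")
    else:
        labels = pd.Series({n: "Unclassified" for n in g}, name=rank)
    fractions = labels.value_counts(normalize=True)
    signs = pd.Series([d["sign"] for _, _, d in g.edges(data=True)])
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    module_sizes = pd.Series(net.modules).value_counts()
    largest = module_sizes.idxmax()
    largest_nodes = [n for n, m in net.modules.items() if m == largest]
    largest_fracs = labels.loc[largest_nodes].value_counts(normalize=True)
    return {
        "node_fractions": fractions,
        "n_positive_edges": n_pos,
        "n_negative_edges": n_neg,
        "positive_fraction": n_pos / max(n_pos + n_neg, 1),
        "largest_module_fractions": largest_fracs,
    }
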