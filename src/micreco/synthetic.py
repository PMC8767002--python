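"""Synthetic communities with known assembly processes.

Generates ultrametric pure-birth phylogenies, long-tailed regional species
pools, Brownian habitat traits, and grouped OTU tables assembled under one of
five named ecological processes:

Samples are built by a colonization lottery: candidate taxa are weighted,
membership is drawn in proportion to each taxon's expected occupancy under a
finite number of colonization events (``colonists``), and individuals are
filled in proportion to the weights (flattened by the ``evenness`` exponent —
local interactions equalize realized abundances relative to the very skewed
regional pool). The five processes differ in how the weights are formed:

``homogeneous_selection``
    every sample in a group weighted by one shared Gaussian niche filter
    (``exp(-(niche - optimum)^2 / 2 trait_sigma^2)``, zeroed below the
    ``niche_cutoff`` fundamental-niche boundary). The niche value of a taxon
    is its Brownian trait as of a conserved ancestral depth (``niche_depth``),
    so the filter retains whole deep clades — the phylogenetically conserved
    habitat filtering the beta nearest-taxon index is built to detect;
``heterogeneous_selection``
    sample-specific optima spread across the niche quantiles, so turnover
    between samples crosses deep clades;
``neutral_drift``
    the unfiltered regional pool: random assembly with no selection or
    dispersal structure;
``dispersal_limitation``
    isolated populations drift apart in abundance: membership stays
    pool-driven (extinction is slow) while each sample's realized abundances
    are an independent low-concentration Dirichlet draw around the pool,
    so compositional turnover far exceeds random assembly;
``homogenizing_dispersal``
    one realized common community per group; each sample is that community
    with a small fraction of individuals exchanged against the pool
    (migration ~ 1 keeps samples nearly identical).

All generators take explicit seeds; a master seed fans out to stage-specific
streams through ``numpy.random.SeedSequence`` spawn keys, so adding one
generator never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data import OtuTable, TAXONOMY_RANKS

__all__ = [
    "PROCESS_LABELS",
    "MetacommunityModel",
    "AssemblyScenario",
    "StudyBundle",
    "child_rng",
    "simulate_tree",
    "brownian_traits",
    "make_metacommunity",
    "simulate_samples",
    "simulate_study",
    "clade_taxonomy",
    "simulate_growth_records",
]

PROCESS_LABELS = (
    "homogeneous_selection",
    "heterogeneous_selection",
    "neutral_drift",
    "dispersal_limitation",
    "homogenizing_dispersal",
)


def child_rng(seed: int, *key) -> np.random.Generator:
    """Independent generator for stage ``key`` derived from a master seed."""
    spawn_key = tuple(
        zlib.crc32(str(k).encode()) if not isinstance(k, (int, np.integer)) else int(k)
        for k in key
    )
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# phylogeny and traits
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int, height: float = 1.0) -> TreeNode:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` tips.

    Waiting times between splits are exponential with rate equal to the
    number of extant lineages; the tree is rescaled to total ``height``.
    Tips are labelled ``OTU_0001`` ... in birth order.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = child_rng(seed, "tree")
    root = TreeNode(name=None)
    # active tips with their birth times
    active: list[tuple[TreeNode, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, born = active.pop(i)
        node.length = t - born if node.parent is not None else None
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / n_tips)
    for node, born in active:
        node.length = t_end - born
    scale = height / t_end
    for node in root.traverse(include_self=False):
        node.length *= scale
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"OTU_{i:04d}"
    return root


def brownian_traits(tree: TreeNode, rate: float = 1.0, seed: int = 0,
                    niche_depth: float | None = None) -> pd.Series | tuple[pd.Series, pd.Series]:
    """Brownian-motion trait evolved along the tree (root value 0).

    With ``niche_depth`` set, also returns each tip's *niche value*: the
    trait of its lineage as of that depth from the root. Tips of a clade
    whose ancestor was extant at that depth share the niche value exactly —
    a phylogenetically conserved habitat preference.
    """
    rng = child_rng(seed, "traits")
    values: dict[int, float] = {id(tree): 0.0}
    depth: dict[int, float] = {id(tree): 0.0}
    anchor: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(rate * node.length)) if node.length > 0 else 0.0
        values[id(node)] = values[id(node.parent)] + step
        depth[id(node)] = depth[id(node.parent)] + node.length
        if niche_depth is not None:
            if depth[id(node.parent)] < niche_depth:
                # first lineage segment crossing the conserved depth fixes the niche
                anchor[id(node)] = (
                    values[id(node)] if depth[id(node)] >= niche_depth else 0.0
                )
            else:
                anchor[id(node)] = anchor[id(node.parent)]
    traits = pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})
    if niche_depth is None:
        return traits
    niches = pd.Series({tip.name: anchor[id(tip)] for tip in tree.tips()})
    return traits, niches


@dataclass
class MetacommunityModel:
    """Regional pool + phylogeny + habitat trait underlying all scenarios."""

    tree: TreeNode
    pool: pd.Series  # regional relative abundances, sum 1
    traits: pd.Series  # habitat trait per tip
    trait_sigma: float = 0.15  # Gaussian selection filter width
    niches: pd.Series | None = None  # conserved niche value per tip

    def __post_init__(self):
        if not np.all(self.pool.to_numpy() > 0):
            raise ValueError("pool abundances must be strictly positive")
        if not np.isclose(self.pool.sum(), 1.0):
            raise ValueError("pool abundances must sum to 1")
        missing = set(self.pool.index) - set(self.traits.index)
        if missing:
            raise ValueError(f"traits missing for taxa: {sorted(missing)[:5]}")
        if self.niches is None:
            self.niches = self.traits

    @property
    def taxa(self) -> list[str]:
        return list(self.pool.index)


def make_metacommunity(
    n_taxa: int,
    seed: int,
    pool_sigma: float = 2.0,
    trait_rate: float = 1.0,
    trait_sigma: float = 0.15,
    niche_depth: float = 0.6,
) -> MetacommunityModel:
    """Log-normal regional pool (``exp(N(0, pool_sigma^2))``, normalized) on a
    simulated Yule tree with a Brownian habitat trait.

    The niche value each selection filter acts on is the trait as of
    ``niche_depth`` from the root (fraction of tree height), so habitat
    preference is conserved within the deep clades extant at that time.
    """
    tree = simulate_tree(n_taxa, seed)
    rng = child_rng(seed, "pool")
    raw = rng.lognormal(mean=0.0, sigma=pool_sigma, size=n_taxa)
    taxa = [t.name for t in tree.tips()]
    pool = pd.Series(raw / raw.sum(), index=taxa)
    traits, niches = brownian_traits(tree, rate=trait_rate, seed=seed,
                                     niche_depth=niche_depth)
    return MetacommunityModel(tree=tree, pool=pool, traits=traits,
                              trait_sigma=trait_sigma, niches=niches)


# ---------------------------------------------------------------------------
# assembly scenarios
# ---------------------------------------------------------------------------

@dataclass
class AssemblyScenario:
    """Design of one simulated assembly experiment."""

    process: str
    n_groups: int = 1
    samples_per_group: int = 12
    depth: int = 20_000
    seed: int = 0
    # process-specific knobs (defaults are the study conditions)
    colonists: int = 300  # colonization events determining expected occupancy
    evenness: float = 0.3  # exponent flattening fill weights (1 = pool-proportional)
    niche_cutoff: float = 0.05  # fundamental-niche boundary on the Gaussian filter
    drift_concentration: float = 3.0  # Dirichlet mass of isolated-population drift
    dispersal_colonists: int = 1200  # established isolated populations keep more members
    migration: float = 0.9  # fraction of individuals retained from the common community

    def __post_init__(self):
        if self.process not in PROCESS_LABELS:
            raise ValueError(
                f"unknown process {self.process!r}; expected one of {PROCESS_LABELS}"
            )
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if not 0.0 <= self.migration <= 1.0:
            raise ValueError("migration must lie in [0, 1]")


def _selection_weights(model: MetacommunityModel, optimum: float,
                       niche_cutoff: float) -> np.ndarray:
    pool = model.pool.to_numpy()
    niches = model.niches.loc[model.pool.index].to_numpy()
    f = np.exp(-((niches - optimum) ** 2) / (2.0 * model.trait_sigma**2))
    clipped = np.where(f >= niche_cutoff, f, 0.0)
    if (clipped > 0).sum() >= 3:
        f = clipped
    w = pool * f
    if w.sum() <= 0:
        raise ValueError("selection filter removed the entire pool")
    return w


def _lottery_sample(weights: np.ndarray, scen: AssemblyScenario,
                    rng: np.random.Generator,
                    fill: np.ndarray | None = None,
                    colonists: int | None = None) -> np.ndarray:
    """Colonization lottery: membership ~ expected occupancy under a finite
    number of colonization events, fill ~ (flattened) weights."""
    depth = scen.depth
    w = weights / weights.sum()
    occupancy = 1.0 - (1.0 - w) ** (colonists or scen.colonists)
    nonzero = int((w > 0).sum())
    # keep some turnover even when every candidate is near-certain to colonize
    cap = max(3, int(np.floor(0.9 * nonzero)))
    richness = max(min(3, nonzero),
                   min(int(round(occupancy.sum())), depth, nonzero, cap))
    taxa = rng.choice(len(w), size=richness, replace=False,
                      p=occupancy / occupancy.sum())
    if fill is None:
        fw = w[taxa] ** scen.evenness
        fill = fw / fw.sum()
    else:
        fill = fill[taxa] + 1e-12
        fill = fill / fill.sum()
    out = np.zeros(len(w), dtype=np.int64)
    out[taxa] = 1 + rng.multinomial(depth - richness, fill)
    return out


def _group_counts(model: MetacommunityModel, scen: AssemblyScenario, group_idx: int,
                  rng: np.random.Generator) -> np.ndarray:
    n, depth = scen.samples_per_group, scen.depth
    pool = model.pool.to_numpy()
    niches = model.niches.to_numpy()
    out = np.zeros((n, len(pool)), dtype=np.int64)

    if scen.process == "homogeneous_selection":
        # the shared habitat matches the niche of one well-populated clade:
        # candidate optima are resident niche values whose filter admits at
        # least min_clade taxa, weighted by the clade's pool mass
        min_clade = min(30, len(pool) // 3)
        uniq = np.unique(niches)
        viable, masses = [], []
        for u in uniq:
            w_u = _selection_weights(model, u, scen.niche_cutoff)
            if (w_u > 0).sum() >= min_clade:
                viable.append(u)
                masses.append(pool[niches == u].sum())
        if not viable:
            counts_per = [(
                (_selection_weights(model, u, scen.niche_cutoff) > 0).sum(), u
            ) for u in uniq]
            viable, masses = [max(counts_per)[1]], [1.0]
        masses = np.asarray(masses)
        optimum = rng.choice(viable, p=masses / masses.sum())
        w = _selection_weights(model, optimum, scen.niche_cutoff)
        for s in range(n):
            out[s] = _lottery_sample(w, scen, rng)
    elif scen.process == "heterogeneous_selection":
        optima = rng.permutation(np.quantile(niches, (np.arange(n) + 0.5) / n))
        for s in range(n):
            w = _selection_weights(model, optima[s], scen.niche_cutoff)
            out[s] = _lottery_sample(w, scen, rng)
    elif scen.process == "neutral_drift":
        for s in range(n):
            out[s] = _lottery_sample(pool, scen, rng)
    elif scen.process == "dispersal_limitation":
        for s in range(n):
            drifted = rng.dirichlet(scen.drift_concentration * pool + 1e-9)
            out[s] = _lottery_sample(pool, scen, rng, fill=drifted,
                                     colonists=scen.dispersal_colonists)
    elif scen.process == "homogenizing_dispersal":
        base = rng.multinomial(depth, pool)
        n_exchange = int(round((1.0 - scen.migration) * depth))
        for s in range(n):
            if n_exchange == 0:
                out[s] = base
            else:
                removed = rng.multivariate_hypergeometric(base, n_exchange)
                immigrants = rng.multinomial(n_exchange, pool)
                out[s] = base - removed + immigrants
    return out


def simulate_samples(model: MetacommunityModel, scenario: AssemblyScenario) -> OtuTable:
    """Draw an OTU table under the scenario's assembly process.

    Every sample's counts sum exactly to the configured sequencing depth.
    Sample ids are ``G{g}_S{s}``; the metadata group labels are ``G1``...
    """
    counts = []
    ids = []
    groups = []
    for g in range(scenario.n_groups):
        rng = child_rng(scenario.seed, "samples", scenario.process, g)
        block = _group_counts(model, scenario, g, rng)
        for s in range(scenario.samples_per_group):
            counts.append(block[s])
            ids.append(f"G{g + 1}_S{s + 1}")
            groups.append(f"G{g + 1}")
    frame = pd.DataFrame(np.vstack(counts), index=ids, columns=model.taxa)
    meta = pd.DataFrame({"group": groups}, index=ids)
    return OtuTable(frame, meta)


# ---------------------------------------------------------------------------
# full study bundle (six groups, taxonomy, growth records)
# ---------------------------------------------------------------------------

#: default per-group assembly processes for the six-group, two-season design
DEFAULT_GROUP_PROCESSES = {
    "CS": "heterogeneous_selection",
    "CW": "heterogeneous_selection",
    "XS": "neutral_drift",
    "XW": "neutral_drift",
    "QS": "dispersal_limitation",
    "QW": "neutral_drift",
}

_GROUP_SEX = {"C": "female", "X": "male", "Q": "all_female"}
_GROUP_SEASON = {"S": "summer", "W": "winter"}


@dataclass
class StudyBundle:
    """Everything one grouped-study simulation produces."""

    table: OtuTable
    tree: TreeNode
    taxonomy: pd.DataFrame
    growth: pd.DataFrame
    model: MetacommunityModel = field(repr=False, default=None)


def clade_taxonomy(tree: TreeNode, n_phyla: int = 8, n_classes: int = 24,
                   n_genera: int = 60) -> pd.DataFrame:
    """Assign pseudo-lineages by cutting the tree into nested clades.

    Splits the largest clade repeatedly until the requested number of clades
    per rank exists, then labels tips by membership. Purely synthetic labels
    (``Phylum_01`` ...), used to exercise taxonomy-aware summaries.
    """
    def cut(k: int) -> list[list[str]]:
        clades = [tree]
        while len(clades) < k:
            sizes = [c.count(tips=True) for c in clades]
            i = int(np.argmax(sizes))
            node = clades.pop(i)
            children = node.children
            if not children:
                clades.append(node)
                break
            clades.extend(children)
        return [[t.name for t in c.tips()] if c.children else [c.name] for c in clades]

    frame = pd.DataFrame(
        index=[t.name for t in tree.tips()], columns=list(TAXONOMY_RANKS), dtype=object
    )
    for rank, k, label in (
        ("phylum", n_phyla, "Phylum"),
        ("class", n_classes, "Class"),
        ("genus", n_genera, "Genus"),
    ):
        for i, tips in enumerate(cut(k), start=1):
            frame.loc[tips, rank] = f"{label}_{i:02d}"
    return frame


# per-sex daily-growth-coefficient medians (% per day) and initial weights (g)
_SEX_DGC_MEDIAN = {"male": 0.55, "female": 0.65, "all_female": 0.68}
_DGC_LOG_SD = 0.12
_INITIAL_WEIGHT_G = 26.6
_INITIAL_WEIGHT_LOG_SD = 0.04
_CONDITION_FACTOR_MEAN = 19.0
_CONDITION_FACTOR_SD = 1.0


def simulate_growth_records(seed: int, n_fish_per_group: int = 30,
                            age_dph: int = 434, initial_age_dph: int = 90) -> pd.DataFrame:
    """Per-fish growth records with a configured female > male growth effect.

    Each fish gets a lognormal initial weight, a lognormal daily growth
    coefficient with a sex-specific median, a final weight implied by
    cube-root growth over the elapsed days, and a body length implied by a
    normal condition factor.
    """
    rng = child_rng(seed, "growth")
    t = age_dph - initial_age_dph
    rows = []
    for sex_code, sex in _GROUP_SEX.items():
        for i in range(n_fish_per_group):
            bw_i = _INITIAL_WEIGHT_G * rng.lognormal(0.0, _INITIAL_WEIGHT_LOG_SD)
            dgc = _SEX_DGC_MEDIAN[sex] * rng.lognormal(0.0, _DGC_LOG_SD)
            bw_f = (bw_i ** (1.0 / 3.0) + dgc * t / 100.0) ** 3
            k = rng.normal(_CONDITION_FACTOR_MEAN, _CONDITION_FACTOR_SD)
            bl = (1000.0 * bw_f / k) ** (1.0 / 3.0)
            rows.append(
                {
                    "fish_id": f"{sex_code}{i + 1:03d}",
                    "sex": sex,
                    "age_dph": age_dph,
                    "elapsed_days": t,
                    "initial_weight_g": bw_i,
                    "body_weight_g": bw_f,
                    "body_length_cm": bl,
                    "total_length_cm": bl * 1.18,
                }
            )
    return pd.DataFrame(rows).set_index("fish_id")


def simulate_study(
    seed: int = 0,
    n_taxa: int = 1000,
    samples_per_group: int = 4,
    depth: int = 20_000,
    group_processes: dict[str, str] | None = None,
    season_shift_sigma: float = 0.3,
) -> StudyBundle:
    """Simulate the full six-group (3 sexes x 2 seasons) study design.

    One shared metacommunity; each group's samples are assembled under its
    configured process. Seasons perturb the regional pool by a lognormal
    shift of scale ``season_shift_sigma`` (shared by all groups of that
    season), so seasonal composition differences exist on top of the
    process structure.
    """
    if samples_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    processes = dict(DEFAULT_GROUP_PROCESSES)
    if group_processes:
        unknown = set(group_processes) - set(processes)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        processes.update(group_processes)
    for proc in processes.values():
        if proc not in PROCESS_LABELS:
            raise ValueError(f"unknown scenario label {proc!r}")

    model = make_metacommunity(n_taxa, seed)
    season_rng = child_rng(seed, "season")
    season_pools = {}
    for season in ("S", "W"):
        shift = season_rng.lognormal(0.0, season_shift_sigma, size=n_taxa)
        shifted = model.pool.to_numpy() * shift
        season_pools[season] = pd.Series(shifted / shifted.sum(), index=model.pool.index)

    counts, ids, meta_rows = [], [], []
    for group, proc in processes.items():
        season = group[-1]
        season_model = MetacommunityModel(
            tree=model.tree,
            pool=season_pools[season],
            traits=model.traits,
            trait_sigma=model.trait_sigma,
        )
        scen = AssemblyScenario(
            process=proc,
            n_groups=1,
            samples_per_group=samples_per_group,
            depth=depth,
            seed=int(child_rng(seed, "scenario", group).integers(2**31)),
        )
        block = simulate_samples(season_model, scen)
        for i, sid in enumerate(block.sample_ids):
            new_id = f"{group}_{i + 1}"
            counts.append(block.counts.loc[sid].to_numpy())
            ids.append(new_id)
            meta_rows.append(
                {
                    "group": group,
                    "sex": _GROUP_SEX[group[0]],
                    "season": _GROUP_SEASON[season],
                }
            )
    frame = pd.DataFrame(np.vstack(counts), index=ids, columns=model.taxa)
    meta = pd.DataFrame(meta_rows, index=ids)
    table = OtuTable(frame, meta)
    taxonomy = clade_taxonomy(model.tree)
    growth = simulate_growth_records(seed)
    return StudyBundle(table=table, tree=model.tree, taxonomy=taxonomy,
                       growth=growth, model=model)
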