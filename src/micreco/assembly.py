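"""Null-model inference of community-assembly processes.

Implements the standard two-step pairwise framework: the beta nearest-taxon
index (betaNTI) screens each pair of communities for phylogenetically
deterministic selection, and the modified Raup-Crick index on Bray-Curtis
(RC_bray) splits the remaining pairs between dispersal-driven and undominated
stochastic processes.

betaMNTD between samples k and m is the abundance-weighted mean patristic
distance from each taxon to its nearest relative in the opposite sample::

    betaMNTD = 1/2 [ sum_i p_ik min_{j in m} d(i,j) + sum_j p_jm min_{i in k} d(j,i) ]

betaNTI is the z-score of the observed betaMNTD against a null built by
shuffling taxon labels across the tree tips (999 shuffles by default).

RC_bray compares the observed Bray-Curtis dissimilarity of a pair with a null
in which each sample keeps its observed richness and total abundance, taxon
membership is drawn with probability proportional to occurrence frequency
across samples, and individuals are filled in proportion to regional relative
abundance. ``RC = 2 ([#null < obs] + 0.5 [#null = obs]) / n_null - 1``.

Pairwise classification (the direction convention follows the standard usage:
RC_bray > +0.95 means dispersal limitation; a flag flips it):

* betaNTI > +2  -> heterogeneous selection
* betaNTI < -2  -> homogeneous selection
* else RC_bray > +0.95 -> dispersal limitation
* else RC_bray < -0.95 -> homogenizing dispersal
* otherwise            -> undominated
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .data import OtuTable, patristic_distances
from .diversity import PermTestResult, distance_matrix
from .synthetic import child_rng

__all__ = [
    "PAIR_LABELS",
    "SimilarityNullResult",
    "AssemblyResult",
    "observed_similarity",
    "null_expected_similarity",
    "determinism_test",
    "beta_mntd",
    "beta_nti",
    "rc_bray",
    "classify_pair",
    "classify_processes",
]

PAIR_LABELS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


# ---------------------------------------------------------------------------
# observed and null-expected similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityNullResult:
    """Observed vs null-expected Bray-Curtis similarity over sample pairs."""

    sample_ids: list
    d_obs: pd.DataFrame  # observed dissimilarity (square)
    s_obs: pd.DataFrame  # 1 - d_obs
    e_exp: pd.DataFrame | None = None  # mean null similarity per pair
    null_similarities: np.ndarray | None = None  # reps x pairs (condensed order)


def observed_similarity(table: OtuTable) -> SimilarityNullResult:
    """Bray-Curtis similarity S_obs = 1 - D_obs for every sample pair."""
    dm = distance_matrix(table, "bray_curtis")
    d = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    return SimilarityNullResult(sample_ids=list(dm.ids), d_obs=d, s_obs=1.0 - d)


def _null_count_matrix(counts: np.ndarray, occ_p: np.ndarray, regional: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """One null realization: per sample keep richness and total abundance,
    draw membership ~ occurrence frequency, fill individuals ~ regional pool."""
    n_samples, n_taxa = counts.shape
    null = np.zeros_like(counts)
    for s in range(n_samples):
        richness = int((counts[s] > 0).sum())
        total = int(counts[s].sum())
        taxa = rng.choice(n_taxa, size=richness, replace=False, p=occ_p)
        fill_p = regional[taxa]
        fill_p = fill_p / fill_p.sum()
        null[s, taxa] = 1
        if total > richness:
            null[s, taxa] += rng.multinomial(total - richness, fill_p)
    return null


def _bray_condensed(counts: np.ndarray) -> np.ndarray:
    props = counts / counts.sum(axis=1, keepdims=True)
    return pdist(props, metric="braycurtis")


def null_expected_similarity(table: OtuTable, n_reps: int = 999,
                             seed: int = 0) -> SimilarityNullResult:
    """Null-expected similarity distribution per sample pair.

    Warns below 99 reps (poor resolution), errors below 2.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 null replicates")
    if n_reps < 99:
        import warnings

        warnings.warn("fewer than 99 null replicates gives poor resolution", stacklevel=2)
    result = observed_similarity(table)
    counts = table.counts.to_numpy()
    occ = (counts > 0).sum(axis=0).astype(float)
    occ_p = occ / occ.sum()
    regional = counts.sum(axis=0).astype(float)
    regional = regional / regional.sum()
    rng = child_rng(seed, "null_similarity")
    n_pairs = table.n_samples * (table.n_samples - 1) // 2
    sims = np.empty((n_reps, n_pairs))
    for r in range(n_reps):
        null = _null_count_matrix(counts, occ_p, regional, rng)
        sims[r] = 1.0 - _bray_condensed(null)
    e_exp = squareform(sims.mean(axis=0))
    result.e_exp = pd.DataFrame(e_exp, index=result.sample_ids, columns=result.sample_ids)
    result.null_similarities = sims
    return result


def determinism_test(result: SimilarityNullResult, n_perm: int = 999,
                     seed: int = 0) -> tuple[PermTestResult, str]:
    """Permutation F-test of observed vs null-expected pairwise similarities.

    Compares the per-pair observed similarities with the per-pair null means;
    the verdict is ``determinism`` when the observed similarities are
    significantly higher than the null expectation, else ``stochasticity``.
    """
    if result.e_exp is None:
        raise ValueError("run null_expected_similarity first")
    n = len(result.sample_ids)
    iu = np.triu_indices(n, k=1)
    obs = result.s_obs.to_numpy()[iu]
    exp = result.e_exp.to_numpy()[iu]
    values = np.concatenate([obs, exp])
    labels = np.concatenate([np.zeros(len(obs)), np.ones(len(exp))])

    def f_stat(v: np.ndarray) -> float:
        g0, g1 = v[labels == 0], v[labels == 1]
        grand = v.mean()
        ss_between = len(g0) * (g0.mean() - grand) ** 2 + len(g1) * (g1.mean() - grand) ** 2
        ss_within = ((g0 - g0.mean()) ** 2).sum() + ((g1 - g1.mean()) ** 2).sum()
        df_w = len(v) - 2
        if ss_within == 0:
            return np.inf if ss_between > 0 else 0.0
        return float(ss_between / (ss_within / df_w))

    f_obs = f_stat(values)
    rng = child_rng(seed, "determinism")
    exceed = 0
    for _ in range(n_perm):
        exceed += f_stat(rng.permutation(values)) >= f_obs - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    test = PermTestResult(name="observed_vs_null", statistic=f_obs, p_value=p,
                          n_perm=n_perm, seed=seed)
    verdict = "determinism" if (p < 0.05 and obs.mean() > exp.mean()) else "stochasticity"
    return test, verdict


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------

def _beta_mntd_from_dist(rel: np.ndarray, present_idx: list[np.ndarray],
                         dist: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given a patristic matrix.

    ``CM[m, i] = min_{j in sample m} d(i, j)``; then
    ``betaMNTD[k, m] = 1/2 (p_k . CM[m] + p_m . CM[k])`` since absent taxa
    carry zero weight.
    """
    n_samples = rel.shape[0]
    cm = np.empty((n_samples, rel.shape[1]))
    for m in range(n_samples):
        cm[m] = dist[:, present_idx[m]].min(axis=1)
    half = rel @ cm.T  # half[k, m] = sum_i p_ik * min_{j in m} d(i, j)
    out = 0.5 * (half + half.T)
    np.fill_diagonal(out, 0.0)
    return out


def _prepare_phylo(table: OtuTable, tree):
    otus = table.otu_ids
    dist_df = patristic_distances(tree)
    missing = set(otus) - set(dist_df.index)
    if missing:
        raise ValueError(
            f"{len(missing)} table OTUs missing from the tree; reconcile with "
            "match_tree_and_table first"
        )
    dist = dist_df.loc[otus, otus].to_numpy()
    counts = table.counts.to_numpy().astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    present_idx = [np.flatnonzero(counts[s] > 0) for s in range(table.n_samples)]
    return rel, present_idx, dist


def beta_mntd(table: OtuTable, tree, abundance_weighted: bool = True) -> pd.DataFrame:
    """Pairwise beta mean nearest-taxon distance (branch-length units)."""
    rel, present_idx, dist = _prepare_phylo(table, tree)
    if not abundance_weighted:
        pres = (rel > 0).astype(float)
        rel = pres / pres.sum(axis=1, keepdims=True)
    out = _beta_mntd_from_dist(rel, present_idx, dist)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


def beta_nti(table: OtuTable, tree, n_null: int = 999, seed: int = 0,
             abundance_weighted: bool = True) -> pd.DataFrame:
    """Beta nearest-taxon index: z-score of betaMNTD against a taxa-shuffle null.

    The null shuffles OTU labels across all tree tips in the metacommunity
    and recomputes betaMNTD per shuffle. A zero null standard deviation for
    any pair (degenerate tree or table) raises with a diagnostic.
    """
    rel, present_idx, dist = _prepare_phylo(table, tree)
    if not abundance_weighted:
        pres = (rel > 0).astype(float)
        rel = pres / pres.sum(axis=1, keepdims=True)
    obs = _beta_mntd_from_dist(rel, present_idx, dist)
    rng = child_rng(seed, "beta_nti")
    n_taxa = rel.shape[1]
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        null = _beta_mntd_from_dist(rel, present_idx, dist[np.ix_(perm, perm)])
        null_sum += null
        null_sq += null**2
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    var = np.maximum(var, 0.0)
    sd = np.sqrt(var * n_null / max(n_null - 1, 1))
    n = obs.shape[0]
    iu = np.triu_indices(n, k=1)
    if np.any(sd[iu] <= 1e-12):
        raise ValueError(
            "null betaMNTD has zero variance for at least one pair "
            "(degenerate tree, e.g. a star phylogeny, or identical memberships)"
        )
    z = np.zeros_like(obs)
    z[iu] = (obs[iu] - mean[iu]) / sd[iu]
    z = z + z.T
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ---------------------------------------------------------------------------

def rc_bray(table: OtuTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """Modified Raup-Crick index per pair, in [-1, +1].

    Null pairs come from the same richness/abundance-preserving algorithm as
    ``null_expected_similarity``; the raw quantile of the observed
    dissimilarity within the null distribution is rescaled to [-1, +1].
    """
    nullres = null_expected_similarity(table, n_reps=n_null, seed=seed)
    n = table.n_samples
    iu = np.triu_indices(n, k=1)
    obs_d = nullres.d_obs.to_numpy()[iu]
    null_d = 1.0 - nullres.null_similarities  # reps x pairs
    less = (null_d < obs_d - 1e-12).sum(axis=0)
    ties = (np.abs(null_d - obs_d) <= 1e-12).sum(axis=0)
    rc_raw = (less + 0.5 * ties) / n_null
    rc = 2.0 * (rc_raw - 0.5)
    out = np.zeros((n, n))
    out[iu] = rc
    out = out + out.T
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# process classification
# ---------------------------------------------------------------------------

def classify_pair(bnti: float, rc: float,
                  rc_positive_is_dispersal_limitation: bool = True) -> str:
    """Deterministic label for one community pair from (betaNTI, RC_bray)."""
    if np.isnan(bnti) or np.isnan(rc):
        raise ValueError("betaNTI / RC_bray must not be NaN")
    if bnti > 2.0:
        return "heterogeneous_selection"
    if bnti < -2.0:
        return "homogeneous_selection"
    if rc > 0.95:
        return ("dispersal_limitation" if rc_positive_is_dispersal_limitation
                else "homogenizing_dispersal")
    if rc < -0.95:
        return ("homogenizing_dispersal" if rc_positive_is_dispersal_limitation
                else "dispersal_limitation")
    return "undominated"


@dataclass
class AssemblyResult:
    """Per-pair assembly statistics plus per-group aggregation."""

    pairs: pd.DataFrame  # sample_i, sample_j, group_i, group_j, bnti, rc, label
    groups: pd.DataFrame  # group, mean_bnti, mean_rc, modal_label, verdict


def classify_processes(bnti: pd.DataFrame, rc: pd.DataFrame,
                       grouping: pd.Series | None = None,
                       rc_positive_is_dispersal_limitation: bool = True,
                       summary: str = "mean") -> AssemblyResult:
    """Classify every pair and aggregate within groups.

    Group rows report the mean (or median) within-group betaNTI and RC_bray,
    the modal pairwise label, and a determinism/stochasticity verdict
    (selection labels count as determinism).
    """
    if list(bnti.index) != list(rc.index):
        raise ValueError("betaNTI and RC matrices cover different samples")
    ids = list(bnti.index)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            b = float(bnti.iloc[i, j])
            r = float(rc.iloc[i, j])
            rows.append(
                {
                    "sample_i": ids[i],
                    "sample_j": ids[j],
                    "bnti": b,
                    "rc_bray": r,
                    "label": classify_pair(b, r, rc_positive_is_dispersal_limitation),
                }
            )
    pairs = pd.DataFrame(rows)
    agg = np.mean if summary == "mean" else np.median
    group_rows = []
    if grouping is not None:
        grouping = grouping.loc[ids]
        pairs["group_i"] = grouping.loc[pairs["sample_i"]].to_numpy()
        pairs["group_j"] = grouping.loc[pairs["sample_j"]].to_numpy()
        for g in pd.unique(grouping):
            sub = pairs[(pairs["group_i"] == g) & (pairs["group_j"] == g)]
            if sub.empty:
                continue
            modal = sub["label"].mode().iloc[0]
            mean_b = float(agg(sub["bnti"]))
            mean_r = float(agg(sub["rc_bray"]))
            verdict = (
                "determinism"
                if modal in ("heterogeneous_selection", "homogeneous_selection")
                else "stochasticity"
            )
            group_rows.append(
                {
                    "group": g,
                    "n_pairs": len(sub),
                    "mean_bnti": mean_b,
                    "mean_rc_bray": mean_r,
                    "modal_label": modal,
                    "verdict": verdict,
                }
            )
    groups = pd.DataFrame(group_rows)
    return AssemblyResult(pairs=pairs, groups=groups)
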