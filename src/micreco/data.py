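"""Core data model and I/O for OTU tables, phylogenies, taxonomy and sample metadata.

The universal input of every downstream stage is an :class:`OtuTable`: an
integer count matrix (samples x OTUs) plus a per-sample metadata frame
carrying at least a ``group`` factor (and optionally ``sex`` / ``season``).
Phylogenies are scikit-bio ``TreeNode`` objects read from Newick; taxonomy is
a pandas DataFrame indexed by OTU id.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "load_otu_table",
    "write_otu_table",
    "load_tree",
    "write_tree",
    "load_taxonomy",
    "write_taxonomy",
    "match_tree_and_table",
    "patristic_distances",
    "shared_otu_counts",
]

TAXONOMY_RANKS = ("phylum", "class", "genus")
_RANK_PREFIXES = {"p__": "phylum", "c__": "class", "g__": "genus"}


class OtuTable:
    """Validated sample-by-OTU count table with sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer counts, rows = samples, columns = OTUs.
    metadata : pandas.DataFrame
        Indexed by sample id, 1:1 with ``counts`` rows; must contain a
        ``group`` column.
    """

    def __init__(self, counts: pd.DataFrame, metadata: pd.DataFrame):
        counts = counts.copy()
        metadata = metadata.copy()
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {counts.index[i]!r}, OTU {counts.columns[j]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValueError(
                f"non-integer count at sample {counts.index[i]!r}, OTU {counts.columns[j]!r}"
            )
        counts = counts.astype(np.int64)
        totals = counts.sum(axis=1)
        if (totals == 0).any():
            empty = totals.index[totals == 0].tolist()
            raise ValueError(f"samples with zero total count: {empty}")
        if set(metadata.index) != set(counts.index) or len(metadata) != len(counts):
            missing = sorted(set(counts.index) - set(metadata.index))
            extra = sorted(set(metadata.index) - set(counts.index))
            raise ValueError(
                f"metadata/sample mismatch: missing metadata for {missing}, "
                f"metadata without counts for {extra}"
            )
        if "group" not in metadata.columns:
            raise ValueError("metadata must contain a 'group' column")
        counts.index.name = "sample_id"
        metadata.index.name = "sample_id"
        counts.columns.name = None
        self.counts = counts
        self.metadata = metadata.loc[counts.index]

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def groups(self) -> pd.Series:
        return self.metadata["group"]

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(self.counts.loc[list(sample_ids)], self.metadata.loc[list(sample_ids)])

    def subset_group(self, group: str) -> "OtuTable":
        ids = self.metadata.index[self.metadata["group"] == group]
        if len(ids) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return self.subset_samples(ids)

    def drop_otus(self, otu_ids) -> "OtuTable":
        keep = [o for o in self.counts.columns if o not in set(otu_ids)]
        return OtuTable(self.counts[keep], self.metadata)

    def to_relative_abundance(self) -> "RelAbundanceTable":
        return to_relative_abundance(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<OtuTable {self.n_samples} samples x {self.n_otus} OTUs>"


@dataclass
class RelAbundanceTable:
    """Per-sample relative abundances; rows sum to 1."""

    proportions: pd.DataFrame
    row_sum_tol: float = field(default=1e-9, repr=False)

    def __post_init__(self):
        arr = self.proportions.to_numpy(dtype=float)
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = arr.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=self.row_sum_tol, rtol=0):
            bad = self.proportions.index[~np.isclose(sums, 1.0, atol=self.row_sum_tol, rtol=0)]
            raise ValueError(f"rows do not sum to 1: {list(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.proportions.columns)


def to_relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Divide each sample's counts by its total."""
    totals = table.sample_totals()
    props = table.counts.div(totals, axis=0)
    return RelAbundanceTable(props)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_otu_table(path, metadata_path) -> OtuTable:
    """Read a tab-separated OTU count table plus its sample sheet.

    The count file has samples as rows (first column = sample id) and OTUs as
    columns. The metadata file needs columns ``sample_id`` and ``group``.
    Malformed numeric cells are reported with their row/column address.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    counts = raw.apply(pd.to_numeric, errors="coerce")
    if counts.isna().to_numpy().any():
        i, j = np.argwhere(counts.isna().to_numpy())[0]
        raise ValueError(
            f"malformed numeric cell {raw.iloc[i, j]!r} at sample "
            f"{raw.index[i]!r}, OTU {raw.columns[j]!r} in {path}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata must have 'sample_id' and 'group' columns")
    meta = meta.set_index("sample_id")
    return OtuTable(counts, meta)


def write_otu_table(table: OtuTable, path, metadata_path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")
    table.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")


def load_tree(path) -> TreeNode:
    """Read a rooted Newick tree; every non-root branch must have a length."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise ValueError(f"could not parse Newick file {path}: {exc}") from exc
    return _validate_tree(tree)


def _validate_tree(tree: TreeNode) -> TreeNode:
    tips = list(tree.tips())
    names = [t.name for t in tips]
    if len(set(names)) != len(names):
        raise ValueError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(
                "tree has branches without lengths; phylogenetic metrics are undefined"
            )
        if node.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def patristic_distances(tree: TreeNode) -> pd.DataFrame:
    """All pairwise tip-to-tip path lengths as a labelled square DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def load_taxonomy(path) -> pd.DataFrame:
    """Read OTU -> lineage TSV.

    Lineages are semicolon-delimited and may use the ``p__X;c__Y;g__Z``
    dialect or plain rank names in (phylum, class, genus) order.
    """
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError("taxonomy file needs OTU id and lineage columns")
    otu_col, lineage_col = raw.columns[0], raw.columns[1]
    if raw[otu_col].duplicated().any():
        dups = raw[otu_col][raw[otu_col].duplicated()].tolist()
        raise ValueError(f"duplicate OTU ids in taxonomy: {dups}")
    rows = {}
    for otu, lineage in zip(raw[otu_col], raw[lineage_col]):
        fields = [f.strip() for f in str(lineage).split(";")]
        parsed = dict.fromkeys(TAXONOMY_RANKS, "Unclassified")
        plain = []
        for f in fields:
            if not f:
                continue
            prefix = f[:3]
            if prefix in _RANK_PREFIXES:
                if len(f) > 3:
                    parsed[_RANK_PREFIXES[prefix]] = f[3:]
            else:
                plain.append(f)
        for rank, value in zip(TAXONOMY_RANKS, plain):
            parsed[rank] = value
        rows[otu] = parsed
    return pd.DataFrame.from_dict(rows, orient="index")[list(TAXONOMY_RANKS)]


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    lineage = taxonomy.apply(lambda r: ";".join(r[list(TAXONOMY_RANKS)]), axis=1)
    pd.DataFrame({"otu_id": taxonomy.index, "lineage": lineage.values}).to_csv(
        path, sep="\t", index=False
    )


def match_tree_and_table(table: OtuTable, tree: TreeNode, min_coverage: float = 0.5):
    """Reconcile tree tips with table OTUs.

    Tips absent from the table are pruned; table OTUs absent from the tree are
    dropped, each with a warning. A hard error is raised when fewer than
    ``min_coverage`` of the table's OTUs are on the tree (annotated tables and
    reference trees routinely mismatch at the margin, but a gross mismatch
    means the wrong tree).
    """
    tip_names = {t.name for t in tree.tips()}
    table_otus = set(table.otu_ids)
    on_tree = table_otus & tip_names
    if len(on_tree) < min_coverage * len(table_otus):
        raise ValueError(
            f"only {len(on_tree)}/{len(table_otus)} table OTUs are on the tree "
            f"(< {min_coverage:.0%} coverage)"
        )
    missing_from_tree = table_otus - tip_names
    extra_tips = tip_names - table_otus
    if missing_from_tree:
        warnings.warn(
            f"dropping {len(missing_from_tree)} table OTUs absent from the tree",
            stacklevel=2,
        )
        table = table.drop_otus(missing_from_tree)
    if extra_tips:
        warnings.warn(
            f"pruning {len(extra_tips)} tree tips absent from the table", stacklevel=2
        )
        tree = tree.shear(on_tree)
    return table, tree


# ---------------------------------------------------------------------------
# shared-OTU intersections (UpSet semantics)
# ---------------------------------------------------------------------------

def shared_otu_counts(table: OtuTable, group_col: str = "group") -> dict[tuple, int]:
    """Exact UpSet intersection sizes over groups.

    An OTU is present in a group when its summed count over the group's
    samples is > 0. Each observed OTU is assigned to exactly one combination:
    the full set of groups containing it. Sizes therefore sum to the number
    of OTUs observed anywhere.
    """
    groups = table.metadata[group_col]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("shared_otu_counts needs at least 2 groups")
    presence = {}
    for g in levels:
        ids = groups.index[groups == g]
        presence[g] = table.counts.loc[ids].sum(axis=0) > 0
    pres = pd.DataFrame(presence)  # OTUs x groups
    observed = pres.any(axis=1)
    pres = pres.loc[observed]
    combos: dict[tuple, int] = {}
    for r in range(1, len(levels) + 1):
        for combo in itertools.combinations(levels, r):
            in_combo = pres[list(combo)].all(axis=1)
            out_groups = [g for g in levels if g not in combo]
            only = in_combo & ~pres[out_groups].any(axis=1) if out_groups else in_combo
            n = int(only.sum())
            if n > 0:
                combos[combo] = n
    return combos
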