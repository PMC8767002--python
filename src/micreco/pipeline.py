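"""End-to-end orchestration: data -> diversity -> categories -> assembly ->
networks -> growth, from one config, with per-stage seeds and a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, categories, data, diversity, growth, network, synthetic

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("micreco")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "micreco_out"
    seed: int = 0
    # input files (all four required together) or a synthetic scenario
    otu_table: str | None = None
    metadata: str | None = None
    tree: str | None = None
    taxonomy: str | None = None
    growth_records: str | None = None
    synthetic: dict = field(default_factory=dict)  # kwargs for simulate_study
    group_col: str = "group"
    n_perm: int = 999
    n_null: int = 999
    rare_cutoff: float = 0.001
    abundant_cutoff: float = 0.01
    min_prevalence: float = 0.5
    rmt_start: float = 0.30
    rmt_stop: float = 0.90
    rmt_step: float = 0.01
    n_random_networks: int = 30
    stages: tuple = ("diversity", "categories", "assembly", "network", "growth")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg


def _load_inputs(cfg: PipelineConfig):
    if cfg.otu_table:
        table = data.load_otu_table(cfg.otu_table, cfg.metadata)
        tree = data.load_tree(cfg.tree) if cfg.tree else None
        taxonomy = data.load_taxonomy(cfg.taxonomy) if cfg.taxonomy else None
        records = (
            pd.read_csv(cfg.growth_records, sep="\t", index_col=0)
            if cfg.growth_records
            else None
        )
        if tree is not None:
            table, tree = data.match_tree_and_table(table, tree)
        return table, tree, taxonomy, records
    bundle = synthetic.simulate_study(seed=cfg.seed, **cfg.synthetic)
    return bundle.table, bundle.tree, bundle.taxonomy, bundle.growth


def _write_tsv(frame: pd.DataFrame, path: Path, **kwargs) -> None:
    if frame is None or len(frame) == 0:
        raise ValueError(f"refusing to write empty results to {path}")
    frame.to_csv(path, sep="\t", **kwargs)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("diversity")
def _run_diversity(cfg, table, tree, outdir) -> list[Path]:
    written = []
    alpha = pd.DataFrame(
        {
            m: diversity.alpha_diversity(table, m, tree=tree)
            for m in diversity.ALPHA_METRICS
            if m != "faith_pd" or tree is not None
        }
    )
    p = outdir / "alpha_diversity.tsv"
    _write_tsv(alpha, p, index_label="sample_id")
    written.append(p)

    test_rows = []
    for metric in ("bray_curtis", "jaccard"):
        dm = diversity.distance_matrix(table, metric)
        p = outdir / f"distance_{metric}.tsv"
        _write_tsv(
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
            p, index_label="sample_id",
        )
        written.append(p)
        factors = [cfg.group_col]
        if {"sex", "season"}.issubset(table.metadata.columns):
            factors = ["sex", "season"]
        res = diversity.permanova(dm, table.metadata, factors,
                                  n_perm=cfg.n_perm, seed=cfg.seed)
        for term, r in res.items():
            test_rows.append({"test": "permanova", "metric": metric, "term": term,
                              "statistic": r.statistic, "p_value": r.p_value,
                              "n_perm": r.n_perm, "seed": r.seed})
        an = diversity.anosim(dm, table.metadata[cfg.group_col],
                              n_perm=cfg.n_perm, seed=cfg.seed)
        test_rows.append({"test": "anosim", "metric": metric, "term": cfg.group_col,
                          "statistic": an.statistic, "p_value": an.p_value,
                          "n_perm": an.n_perm, "seed": an.seed})
    jac = diversity.distance_matrix(table, "jaccard")
    coords, stress = diversity.nmds(jac, seed=cfg.seed)
    coords["stress"] = stress
    p = outdir / "nmds_jaccard.tsv"
    _write_tsv(coords, p, index_label="sample_id")
    written.append(p)
    p = outdir / "permutation_tests.tsv"
    _write_tsv(pd.DataFrame(test_rows), p, index=False)
    written.append(p)
    return written


@_stage("categories")
def _run_categories(cfg, table, outdir) -> list[Path]:
    thresholds = categories.CategoryThresholds(cfg.rare_cutoff, cfg.abundant_cutoff)
    assignments = {}
    for g in sorted(table.groups().unique()):
        sub = table.subset_group(g)
        assignments[g] = categories.classify_taxa(sub.to_relative_abundance(), thresholds)
    summary = categories.category_summary(assignments)
    p1 = outdir / "category_summary.tsv"
    _write_tsv(summary, p1, index=False)
    p2 = outdir / "category_report.tsv"
    _write_tsv(categories.category_report(summary), p2, index_label="category")
    return [p1, p2]


@_stage("assembly")
def _run_assembly(cfg, table, tree, outdir) -> list[Path]:
    group_rows = []
    pair_frames = []
    for g in sorted(table.groups().unique()):
        sub = table.subset_group(g)
        nullres = assembly.null_expected_similarity(sub, n_reps=cfg.n_null, seed=cfg.seed)
        test, _ = assembly.determinism_test(nullres, n_perm=cfg.n_perm, seed=cfg.seed)
        bnti = assembly.beta_nti(sub, tree, n_null=cfg.n_null, seed=cfg.seed)
        rc = assembly.rc_bray(sub, n_null=cfg.n_null, seed=cfg.seed)
        res = assembly.classify_processes(bnti, rc, grouping=sub.groups())
        pair_frames.append(res.pairs.assign(group=g))
        iu = np.triu_indices(sub.n_samples, k=1)
        row = res.groups.iloc[0].to_dict()
        row.update(
            {
                "group": g,
                "mean_s_obs": float(nullres.s_obs.to_numpy()[iu].mean()),
                "mean_e_exp": float(nullres.e_exp.to_numpy()[iu].mean()),
                "F": test.statistic,
                "p": test.p_value,
            }
        )
        group_rows.append(row)
    cols = ["group", "mean_s_obs", "mean_e_exp", "F", "p", "mean_bnti",
            "mean_rc_bray", "modal_label", "verdict", "n_pairs"]
    p1 = outdir / "assembly_groups.tsv"
    _write_tsv(pd.DataFrame(group_rows)[cols], p1, index=False)
    p2 = outdir / "assembly_pairs.tsv"
    _write_tsv(pd.concat(pair_frames, ignore_index=True), p2, index=False)
    return [p1, p2]


@_stage("network")
def _run_network(cfg, table, taxonomy, outdir) -> list[Path]:
    written = []
    topo_rows = []
    for g in sorted(table.groups().unique()):
        sub = table.subset_group(g)
        if sub.n_samples < 6:
            logger.warning("group %s has %d samples; correlations will be noisy",
                           g, sub.n_samples)
        prepared = network.prepare_abundance_matrix(sub, cfg.min_prevalence)
        corr = network.correlation_matrix(prepared)
        try:
            st, _ = network.rmt_threshold(corr, cfg.rmt_start, cfg.rmt_stop, cfg.rmt_step)
        except ValueError as exc:
            logger.warning("group %s: %s; falling back to 0.80", g, exc)
            st = 0.80
        net = network.build_network(corr, st)
        network.detect_modules(net)
        topo = network.topology_indices(net)
        baseline = network.random_network_baseline(
            net, n_random=cfg.n_random_networks, seed=cfg.seed
        )
        roles = network.node_roles(net)
        if taxonomy is not None:
            roles = roles.join(taxonomy, how="left")
        p = outdir / f"network_{g}_nodes.tsv"
        _write_tsv(roles, p, index_label="node")
        written.append(p)
        edges = pd.DataFrame(
            [
                {"source": u, "target": v, "correlation": d["weight"], "sign": d["sign"]}
                for u, v, d in net.graph.edges(data=True)
            ]
        )
        p = outdir / f"network_{g}_edges.tsv"
        _write_tsv(edges, p, index=False)
        written.append(p)
        import networkx as nx

        nx.write_graphml(net.graph, outdir / f"network_{g}.graphml")
        row = {"group": g, "threshold": st, **asdict(topo)}
        row.pop("extras", None)
        for idx in baseline.index:
            row[f"random_{idx}_mean"] = baseline.loc[idx, "random_mean"]
            row[f"random_{idx}_sd"] = baseline.loc[idx, "random_sd"]
        topo_rows.append(row)
    p = outdir / "network_topology.tsv"
    _write_tsv(pd.DataFrame(topo_rows), p, index=False)
    written.append(p)
    return written


@_stage("growth")
def _run_growth(cfg, records, outdir) -> list[Path]:
    if records is None:
        return []
    p = outdir / "growth_summary.tsv"
    _write_tsv(growth.growth_summary(records), p, index_label="sex")
    return [p]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest (also written as JSON)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, tree, taxonomy, records = _load_inputs(cfg)
    logger.info("inputs: %d samples x %d OTUs", table.n_samples, table.n_otus)
    written: list[Path] = []
    try:
        if "diversity" in cfg.stages:
            written += _run_diversity(cfg, table, tree, outdir)
        if "categories" in cfg.stages:
            written += _run_categories(cfg, table, outdir)
        if "assembly" in cfg.stages:
            if tree is None:
                raise ValueError("assembly stage requires a tree")
            written += _run_assembly(cfg, table, tree, outdir)
        if "network" in cfg.stages:
            written += _run_network(cfg, table, taxonomy, outdir)
        if "growth" in cfg.stages:
            written += _run_growth(cfg, records, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    checksums = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(written)
    }
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_samples": table.n_samples,
        "n_otus": table.n_otus,
        "outputs": checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    # JSON mirrors of every TSV table
    for p in written:
        mirror = pd.read_csv(p, sep="\t")
        mirror.to_json(p.with_suffix(".json"), orient="records", indent=2)
    return manifest
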