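"""End-to-end orchestration: preprocess -> fit -> stability -> enrich -> network.

The pipeline runs once per sample group (e.g. tumour subtype or normal
tissue): preprocessing, optional sparsity tuning, the sparse multi-block
fit, the stability filter, per-component over-representation plus a
preranked GSEA on transcript fold changes, and a prior-calibrated MI network
around the top enriched function.  Cross-group analytics (UpSet-style
intersections, Jaccard similarity of the features behind shared enrichments,
exclusive-category Fisher tests) follow.  A manifest with content hashes of
every output makes runs comparable bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import minetwork as net
from .blocks import OmicsBlock, check_aligned, read_table_tsv, write_table_tsv
from .exceptions import ConfigurationError, ValidationError
from .preprocess import (beta_to_mvalue, filter_missing_features, knn_impute,
                         scale_block_by_first_eigenvalue)
from .sgcca import SGCCAParams, sgcca_fit
from .synthetic_data import read_gmt
from .tuning_stability import DEFAULT_GRID, stability_select, tune_sparsity

logger = logging.getLogger(__name__)

OMICS = ("cpg", "transcript", "mirna")


@dataclass
class PipelineConfig:
    """Paths plus per-stage parameter sections; see docs/methods.md for units."""

    block_paths: Dict[str, str]
    labels_path: str
    annotation_path: str
    genesets_path: str
    outdir: str
    priors_path: Optional[str] = None
    term_classes_path: Optional[str] = None
    seed: int = 0
    reference_group: Optional[str] = None
    preprocess: dict = field(default_factory=lambda: {
        "max_missing_fraction": 0.25, "knn_k": 10, "mvalue_eps": 1e-6})
    tuning: dict = field(default_factory=lambda: {
        "enabled": False, "grid": None, "reps": 10, "per_group": 10})
    fit: dict = field(default_factory=lambda: {"sparsity": None, "ncomp": None})
    stability: dict = field(default_factory=lambda: {
        "enabled": True, "n_runs": 100, "subsample_fraction": 0.5, "keep_threshold": 0.7})
    enrichment: dict = field(default_factory=lambda: {
        "alpha": 0.01, "gsea_n_perm": 1000, "cluster_tau": 1.0})
    network: dict = field(default_factory=lambda: {
        "enabled": True, "nbins": None, "ks_alpha": 0.05,
        "first_neighbors": False, "dpi": False, "dpi_tolerance": 0.0})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate_schema()
        return cfg

    def validate_schema(self) -> None:
        if set(self.block_paths) != set(OMICS):
            raise ConfigurationError(f"block_paths must name exactly {OMICS}")
        for p in [*self.block_paths.values(), self.labels_path,
                  self.annotation_path, self.genesets_path]:
            if not os.path.exists(p):
                raise ConfigurationError(f"input file not found: {p}")
        if self.network.get("enabled", True):
            if not self.priors_path:
                raise ConfigurationError("network stage enabled but no priors file configured")
            if not os.path.exists(self.priors_path):
                raise ConfigurationError(f"priors file not found: {self.priors_path}")
        if self.term_classes_path and not os.path.exists(self.term_classes_path):
            raise ConfigurationError(f"term classes file not found: {self.term_classes_path}")
        if not 0 <= self.preprocess["max_missing_fraction"] < 1:
            raise ConfigurationError("max_missing_fraction out of range")
        if not 0 < self.stability["keep_threshold"] <= 1:
            raise ConfigurationError("keep_threshold out of range")

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in self.__dataclass_fields__}
        return json.loads(json.dumps(d))


@dataclass
class ValidationReport:
    issues: list  # (level, message)

    @property
    def fatal(self) -> bool:
        return any(level == "fatal" for level, _ in self.issues)

    def raise_if_fatal(self) -> None:
        if self.fatal:
            msgs = [m for lv, m in self.issues if lv == "fatal"]
            raise ValidationError("fatal input problems: " + "; ".join(msgs))


def validate_inputs(blocks: Dict[str, OmicsBlock], labels: pd.Series,
                    annotation: pd.DataFrame,
                    priors: Optional[pd.DataFrame] = None) -> ValidationReport:
    """Structured pre-flight checks; misaligned samples are fatal."""
    issues = []
    ref = blocks[OMICS[0]].sample_ids
    for o in OMICS[1:]:
        if blocks[o].sample_ids != ref:
            issues.append(("fatal", f"block {o} is not sample-aligned with block {OMICS[0]}"))
    if sorted(labels.index) != sorted(ref):
        issues.append(("fatal", "label table does not cover exactly the block samples"))
    known = set(annotation["feature"])
    for o in OMICS:
        feats = set(blocks[o].feature_ids)
        cov = len(feats & known) / max(1, len(feats))
        if cov < 1.0:
            issues.append(("warning", f"annotation covers {cov:.0%} of {o} features"))
    if priors is not None:
        try:
            net.RegulatoryPrior(priors).check_types(annotation)
        except ValidationError as e:
            issues.append(("fatal", f"prior table inconsistent: {e}"))
    return ValidationReport(issues=issues)


# ---------------------------------------------------------------------------


def _load_inputs(config: PipelineConfig):
    blocks = {o: OmicsBlock.from_tsv(config.block_paths[o], o) for o in OMICS}
    lab = read_table_tsv(config.labels_path)
    labels = pd.Series(lab["group"].to_numpy(), index=lab["sample_id"].to_numpy(), name="group")
    annotation = read_table_tsv(config.annotation_path)
    annotation["is_tf"] = annotation["is_tf"].astype(bool)
    priors = None
    if config.priors_path:
        priors = read_table_tsv(config.priors_path)
        priors["validated"] = priors["validated"].astype(bool)
    genesets = read_gmt(config.genesets_path)
    classes = {}
    if config.term_classes_path:
        tc = read_table_tsv(config.term_classes_path)
        classes = dict(zip(tc["term"], tc["term_class"]))
    return blocks, labels, annotation, priors, genesets, classes


def _preprocess(blocks: Dict[str, OmicsBlock], cfg: dict) -> Dict[str, OmicsBlock]:
    cpg = blocks["cpg"]
    cpg = filter_missing_features(cpg, cfg["max_missing_fraction"])
    cpg = knn_impute(cpg, cfg["knn_k"])
    cpg = beta_to_mvalue(cpg, cfg["mvalue_eps"])
    out = {"cpg": cpg, "transcript": blocks["transcript"], "mirna": blocks["mirna"]}
    return {o: scale_block_by_first_eigenvalue(b) for o, b in out.items()}


def _default_ncomp(blocks) -> int:
    n = blocks[0].n_samples
    rank = min(min(b.n_features, n - 1) for b in blocks)
    ncomp = min(n - 1, rank)
    if ncomp < n - 1:
        logger.info("ncomp capped at %d by block rank (n-1 = %d)", ncomp, n - 1)
    return max(1, ncomp)


def _component_enrichment(model, kept, annotation, db, alpha, dataset):
    """Per-component ORA on stability-kept co-selected features, aggregated per term."""
    per_comp = {}
    for h in range(model.ncomp):
        feats = set()
        for j in range(len(model.block_names)):
            feats.update(model.selected(h, j))
        if kept is not None:
            feats &= set(kept)
        genes = enr.map_features_to_genes(feats, annotation) & set(db.universe)
        if genes:
            per_comp[h] = enr.ora(genes, db, alpha=alpha, dataset=dataset)
    agg = {}
    for h, results in per_comp.items():
        for r in results:
            cur = agg.get(r.term)
            comps = (cur.components | {h}) if (cur and r.significant) else (
                frozenset({h}) if r.significant else (cur.components if cur else frozenset()))
            if cur is None or r.p < cur.p:
                base = r
            else:
                base = cur
            agg[r.term] = enr.EnrichmentResult(
                term=r.term, p=base.p, fdr=base.fdr,
                hits=(cur.hits | r.hits) if cur else r.hits,
                query_size=base.query_size, term_size=base.term_size,
                universe_size=base.universe_size,
                significant=bool((cur.significant if cur else False) or r.significant),
                components=comps, dataset=dataset, term_class=base.term_class)
    results = sorted(agg.values(), key=lambda r: (r.p, r.term))
    return results, per_comp


def _enrichment_table(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "term": r.term, "term_class": r.term_class or "", "p": r.p, "fdr": r.fdr,
        "significant": r.significant, "n_hits": len(r.hits),
        "hits": ",".join(sorted(r.hits)),
        "components": ",".join(str(c + 1) for c in sorted(r.components)),
        "dataset": r.dataset or "",
    } for r in results])


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> str:
    """Execute the full chain; returns the run directory (= config.outdir)."""
    config.validate_schema()
    os.makedirs(config.outdir, exist_ok=True)
    blocks, labels, annotation, priors, genesets, classes = _load_inputs(config)
    validate_inputs(blocks, labels, annotation, priors).raise_if_fatal()

    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("tuning", "stability", "gsea"), rng.integers(0, 2 ** 31 - 1, size=3))}

    pre = _preprocess(blocks, config.preprocess)
    predir = os.path.join(config.outdir, "preprocessed")
    os.makedirs(predir, exist_ok=True)
    for o, b in pre.items():
        b.to_tsv(os.path.join(predir, f"block_{o}.tsv"))

    universe = enr.map_features_to_genes(
        [f for b in pre.values() for f in b.feature_ids], annotation)
    db = enr.GeneSetDB(sets={t: frozenset(g) for t, g in genesets.items()},
                       classes=classes, universe=frozenset(universe))
    tf_features = set(annotation.loc[annotation["is_tf"], "feature"])

    groups = sorted(labels.unique())
    reference = config.reference_group
    if reference is None:
        reference = "normal" if "normal" in groups else groups[-1]
    if reference not in groups:
        raise ConfigurationError(f"reference group {reference!r} not among {groups}")

    results_by_group: Dict[str, list] = {}
    manifest_stages: Dict[str, dict] = {}
    for g in groups:
        gdir = os.path.join(config.outdir, g)
        os.makedirs(gdir, exist_ok=True)
        samples = list(labels.index[labels == g])
        gblocks = [pre[o].subset_samples(samples) for o in OMICS]
        stage: dict = {"n_samples": len(samples)}

        sparsity = config.fit.get("sparsity")
        if config.tuning.get("enabled") and sparsity is None:
            grid = config.tuning.get("grid") or list(DEFAULT_GRID)
            tuned = tune_sparsity(gblocks, labels.loc[samples], grid=grid,
                                  reps=config.tuning["reps"],
                                  per_group=min(config.tuning["per_group"], len(samples)),
                                  seed=stage_seeds["tuning"])
            tuned.to_tsv(os.path.join(gdir, "tuning.tsv"))
            sparsity = [tuned.chosen[o] for o in OMICS]
        if sparsity is None:
            sparsity = [max(0.3, 1 / math.sqrt(b.n_features)) for b in gblocks]
        ncomp = config.fit.get("ncomp") or _default_ncomp(gblocks)
        params = SGCCAParams(sparsity=sparsity, ncomp=ncomp)
        model = sgcca_fit(gblocks, params)
        model.save(os.path.join(gdir, "model"))
        stage["sparsity"] = list(map(float, np.atleast_1d(sparsity)))
        stage["ncomp_extracted"] = model.ncomp

        kept = None
        if config.stability.get("enabled", True):
            stab = stability_select(gblocks, params,
                                    n_runs=config.stability["n_runs"],
                                    subsample_fraction=config.stability["subsample_fraction"],
                                    keep_threshold=config.stability["keep_threshold"],
                                    seed=stage_seeds["stability"])
            stab.to_tsv(os.path.join(gdir, "stability.tsv"))
            kept = set(stab.kept)
            stage["n_kept"] = len(kept)

        alpha = config.enrichment["alpha"]
        results, _ = _component_enrichment(model, kept, annotation, db, alpha, g)
        write_table_tsv(_enrichment_table(results), os.path.join(gdir, "enrichment.tsv"))
        results_by_group[g] = results
        clusters = enr.cluster_functions_by_components(
            [r for r in results if r.significant], tau=config.enrichment["cluster_tau"])
        with open(os.path.join(gdir, "function_clusters.json"), "w") as fh:
            json.dump({"clusters": [sorted(c) for c in clusters.clusters],
                       "unclustered": sorted(clusters.unclustered)}, fh, indent=1)

        if g != reference:
            contrast, ref_g = g, reference
        else:
            others = [x for x in groups if x != reference]
            contrast, ref_g = (others[0], reference) if others else (None, None)
        logfc = {}
        if contrast is not None:
            csamp = list(labels.index[labels == contrast])
            rsamp = list(labels.index[labels == ref_g])
            for o in OMICS:
                logfc[o] = net.group_logfc(pre[o], csamp, rsamp)
            tr_lfc = logfc["transcript"]
            tr_genes = annotation[annotation["omic_type"] == "transcript"] \
                .drop_duplicates("feature").set_index("feature")["gene"]
            ranking = pd.Series(tr_lfc["logfc"].to_numpy(),
                                index=tr_genes.reindex(tr_lfc.index).to_numpy())
            ranking = ranking[~ranking.index.isna()]
            gsea = enr.gsea_preranked(ranking, db, n_perm=config.enrichment["gsea_n_perm"],
                                      seed=stage_seeds["gsea"])
            gsea.to_csv(os.path.join(gdir, "gsea.tsv"), sep="\t", index=False)

        if config.network.get("enabled", True) and priors is not None:
            stage["network"] = _network_stage(config, gdir, g, pre, samples, annotation,
                                              priors, db, results, kept, tf_features, logfc)
        manifest_stages[g] = stage

    crossdir = os.path.join(config.outdir, "cross")
    os.makedirs(crossdir, exist_ok=True)
    membership, counts = enr.intersection_summary(results_by_group)
    membership.to_csv(os.path.join(crossdir, "membership.tsv"), sep="\t",
                      index_label="term")
    pd.DataFrame({"datasets": ["|".join(k) for k in counts.index],
                  "count": counts.to_numpy()}).to_csv(
        os.path.join(crossdir, "intersections.tsv"), sep="\t", index=False)
    jrows = []
    sig_terms = {d: {r.term: r for r in rs if r.significant}
                 for d, rs in results_by_group.items()}
    for a, b in [(x, y) for i, x in enumerate(groups) for y in groups[i + 1:]]:
        shared = set(sig_terms[a]) & set(sig_terms[b])
        for t in sorted(shared):
            jrows.append({"term": t, "dataset_a": a, "dataset_b": b,
                          "jaccard": enr.jaccard(sig_terms[a][t].hits, sig_terms[b][t].hits)})
    write_table_tsv(pd.DataFrame(jrows, columns=["term", "dataset_a", "dataset_b", "jaccard"]),
                    os.path.join(crossdir, "jaccard.tsv"))
    if len(groups) >= 2:
        excl = enr.exclusive_category_test(results_by_group, db.classes)
        write_table_tsv(excl, os.path.join(crossdir, "exclusive_categories.tsv"))

    manifest = {
        "config": config.to_dict(), "seed": config.seed, "stage_seeds": stage_seeds,
        "groups": groups, "reference_group": reference, "stages": manifest_stages,
    }
    files = {}
    for root, _, names in os.walk(config.outdir):
        for name in sorted(names):
            if name == "manifest.json":
                continue
            p = os.path.join(root, name)
            files[os.path.relpath(p, config.outdir)] = _sha256(p)
    manifest["files"] = dict(sorted(files.items()))
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return config.outdir


def _network_stage(config, gdir, group, pre, samples, annotation, priors, db,
                   results, kept, tf_features, logfc):
    """MI network around the top enriched function of one group."""
    sig = [r for r in results if r.significant] or results[:1]
    if not sig:
        logger.info("group %s: no enriched term; skipping network", group)
        return {"skipped": "no enriched term"}
    top = sig[0]
    term_genes = set(db.sets[top.term])
    gene_map = annotation.groupby("feature")["gene"].agg(set)
    pool = kept if kept else {f for o in OMICS for f in pre[o].feature_ids}
    functional = {f for f in pool if gene_map.get(f, set()) & term_genes}
    # the sub-matrix: every co-selected feature that survived the stability
    # filter (features co-varying with the functional ones)
    sub_feats = set(pool)
    gblocks = []
    for o in OMICS:
        cols = [f for f in pre[o].feature_ids if f in sub_feats]
        if cols:
            gblocks.append(OmicsBlock(pre[o].subset_samples(samples).data.loc[:, cols], o))
    full_gblocks = [pre[o].subset_samples(samples) for o in OMICS]
    nbins = config.network.get("nbins")
    try:
        medians = net.prior_edge_thresholds(net.RegulatoryPrior(priors), full_gblocks,
                                            nbins=nbins)
    except Exception as e:  # no usable priors is a stage-level failure
        raise ValidationError(f"threshold calibration failed for group {group}: {e}")
    if sum(b.n_features for b in gblocks) < 2:
        logger.info("group %s: fewer than 2 co-selected features; skipping network", group)
        return {"skipped": "too few features", "function": top.term}
    pair_mi = net.pairwise_mi(gblocks, tf_features=tf_features, nbins=nbins)
    if pair_mi.empty:
        return {"skipped": "no admissible feature pair", "function": top.term}
    mi_by_type = {t: g["mi"].to_numpy() for t, g in pair_mi.groupby("edge_type")}
    medians = {t: m for t, m in medians.items()}
    try:
        thresholds, mode, ks_table = net.ks_unify_thresholds(
            mi_by_type, medians, alpha=config.network["ks_alpha"])
    except ValidationError:
        thresholds, mode = dict(medians), "per-type"
        ks_table = pd.DataFrame(columns=["type_a", "type_b", "statistic", "p", "significant"])
    for t in set(pair_mi["edge_type"]) - set(thresholds):
        thresholds[t] = min(medians.values())  # untyped fallback, logged
        logger.info("edge type %s had no prior; using the minimum calibrated median", t)
    meta_rows = []
    ann = annotation.drop_duplicates("feature").set_index("feature")
    for o in OMICS:
        lf = logfc.get(o)
        for f in pre[o].feature_ids:
            meta_rows.append({
                "feature": f, "omic_type": o,
                "is_tf": f in tf_features,
                "logfc": float(lf.loc[f, "logfc"]) if lf is not None and f in lf.index else np.nan})
    node_meta = pd.DataFrame(meta_rows).set_index("feature")
    g = net.build_network(pair_mi, thresholds, node_meta, functional=functional, mode=mode)
    if config.network.get("dpi"):
        g = net.dpi_filter(g, config.network.get("dpi_tolerance", 0.0))
    sub = g
    if functional & set(g.nodes):
        sub = net.functional_subgraph(g, functional,
                                      first_neighbors_only=config.network.get("first_neighbors", False))
    metrics = net.node_metrics(g)
    for v in sub.nodes:
        sub.nodes[v]["degree"] = int(metrics.loc[v, "degree"])
        sub.nodes[v]["betweenness"] = float(metrics.loc[v, "betweenness"])
    net.write_sif(sub, os.path.join(gdir, "network.sif"))
    net.write_graphml(sub, os.path.join(gdir, "network.graphml"))
    net.write_threshold_sidecar(thresholds, mode, ks_table,
                                os.path.join(gdir, "thresholds.json"))
    metrics.to_csv(os.path.join(gdir, "node_metrics.tsv"), sep="\t")
    return {"function": top.term, "mode": mode, "n_nodes": sub.number_of_nodes(),
            "n_edges": sub.number_of_edges()}
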