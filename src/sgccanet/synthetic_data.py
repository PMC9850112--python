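"""Synthetic multi-omic datasets with planted, recoverable structure.

The generator emulates the statistical shape of a methylation + transcript +
miRNA study at desk scale: three sample-aligned blocks of different
dimension, latent factors shared by small cross-block feature groups,
group (subtype) structure, a feature-to-gene annotation in which CpG probes
may map to several genes, typed prior regulatory edges consistent with the
annotation (true edges between planted features plus random decoys), and
gene sets among which one collects genes of planted features (recoverable by
enrichment) and one only-noise genes.

For latent factor h with per-sample score z_h, a planted feature is
x = beta * z_h + eps with |beta| = signal_sd and eps ~ N(0, noise_sd); all
other features are pure noise at noise_sd.  Group structure enters through
group-specific latent means.  The CpG block is expressed as beta values in
(0, 1) via the logistic transform of the Gaussian signal, with missing
entries inserted at missing_rate, so the downstream M-value path is
exercised.  Everything is reproducible bit-for-bit from the seed.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .blocks import OmicsBlock, read_matrix_tsv, read_table_tsv, write_matrix_tsv, write_table_tsv
from .exceptions import ConfigurationError, ValidationError

TERM_CLASS_CYCLE = ("development", "metabolism", "signaling")


@dataclass
class SimConfig:
    """Study conditions of a simulated dataset (defaults: the standard desk-scale run)."""

    n_samples_per_group: int = 50
    n_groups: int = 2
    block_dims: Sequence[int] = (200, 150, 50)          # cpg, transcript, mirna
    n_latent: int = 1
    planted_block_size: Sequence[int] = (10, 10, 5)     # per omic, per latent factor
    signal_sd: float = 3.0
    noise_sd: float = 1.0
    n_terms: int = 10
    frac_planted_term: float = 1.0
    n_prior_edges: int = 10
    missing_rate: float = 0.05
    seed: int = 0
    group_mean_spacing: float = 1.0

    def validate(self) -> None:
        dims = list(self.block_dims)
        sizes = list(self.planted_block_size)
        if len(dims) != 3 or len(sizes) != 3:
            raise ConfigurationError("block_dims and planted_block_size need one entry per omic")
        if min(dims) <= 0 or min(sizes) <= 0:
            raise ConfigurationError("all dimensions must be positive")
        for p, s in zip(dims, sizes):
            if s * self.n_latent > p:
                raise ConfigurationError(
                    f"planted_block_size x n_latent = {s * self.n_latent} exceeds block dimension {p}"
                )
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.n_samples_per_group < 2 or self.n_groups < 1 or self.n_latent < 1:
            raise ConfigurationError("need >=2 samples per group, >=1 group, >=1 latent factor")
        if self.signal_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("signal_sd and noise_sd must be nonnegative")
        if not 0 < self.frac_planted_term <= 1:
            raise ConfigurationError("frac_planted_term must be in (0, 1]")
        if self.n_terms < self.n_latent + 1:
            raise ConfigurationError("n_terms must cover the planted terms plus a noise term")
        if self.n_prior_edges < 1:
            raise ConfigurationError("n_prior_edges must be >= 1")


@dataclass
class SyntheticDataset:
    """Blocks, labels, annotation, priors, gene sets, and the planted truth."""

    blocks: Dict[str, OmicsBlock]
    labels: pd.Series                       # sample id -> group
    annotation: pd.DataFrame                # feature, omic_type, gene, is_tf
    priors: pd.DataFrame                    # source, target, edge_type, validated
    genesets: Dict[str, list]
    term_classes: Dict[str, str]
    truth: dict
    config: SimConfig

    def block_list(self) -> list:
        return [self.blocks[o] for o in ("cpg", "transcript", "mirna")]


def _feature_ids(omic: str, p: int) -> list:
    if omic == "cpg":
        return [f"cg{i + 1:07d}" for i in range(p)]
    if omic == "transcript":
        return [f"T{i + 1:04d}" for i in range(p)]
    return [f"hsa-mir-{i + 1}" for i in range(p)]


def generate_multiomics(config: SimConfig) -> SyntheticDataset:
    """Draw a full dataset (blocks, annotation, priors, gene sets) from the config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    omics = ("cpg", "transcript", "mirna")
    dims = dict(zip(omics, config.block_dims))
    sizes = dict(zip(omics, config.planted_block_size))

    n = config.n_samples_per_group * config.n_groups
    samples = [f"S{i + 1:04d}" for i in range(n)]
    groups = [f"group{g + 1}" for g in range(config.n_groups)]
    labels = pd.Series([groups[i // config.n_samples_per_group] for i in range(n)],
                       index=samples, name="group")

    # latent scores: group-specific means + unit noise
    offset = (config.n_groups - 1) / 2.0
    mu = {g: config.group_mean_spacing * (gi - offset) for gi, g in enumerate(groups)}
    Z = np.stack([np.array([mu[labels[s]] for s in samples]) + rng.standard_normal(n)
                  for _ in range(config.n_latent)])  # (n_latent, n)

    features = {o: _feature_ids(o, dims[o]) for o in omics}
    planted: Dict[str, dict] = {o: {} for o in omics}
    data: Dict[str, np.ndarray] = {}
    for o in omics:
        p = dims[o]
        X = rng.normal(0.0, config.noise_sd, size=(n, p))
        perm = rng.permutation(p)
        for h in range(config.n_latent):
            idx = perm[h * sizes[o]:(h + 1) * sizes[o]]
            beta = config.signal_sd * rng.choice([-1.0, 1.0], size=idx.size)
            X[:, idx] += np.outer(Z[h], beta)
            planted[o][h] = sorted(features[o][i] for i in idx)
        data[o] = X

    # CpG block to beta values in (0,1), then missingness
    B = 1.0 / (1.0 + np.exp(-data["cpg"]))
    if config.missing_rate > 0:
        mask = rng.random(B.shape) < config.missing_rate
        # never blank a full sample row
        full = mask.all(axis=1)
        mask[full, 0] = False
        B = np.where(mask, np.nan, B)
    data["cpg"] = B

    blocks = {o: OmicsBlock(pd.DataFrame(data[o], index=samples, columns=features[o]), o)
              for o in omics}

    annotation, gene_of = _build_annotation(config, rng, features, planted)
    genesets, term_classes, planted_terms, noise_term = _build_genesets(
        config, rng, annotation, planted, gene_of)
    priors, true_edges, decoy_edges = _build_priors(config, rng, annotation, planted)

    truth = {
        "planted": {o: {str(h): planted[o][h] for h in planted[o]} for o in omics},
        "planted_terms": planted_terms,
        "noise_term": noise_term,
        "true_prior_edges": true_edges,
        "decoy_prior_edges": decoy_edges,
    }
    return SyntheticDataset(blocks=blocks, labels=labels, annotation=annotation,
                            priors=priors, genesets=genesets, term_classes=term_classes,
                            truth=truth, config=config)


def _build_annotation(config, rng, features, planted):
    """Feature -> gene map: transcripts 1:1, miRNAs by name, CpGs to 1-2 genes.

    Planted CpGs are annotated to genes of planted transcripts of the same
    factor, so prior edges between planted features are annotation-consistent.
    """
    rows = []
    gene_of = {}
    for i, f in enumerate(features["transcript"]):
        gene_of[f] = f"GENE{i + 1:04d}"
    for f in features["mirna"]:
        gene_of[f] = "MIR" + f.replace("hsa-mir-", "").upper()

    # TF flags: a third of each planted transcript group plus ~10% of the rest
    tf = set()
    for h, feats in planted["transcript"].items():
        tf.update(feats[:max(1, math.ceil(len(feats) / 3))])
    noise_tr = [f for f in features["transcript"]
                if all(f not in planted["transcript"][h] for h in planted["transcript"])]
    n_extra = max(1, len(features["transcript"]) // 10)
    tf.update(rng.choice(noise_tr, size=min(n_extra, len(noise_tr)), replace=False).tolist())

    for f in features["transcript"]:
        rows.append((f, "transcript", gene_of[f], f in tf))
    for f in features["mirna"]:
        rows.append((f, "mirna", gene_of[f], False))

    planted_cpg_all = {h: set(planted["cpg"][h]) for h in planted["cpg"]}
    all_tr = features["transcript"]
    for f in features["cpg"]:
        factor = next((h for h, s in planted_cpg_all.items() if f in s), None)
        if factor is not None:
            pool = planted["transcript"][factor]
        else:
            pool = noise_tr if noise_tr else all_tr
        k = int(rng.integers(1, 3))  # 1 or 2 overlapping genes
        chosen = rng.choice(pool, size=min(k, len(pool)), replace=False)
        for t in chosen:
            rows.append((f, "cpg", gene_of[t], False))
    annotation = pd.DataFrame(rows, columns=["feature", "omic_type", "gene", "is_tf"])
    return annotation, gene_of


def _build_genesets(config, rng, annotation, planted, gene_of):
    universe = sorted(annotation["gene"].unique())
    planted_genes = {}
    for h in range(config.n_latent):
        genes = set()
        for o in planted:
            for f in planted[o][h]:
                genes.update(annotation.loc[annotation["feature"] == f, "gene"])
        planted_genes[h] = sorted(genes)
    noise_genes = sorted(set(universe) - set(g for gs in planted_genes.values() for g in gs))

    genesets = {}
    planted_terms = []
    for h in range(config.n_latent):
        pool = planted_genes[h]
        k = max(1, math.ceil(config.frac_planted_term * len(pool)))
        name = f"planted_term_{h + 1}"
        genesets[name] = sorted(rng.choice(pool, size=k, replace=False).tolist())
        planted_terms.append(name)
    noise_term = "noise_only_term"
    k = min(15, len(noise_genes))
    if k == 0:
        raise ConfigurationError("no noise-only genes available for the noise gene set")
    genesets[noise_term] = sorted(rng.choice(noise_genes, size=k, replace=False).tolist())
    for i in range(config.n_terms - config.n_latent - 1):
        k = int(rng.integers(10, 31))
        genesets[f"random_term_{i + 1}"] = sorted(
            rng.choice(universe, size=min(k, len(universe)), replace=False).tolist())
    term_classes = {t: TERM_CLASS_CYCLE[i % len(TERM_CLASS_CYCLE)]
                    for i, t in enumerate(sorted(genesets))}
    return genesets, term_classes, planted_terms, noise_term


def _prior_pairs(rng, a_feats, b_feats, count, forbid=()):
    """Draw up to `count` distinct unordered pairs (a from a_feats, b from b_feats)."""
    pairs = [(a, b) for a in a_feats for b in b_feats if a != b and (a, b) not in forbid]
    if not pairs:
        return []
    idx = rng.choice(len(pairs), size=min(count, len(pairs)), replace=False)
    return [pairs[i] for i in sorted(idx)]


def _build_priors(config, rng, annotation, planted):
    """True edges connect planted features of the same factor; decoys connect noise features."""
    ann = annotation.drop_duplicates("feature").set_index("feature")
    tf_tr = set(ann.index[(ann["omic_type"] == "transcript") & ann["is_tf"]])
    by_omic = {o: list(ann.index[ann["omic_type"] == o]) for o in ("cpg", "transcript", "mirna")}
    planted_all = {o: set(f for h in planted[o] for f in planted[o][h]) for o in planted}
    noise = {o: [f for f in by_omic[o] if f not in planted_all[o]] for o in by_omic}

    rows, true_edges, decoy_edges = [], [], []
    edge_rules = [
        ("cpg-transcript", "cpg", "transcript", None),
        ("cpg-mirna", "cpg", "mirna", None),
        ("mirna-transcript", "mirna", "transcript", None),
        ("tf_transcript-transcript", "transcript", "transcript", "tf"),
    ]
    per_type = config.n_prior_edges
    for etype, oa, ob, flag in edge_rules:
        # true: planted x planted within a factor
        cand_true = []
        for h in range(config.n_latent):
            a_feats = planted[oa][h]
            b_feats = planted[ob][h]
            if flag == "tf":
                a_feats = [f for f in a_feats if f in tf_tr]
            cand_true += [(a, b) for a in a_feats for b in b_feats if a != b]
        seen = set()
        cand_true = [p for p in cand_true if not (p in seen or seen.add(p))]
        idx = rng.choice(len(cand_true), size=min(per_type, len(cand_true)), replace=False)
        t_pairs = [cand_true[i] for i in sorted(idx)]
        a_noise = [f for f in noise[oa] if flag != "tf" or f in tf_tr]
        d_pairs = _prior_pairs(rng, a_noise, noise[ob], per_type, forbid=set(t_pairs))
        for s, t in t_pairs:
            rows.append((s, t, etype, True))
            true_edges.append([s, t, etype])
        for s, t in d_pairs:
            rows.append((s, t, etype, False))
            decoy_edges.append([s, t, etype])
    priors = pd.DataFrame(rows, columns=["source", "target", "edge_type", "validated"])
    return priors, true_edges, decoy_edges


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

GMT_SEP = "\t"


def write_gmt(genesets: Dict[str, list], path, descriptions: Dict[str, str] | None = None) -> None:
    """Write term<TAB>description<TAB>gene1<TAB>... lines; empty sets are rejected."""
    with open(path, "w") as fh:
        for term in genesets:
            genes = list(genesets[term])
            if not genes:
                raise ValidationError(f"gene set {term!r} is empty")
            desc = (descriptions or {}).get(term, "na")
            fh.write(GMT_SEP.join([term, desc, *genes]) + "\n")


def read_gmt(path) -> Dict[str, list]:
    genesets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(GMT_SEP)
            if len(parts) < 3:
                raise ValidationError(f"malformed GMT line: {line[:60]!r}")
            genesets[parts[0]] = parts[2:]
    return genesets


def write_fixtures(dataset: SyntheticDataset, directory) -> dict:
    """Emit the dataset as plain-text fixtures; returns the path map."""
    os.makedirs(directory, exist_ok=True)
    paths = {}
    for o, b in dataset.blocks.items():
        paths[o] = os.path.join(directory, f"block_{o}.tsv")
        b.to_tsv(paths[o])
    paths["labels"] = os.path.join(directory, "labels.tsv")
    write_table_tsv(dataset.labels.rename_axis("sample_id").reset_index(), paths["labels"])
    paths["annotation"] = os.path.join(directory, "annotation.tsv")
    write_table_tsv(dataset.annotation, paths["annotation"])
    paths["priors"] = os.path.join(directory, "priors.tsv")
    write_table_tsv(dataset.priors, paths["priors"])
    paths["genesets"] = os.path.join(directory, "genesets.gmt")
    write_gmt(dataset.genesets, paths["genesets"], descriptions=dataset.term_classes)
    paths["term_classes"] = os.path.join(directory, "term_classes.tsv")
    write_table_tsv(pd.DataFrame(sorted(dataset.term_classes.items()),
                                 columns=["term", "term_class"]), paths["term_classes"])
    paths["truth"] = os.path.join(directory, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
    paths["config"] = os.path.join(directory, "config.json")
    cfg = asdict(dataset.config)
    cfg["block_dims"] = list(cfg["block_dims"])
    cfg["planted_block_size"] = list(cfg["planted_block_size"])
    with open(paths["config"], "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
    return paths


def read_fixtures(directory) -> SyntheticDataset:
    """Round-trip reader for :func:`write_fixtures` output."""
    with open(os.path.join(directory, "config.json")) as fh:
        cfg = json.load(fh)
    config = SimConfig(**cfg)
    blocks = {o: OmicsBlock.from_tsv(os.path.join(directory, f"block_{o}.tsv"), o)
              for o in ("cpg", "transcript", "mirna")}
    lab = read_table_tsv(os.path.join(directory, "labels.tsv"))
    labels = pd.Series(lab["group"].to_numpy(), index=lab["sample_id"].to_numpy(), name="group")
    annotation = read_table_tsv(os.path.join(directory, "annotation.tsv"))
    annotation["is_tf"] = annotation["is_tf"].astype(bool)
    priors = read_table_tsv(os.path.join(directory, "priors.tsv"))
    priors["validated"] = priors["validated"].astype(bool)
    genesets = read_gmt(os.path.join(directory, "genesets.gmt"))
    tc = read_table_tsv(os.path.join(directory, "term_classes.tsv"))
    term_classes = dict(zip(tc["term"], tc["term_class"]))
    with open(os.path.join(directory, "truth.json")) as fh:
        truth = json.load(fh)
    truth["true_prior_edges"] = [list(e) for e in truth["true_prior_edges"]]
    truth["decoy_prior_edges"] = [list(e) for e in truth["decoy_prior_edges"]]
    return SyntheticDataset(blocks=blocks, labels=labels, annotation=annotation,
                            priors=priors, genesets=genesets, term_classes=term_classes,
                            truth=truth, config=config)
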