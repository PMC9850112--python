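"""Mutual-information network reconstruction calibrated on regulatory priors.

All cross-omic feature pairs of the four admissible edge types
(CpG-transcript, CpG-miRNA, TF-transcript-transcript, miRNA-transcript) are
scored by a plug-in mutual information estimator over equal-frequency bins.
Known regulatory interactions (the prior table) provide, per edge type, a
median MI used as the retention threshold; the median is preferred over the
mean so single outliers do not dominate.  When two-sample Kolmogorov-Smirnov
tests find no significant difference between the per-type MI distributions,
one unified threshold (the minimum per-type median) is applied instead,
relaxing retention uniformly.  Edges with MI >= their threshold survive
("lower than the median" is removed, so ties survive).  CpG-CpG and non-TF
transcript-transcript pairs are never scored.

One MI estimator (equal-frequency binning with nbins = ceil(n^(1/3)),
plug-in entropies, natural log) is used both for the all-pairs scores and
for the prior calibration, so no cross-estimator bias enters the thresholds.
"""
from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .blocks import OmicsBlock, check_aligned
from .exceptions import DegenerateDataError, ThresholdError, ValidationError

logger = logging.getLogger(__name__)

EDGE_TYPES = ("cpg-transcript", "cpg-mirna", "tf_transcript-transcript", "mirna-transcript")


def edge_type_for(omic_a: str, tf_a: bool, omic_b: str, tf_b: bool) -> Optional[str]:
    """The admissible edge type of a feature pair, or None if the pair is not scored."""
    pair = frozenset((omic_a, omic_b))
    if pair == frozenset(("cpg", "transcript")):
        return "cpg-transcript"
    if pair == frozenset(("cpg", "mirna")):
        return "cpg-mirna"
    if pair == frozenset(("mirna", "transcript")):
        return "mirna-transcript"
    if pair == frozenset(("transcript",)) and (tf_a or tf_b):
        return "tf_transcript-transcript"
    return None


@dataclass
class RegulatoryPrior:
    """Typed prior regulatory edges (source, target, edge_type, validated)."""

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"source", "target", "edge_type"}
        if not need.issubset(self.edges.columns):
            raise ValidationError(f"prior table needs columns {sorted(need)}")
        bad = set(self.edges["edge_type"]) - set(EDGE_TYPES)
        if bad:
            raise ValidationError(f"unknown edge types: {sorted(bad)}")
        if (self.edges["source"] == self.edges["target"]).any():
            raise ValidationError("self-edges are not allowed in the prior table")

    def check_types(self, annotation: pd.DataFrame) -> None:
        """Verify each edge's type against the endpoints' omic types and TF flags."""
        ann = annotation.drop_duplicates("feature").set_index("feature")
        for _, row in self.edges.iterrows():
            for end in (row["source"], row["target"]):
                if end not in ann.index:
                    raise ValidationError(f"prior edge endpoint {end!r} not in annotation")
            a, b = ann.loc[row["source"]], ann.loc[row["target"]]
            expected = edge_type_for(a["omic_type"], bool(a["is_tf"]),
                                     b["omic_type"], bool(b["is_tf"]))
            if expected != row["edge_type"]:
                raise ValidationError(
                    f"edge {row['source']}-{row['target']} typed {row['edge_type']!r} "
                    f"but endpoints imply {expected!r}")


def default_nbins(n: int) -> int:
    """ceil(n^(1/3)), never below 2."""
    return max(2, math.ceil(n ** (1.0 / 3.0) - 1e-9))


def discretize_equal_frequency(x: Sequence[float], nbins: int) -> np.ndarray:
    """Equal-frequency binning: bin sizes differ by at most one, ties stable.

    Points are assigned by their position in the stable sort of the vector,
    so tied values fall in bins by original order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if nbins < 2:
        raise ValidationError("nbins must be >= 2")
    if n < nbins:
        raise ValidationError("need at least nbins observations")
    if np.unique(x).size == 1:
        logger.warning("constant vector: all observations fall in one bin")
        return np.zeros(n, dtype=int)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * nbins) // n


def mutual_information(x: Sequence[float], y: Sequence[float],
                       nbins: Optional[int] = None) -> float:
    """Plug-in MI (nats) from the joint table of equal-frequency-binned x, y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValidationError("need at least 4 observations")
    if nbins is None:
        nbins = default_nbins(n)
    cx = discretize_equal_frequency(x, nbins)
    cy = discretize_equal_frequency(y, nbins)
    return _mi_from_codes(cx, cy, nbins)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, nbins: int) -> float:
    n = len(cx)
    joint = np.zeros((nbins, nbins))
    np.add.at(joint, (cx, cy), 1.0)
    joint /= n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / np.outer(px, py)[nz]
    return float(max(0.0, np.sum(joint[nz] * np.log(ratio))))


def pairwise_mi(blocks: Sequence[OmicsBlock], tf_features: Iterable[str] = (),
                nbins: Optional[int] = None) -> pd.DataFrame:
    """MI for every unordered cross pair forming an admissible edge type.

    Returns a DataFrame (source, target, edge_type, mi).  CpG-CpG, miRNA-miRNA
    and non-TF transcript pairs are excluded.
    """
    blocks = list(blocks)
    check_aligned(blocks)
    tf = set(tf_features)
    feats = []
    for b in blocks:
        X = b.values
        if np.isnan(X).any():
            raise ValidationError("blocks must be imputed before MI estimation")
        for i, f in enumerate(b.feature_ids):
            feats.append((f, b.omic_type, f in tf, X[:, i]))
    if len(feats) < 2:
        raise ValidationError("need at least 2 features")
    n = len(feats[0][3])
    if nbins is None:
        nbins = default_nbins(n)
    codes = {f: discretize_equal_frequency(v, nbins) for f, _, _, v in feats}
    rows = []
    for (fa, oa, ta, _), (fb, ob, tb, _) in itertools.combinations(feats, 2):
        etype = edge_type_for(oa, ta, ob, tb)
        if etype is None:
            continue
        rows.append((fa, fb, etype, _mi_from_codes(codes[fa], codes[fb], nbins)))
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "mi"])


def prior_edge_thresholds(priors: RegulatoryPrior, blocks: Sequence[OmicsBlock],
                          nbins: Optional[int] = None) -> Dict[str, float]:
    """Per edge type, the median MI over the prior edges present in the data."""
    blocks = list(blocks)
    check_aligned(blocks)
    col = {}
    for b in blocks:
        X = b.values
        for i, f in enumerate(b.feature_ids):
            col[f] = X[:, i]
    n = blocks[0].n_samples
    if nbins is None:
        nbins = default_nbins(n)
    by_type: Dict[str, list] = {}
    for _, row in priors.edges.iterrows():
        s, t = row["source"], row["target"]
        if s not in col or t not in col:
            continue
        by_type.setdefault(row["edge_type"], []).append(
            mutual_information(col[s], col[t], nbins))
    if not by_type:
        raise ThresholdError("no prior edge has both endpoints in the data")
    for etype in EDGE_TYPES:
        if etype not in by_type:
            logger.info("no usable prior edge of type %s; no threshold for it", etype)
    return {etype: float(np.median(v)) for etype, v in by_type.items()}


def ks_unify_thresholds(mi_by_type: Dict[str, np.ndarray],
                        medians: Dict[str, float],
                        alpha: float = 0.05):
    """Decide between per-type thresholds and one unified threshold.

    Two-sample KS tests compare the all-pairs MI distributions of every pair
    of edge types (types with < 2 values are excluded, with a log entry).
    If no pair differs significantly at alpha, the unified threshold is the
    minimum per-type median; otherwise each type keeps its own median.

    Returns (thresholds: edge_type -> float, mode: 'unified'|'per-type',
    ks_table: DataFrame).
    """
    usable = {t: np.asarray(v, dtype=float) for t, v in mi_by_type.items()
              if len(v) >= 2}
    for t in mi_by_type:
        if t not in usable:
            logger.info("edge type %s has <2 MI values; excluded from KS testing", t)
    if len(usable) < 2:
        raise ValidationError("need at least 2 edge types with MI distributions")
    rows = []
    any_sig = False
    for a, b in itertools.combinations(sorted(usable), 2):
        res = stats.ks_2samp(usable[a], usable[b])
        sig = res.pvalue < alpha
        any_sig = any_sig or sig
        rows.append({"type_a": a, "type_b": b, "statistic": float(res.statistic),
                     "p": float(res.pvalue), "significant": bool(sig)})
    ks_table = pd.DataFrame(rows)
    present = {t for t in mi_by_type} | set(medians)
    if any_sig:
        mode = "per-type"
        thresholds = dict(medians)
    else:
        mode = "unified"
        lo = min(medians.values())
        thresholds = {t: lo for t in present}
    return thresholds, mode, ks_table


def build_network(pair_mi: pd.DataFrame, thresholds: Dict[str, float],
                  node_meta: pd.DataFrame, functional: Iterable[str] = (),
                  mode: str = "per-type") -> nx.Graph:
    """Retain edges with MI >= the threshold of their type; annotate nodes.

    node_meta is indexed by feature with columns omic_type, is_tf and
    optionally logfc.  Isolated nodes are dropped unless flagged functional.
    """
    missing = set(pair_mi["edge_type"]) - set(thresholds)
    if missing:
        raise ValidationError(f"no threshold for edge types {sorted(missing)}")
    g = nx.Graph(threshold_mode=mode,
                 thresholds=json.dumps(thresholds, sort_keys=True))
    functional = set(functional)
    keep = pair_mi[pair_mi.apply(lambda r: r["mi"] >= thresholds[r["edge_type"]], axis=1)]
    for _, row in keep.iterrows():
        g.add_edge(row["source"], row["target"], mi=float(row["mi"]),
                   edge_type=row["edge_type"])
    for f in functional:
        if f not in g and f in node_meta.index:
            g.add_node(f)
    for node in g.nodes:
        if node in node_meta.index:
            meta = node_meta.loc[node]
            g.nodes[node]["omic_type"] = str(meta["omic_type"])
            g.nodes[node]["is_tf"] = bool(meta["is_tf"])
            if "logfc" in node_meta.columns and pd.notna(meta.get("logfc")):
                g.nodes[node]["logfc"] = float(meta["logfc"])
        g.nodes[node]["functional"] = node in functional
    return g


def dpi_filter(network: nx.Graph, tolerance: float = 0.0) -> nx.Graph:
    """Data-processing-inequality pruning: in every triangle, mark the
    minimum-MI edge for removal when its MI < (1 - tolerance) * min(other two);
    all marks are taken on the original weights, then removed together."""
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    g = network.copy()
    to_remove = set()
    for tri in _triangles(g):
        edges = [tuple(sorted(e)) for e in itertools.combinations(tri, 2)]
        weights = [g.edges[e]["mi"] for e in edges]
        i = int(np.argmin(weights))
        others = [w for j, w in enumerate(weights) if j != i]
        if weights[i] < (1 - tolerance) * min(others):
            to_remove.add(edges[i])
    g.remove_edges_from(to_remove)
    return g


def _triangles(g: nx.Graph):
    seen = set()
    for u in g:
        for v, w in itertools.combinations(sorted(g[u]), 2):
            if g.has_edge(v, w):
                tri = tuple(sorted((u, v, w)))
                if tri not in seen:
                    seen.add(tri)
                    yield tri


def functional_subgraph(network: nx.Graph, functional: Iterable[str],
                        first_neighbors_only: bool = False) -> nx.Graph:
    """Components containing a functional feature; optionally restrict to the
    functional features and their direct neighbours (induced edges)."""
    functional = set(functional)
    if not functional:
        raise ValidationError("functional feature set is empty")
    present = functional & set(network.nodes)
    if not present:
        logger.info("no functional feature in the network; returning empty subgraph")
        return nx.Graph(network.graph)
    keep = set()
    for comp in nx.connected_components(network):
        if comp & present:
            keep |= comp
    if first_neighbors_only:
        near = set(present)
        for f in present:
            near |= set(network[f])
        keep &= near
    return network.subgraph(keep).copy()


def node_metrics(network: nx.Graph) -> pd.DataFrame:
    """Per-node degree and normalised shortest-path betweenness (unit lengths)."""
    deg = dict(network.degree())
    btw = nx.betweenness_centrality(network, normalized=True)
    nodes = sorted(network.nodes)
    return pd.DataFrame({"degree": [deg[v] for v in nodes],
                         "betweenness": [btw[v] for v in nodes]},
                        index=pd.Index(nodes, name="feature"))


def group_logfc(block: OmicsBlock, group_samples: Sequence[str],
                reference_samples: Sequence[str]) -> pd.DataFrame:
    """Per-feature logFC (mean group - mean reference) with Welch p and BH q.

    Data are assumed on a log scale.  Features whose variance is degenerate
    in both groups get p = 1 and are flagged.
    """
    from statsmodels.stats.multitest import multipletests

    ga = block.subset_samples(group_samples).values
    gb = block.subset_samples(reference_samples).values
    if ga.shape[0] < 2 or gb.shape[0] < 2:
        raise ValidationError("both groups need at least 2 samples")
    logfc = ga.mean(axis=0) - gb.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(ga, gb, axis=0, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"logfc": logfc, "p": p, "q": q, "degenerate": degenerate},
                        index=pd.Index(block.feature_ids, name="feature"))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_sif(network: nx.Graph, path) -> None:
    """source <TAB> edge_type <TAB> target, one line per edge."""
    with open(path, "w") as fh:
        for u, v, d in sorted(network.edges(data=True)):
            fh.write(f"{u}\t{d.get('edge_type', 'mi')}\t{v}\n")


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)


def write_threshold_sidecar(thresholds: Dict[str, float], mode: str,
                            ks_table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        json.dump({"mode": mode, "thresholds": thresholds,
                   "ks_tests": ks_table.to_dict(orient="records")},
                  fh, indent=1, sort_keys=True)
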