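"""Cross-omic functional enrichment analytics.

Features selected by the multi-block fit (CpG probes, transcripts, miRNA
precursors) are first mapped to a common gene vocabulary: transcripts map
one-to-one, miRNAs by direct name (hsa-mir-34b -> MIR34B), and CpG probes
expand to every overlapping gene of their annotation.  Mapped gene sets are
tested for over-representation against a gene-set database (hypergeometric
upper tail, Benjamini-Hochberg FDR), and rank-based gene set enrichment
(GSEA) with a permutation null provides an expression-only counterpart.
Similarity and structure among the enriched functions are quantified with
the Jaccard index, UpSet-style intersection counts, component-sharing
clusters, and an exclusive-category Fisher test with Bonferroni control.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateDataError, ValidationError
from .synthetic_data import read_gmt, write_gmt  # re-exported format helpers

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetDB", "EnrichmentResult", "map_features_to_genes", "ora",
    "gsea_preranked", "jaccard", "cluster_functions_by_components",
    "exclusive_category_test", "intersection_summary", "read_gmt", "write_gmt",
]


@dataclass
class GeneSetDB:
    """Term -> gene sets, an optional term -> class map, and the gene universe."""

    sets: Dict[str, frozenset]
    classes: Dict[str, str] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.sets = {t: frozenset(g) for t, g in self.sets.items()}
        for t, g in self.sets.items():
            if not g:
                raise ValidationError(f"gene set {t!r} is empty")
        if not self.universe:
            self.universe = frozenset(g for s in self.sets.values() for g in s)
        else:
            self.universe = frozenset(self.universe)

    @classmethod
    def from_gmt(cls, path, classes: Optional[Dict[str, str]] = None,
                 universe: Optional[Iterable[str]] = None) -> "GeneSetDB":
        return cls(sets=read_gmt(path), classes=dict(classes or {}),
                   universe=frozenset(universe or ()))


@dataclass
class EnrichmentResult:
    """Per-term over-representation statistics."""

    term: str
    p: float
    fdr: float
    hits: frozenset
    query_size: int
    term_size: int
    universe_size: int
    significant: bool
    components: frozenset = frozenset()
    dataset: Optional[str] = None
    term_class: Optional[str] = None


def map_features_to_genes(features: Iterable[str], annotation: pd.DataFrame) -> set:
    """Union of genes reached by the features through the annotation table.

    CpG probes may contribute several genes each; features absent from the
    annotation are logged and skipped.
    """
    features = list(features)
    if not features:
        return set()
    known = set(annotation["feature"])
    missing = [f for f in features if f not in known]
    if missing:
        logger.info("%d features missing from annotation (e.g. %s)", len(missing), missing[:3])
    sub = annotation[annotation["feature"].isin(set(features) & known)]
    genes = set(sub["gene"])
    if not genes:
        logger.warning("no feature could be mapped to a gene")
    return genes


def ora(query: Iterable[str], db: GeneSetDB, alpha: float = 0.01,
        components: Dict[str, frozenset] | None = None,
        dataset: Optional[str] = None) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of the query against every term.

    p = P(X >= k) with k hits among a query of size m, drawn without
    replacement from a universe of size N containing K term genes; BH
    adjustment across terms; significant means adjusted p < alpha.

    ``components`` optionally carries per-term contributing component index
    sets (attached to the results for downstream clustering).
    """
    query = set(query)
    dropped = query - db.universe
    if dropped:
        logger.info("dropping %d query genes outside the universe", len(dropped))
    query &= db.universe
    if not query:
        raise ValidationError("empty query after restricting to the universe")
    N = len(db.universe)
    m = len(query)
    terms = sorted(db.sets)
    pvals, rows = [], []
    for t in terms:
        term_genes = db.sets[t] & db.universe
        K = len(term_genes)
        hits = frozenset(query & term_genes)
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, m)) if K else 1.0
        pvals.append(min(p, 1.0))
        rows.append((t, hits, K))
    fdr = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for (t, hits, K), p, q in zip(rows, pvals, fdr):
        results.append(EnrichmentResult(
            term=t, p=p, fdr=float(q), hits=hits, query_size=m, term_size=K,
            universe_size=N, significant=bool(q < alpha),
            components=frozenset((components or {}).get(t, frozenset())),
            dataset=dataset, term_class=db.classes.get(t)))
    results.sort(key=lambda r: (r.p, r.term))
    return results


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _enrichment_score(abs_scores: np.ndarray, hit: np.ndarray) -> float:
    """Running-sum enrichment score: hits step +|s|/NR, misses -1/(n - n_hit)."""
    nr = float(abs_scores[hit].sum())
    n = len(abs_scores)
    nh = int(hit.sum())
    if nr == 0 or nh == 0 or nh == n:
        return np.nan
    steps = np.where(hit, abs_scores / nr, -1.0 / (n - nh))
    run = np.cumsum(steps)
    return float(run[int(np.argmax(np.abs(run)))])


def gsea_preranked(scores: pd.Series, db: GeneSetDB, n_perm: int = 1000,
                   seed: int = 0, min_size: int = 1) -> pd.DataFrame:
    """Weighted (exponent 1) preranked GSEA with a gene-label permutation null.

    ``scores`` maps genes to a real ranking statistic; genes are sorted by
    decreasing score.  For every term with at least ``min_size`` ranked
    members, the enrichment score ES is the maximum deviation of the running
    sum, NES = ES / mean(|null ES| of matching sign), and p is the same-sign
    permutation tail probability.  Every term is reported regardless of p.
    """
    if scores.index.has_duplicates:
        raise ValidationError("duplicate gene names in the ranking")
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("ranking scores must be finite")
    order = np.lexsort((scores.index.to_numpy(), -vals))
    genes = scores.index.to_numpy()[order]
    w = np.abs(vals[order])
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    rows = []
    for term in sorted(db.sets):
        members = [g for g in db.sets[term] if g in pos]
        if len(members) < min_size or len(members) >= n:
            logger.info("skipping term %r with %d ranked members", term, len(members))
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[pos[g] for g in members]] = True
        es = _enrichment_score(w, hit)
        null = np.empty(n_perm)
        size = len(members)
        for b in range(n_perm):
            hb = np.zeros(n, dtype=bool)
            hb[rng.choice(n, size=size, replace=False)] = True
            null[b] = _enrichment_score(w, hb)
        null = null[np.isfinite(null)]
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same.size:
            nes = es / float(np.mean(np.abs(same)))
            p = (1.0 + float(np.sum(np.abs(same) >= abs(es)))) / (1.0 + same.size)
        else:
            nes, p = np.nan, 1.0
        rows.append({"term": term, "es": es, "nes": nes, "p": p, "size": size})
    return pd.DataFrame(rows, columns=["term", "es", "nes", "p", "size"])


# ---------------------------------------------------------------------------
# set similarity and structure
# ---------------------------------------------------------------------------

def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """|A n B| / |A u B|; undefined (error) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise DegenerateDataError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


@dataclass
class FunctionClusters:
    clusters: List[set]
    unclustered: set

    def cluster_of(self, term: str) -> Optional[int]:
        for i, c in enumerate(self.clusters):
            if term in c:
                return i
        return None


def cluster_functions_by_components(results: Sequence[EnrichmentResult],
                                    tau: float = 1.0) -> FunctionClusters:
    """Cluster enriched terms by the overlap of their contributing components.

    Two terms are linked when the Jaccard index of their component index
    sets is >= tau; clusters are the connected components of that graph.
    Terms linked to nothing come back as singleton clusters and are also
    listed in ``unclustered``.
    """
    g = nx.Graph()
    terms = [r for r in results if r.components]
    g.add_nodes_from(r.term for r in terms)
    for a, b in itertools.combinations(terms, 2):
        if jaccard(a.components, b.components) >= tau:
            g.add_edge(a.term, b.term)
    clusters = [set(c) for c in nx.connected_components(g)]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    unclustered = {t for c in clusters if len(c) == 1 for t in c}
    return FunctionClusters(clusters=clusters, unclustered=unclustered)


def exclusive_category_test(enrichments: Dict[str, Sequence[EnrichmentResult]],
                            classes: Dict[str, str], alpha: float = 0.05) -> pd.DataFrame:
    """Class bias of terms enriched in exactly one dataset (Fisher + Bonferroni).

    For each (class, dataset) pair the 2x2 table crosses membership in the
    class with membership in the dataset, over all exclusive terms; tested
    two-sided, Bonferroni-adjusted over all pairs; significant at adjusted
    p < 0.05.
    """
    if len(enrichments) < 2:
        raise ValidationError("need enrichment results from at least 2 datasets")
    sig = {d: {r.term for r in rs if r.significant} for d, rs in enrichments.items()}
    counts = {}
    for d, terms in sig.items():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    exclusive = {d: {t for t in terms if counts[t] == 1} for d, terms in sig.items()}
    if not any(exclusive.values()):
        logger.info("no exclusively enriched term; nothing to test")
        return pd.DataFrame(columns=["term_class", "dataset", "a", "b", "c", "d",
                                     "p", "p_bonferroni", "significant"])
    classed = {d: {t for t in ts if t in classes} for d, ts in exclusive.items()}
    all_classes = sorted({classes[t] for ts in classed.values() for t in ts})
    rows = []
    for cls in all_classes:
        for d in sorted(enrichments):
            in_d = classed[d]
            in_others = {t for d2, ts in classed.items() if d2 != d for t in ts}
            a = sum(1 for t in in_d if classes[t] == cls)
            b = len(in_d) - a
            c = sum(1 for t in in_others if classes[t] == cls)
            dd = len(in_others) - c
            _, p = stats.fisher_exact([[a, b], [c, dd]], alternative="two-sided")
            rows.append({"term_class": cls, "dataset": d, "a": a, "b": b, "c": c, "d": dd,
                         "p": float(p)})
    out = pd.DataFrame(rows)
    n_tests = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * n_tests, 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def intersection_summary(enrichments: Dict[str, Sequence[EnrichmentResult]],
                         significant_only: bool = True):
    """UpSet-style counting: term x dataset membership and per-pattern counts.

    Returns (membership, counts): a boolean DataFrame terms x datasets, and a
    Series keyed by the tuple of datasets forming each non-empty exact
    intersection pattern, valued by the number of terms showing it.
    """
    sets = {d: {r.term for r in rs if (r.significant or not significant_only)}
            for d, rs in enrichments.items()}
    terms = sorted(set().union(*sets.values())) if sets else []
    datasets = sorted(sets)
    membership = pd.DataFrame({d: [t in sets[d] for t in terms] for d in datasets},
                              index=terms)
    patterns = {}
    for t in terms:
        key = tuple(d for d in datasets if t in sets[d])
        patterns[key] = patterns.get(key, 0) + 1
    counts = pd.Series(list(patterns.values()),
                       index=pd.Index(list(patterns.keys()), dtype=object,
                                      tupleize_cols=False),
                       dtype=int).sort_values(ascending=False)
    return membership, counts
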