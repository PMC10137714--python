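"""Regulatory-network assembly, hub ranking, ORA, and preranked GSEA.

An edge regulator->gene is retained when three conditions hold at once:
a duplex hit links the pair, the two features are differentially expressed
in opposite directions, and their expression is negatively correlated
across the shared samples. With n = 3 per group, correlation p-values carry
little information, so only the sign is required by default; a p cutoff is
available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .duplex import DuplexHit


def correlate(x: Sequence[float], y: Sequence[float]
              ) -> Tuple[float, float, bool]:
    """Pearson r with two-sided t-distribution p.

    Returns (r, p, defined). A constant vector makes r undefined; the flag
    is then False and r, p are NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan"), False
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), True


@dataclass(frozen=True)
class NetworkEdge:
    regulator_id: str
    target_gene_id: str
    mfe: float
    pearson_r: float
    corr_p: float
    retained: bool


def build_network(de_regulators: pd.DataFrame, de_mrna: pd.DataFrame,
                  duplex_hits: Sequence[DuplexHit],
                  expr_regulators: pd.DataFrame, expr_mrna: pd.DataFrame,
                  corr_p_max: Optional[float] = None
                  ) -> Tuple[List[NetworkEdge], pd.DataFrame]:
    """Assemble anti-correlation edges from duplex hits among DE features.

    ``de_regulators``/``de_mrna`` are nb_exact_test outputs (indexed by
    feature); expression tables are feature x sample with shared sample
    columns. Returns (edges, degree table over retained edges).
    """
    shared = [s for s in expr_regulators.columns if s in expr_mrna.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples for correlation")
    edges: List[NetworkEdge] = []
    for hit in duplex_hits:
        reg, gene = hit.regulator_id, hit.gene_id
        if reg not in de_regulators.index or gene not in de_mrna.index:
            continue
        dreg = de_regulators.loc[reg]
        dgene = de_mrna.loc[gene]
        if reg not in expr_regulators.index or gene not in expr_mrna.index:
            continue
        r, p, defined = correlate(
            expr_regulators.loc[reg, shared].to_numpy(),
            expr_mrna.loc[gene, shared].to_numpy())
        opposite = (bool(dreg["significant"]) and bool(dgene["significant"])
                    and dreg["direction"] != dgene["direction"])
        retained = bool(opposite and defined and r < 0)
        if retained and corr_p_max is not None:
            retained = p <= corr_p_max
        edges.append(NetworkEdge(reg, gene, hit.mfe,
                                 r if defined else float("nan"),
                                 p if defined else float("nan"), retained))
    degree: Dict[str, int] = {}
    for e in edges:
        if e.retained:
            degree[e.regulator_id] = degree.get(e.regulator_id, 0) + 1
            degree[e.target_gene_id] = degree.get(e.target_gene_id, 0) + 1
    degree_table = (pd.DataFrame(sorted(degree.items()),
                                 columns=["node", "degree"])
                    .sort_values(["degree", "node"], ascending=[False, True])
                    .reset_index(drop=True))
    return edges, degree_table


def edges_to_table(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.regulator_id, e.target_gene_id, e.mfe, e.pearson_r, e.corr_p,
          e.retained) for e in edges],
        columns=["regulator_id", "target_gene_id", "mfe", "pearson_r",
                 "corr_p", "retained"])


def hub_nodes(edges: Sequence[NetworkEdge], k: int) -> List[Tuple[str, int]]:
    """Top-k nodes of the retained network by degree, ties by node id."""
    degree: Dict[str, int] = {}
    for e in edges:
        if e.retained:
            degree[e.regulator_id] = degree.get(e.regulator_id, 0) + 1
            degree[e.target_gene_id] = degree.get(e.target_gene_id, 0) + 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets from a GMT file (term, description, genes...)."""
    sets: Dict[str, List[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def ora_hypergeometric(query_genes: Iterable[str], universe: Iterable[str],
                       gmt_sets: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Over-representation analysis: hypergeometric upper-tail p per term."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")
    rows = []
    for term in sorted(gmt_sets):
        members = set(gmt_sets[term]) & universe
        overlap = len(members & query)
        # P(X >= overlap), X ~ Hypergeom(M=|U|, K=|term|, n=|query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe),
                                     len(members), len(query)))
        rows.append({"term_id": term, "term_size": len(members),
                     "overlap": overlap, "p_value": min(1.0, p)})
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.set_index("term_id")


def enrichment_score(ranked_genes: Sequence[str], scores: Sequence[float],
                     gene_set: Iterable[str], weight: float = 1.0
                     ) -> Tuple[float, np.ndarray]:
    """Classic running-sum enrichment score for one set.

    Hits advance by |score|^weight (normalized to unit total); misses
    decrement by 1/(N - Nh). ES is the signed extremum of the running sum.
    """
    members = set(gene_set)
    n = len(ranked_genes)
    is_hit = np.array([g in members for g in ranked_genes])
    nh = int(is_hit.sum())
    if nh == 0 or nh == n:
        raise ValueError("gene set empty (or full) on the ranked list")
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    hit_mass = np.where(is_hit, w, 0.0)
    total = hit_mass.sum()
    if total == 0:  # all hit scores zero: fall back to equal increments
        hit_mass = is_hit.astype(float)
        total = hit_mass.sum()
    steps = hit_mass / total - (~is_hit) / (n - nh)
    running = np.cumsum(steps)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def gsea_preranked(ranked: pd.Series, gmt_sets: Mapping[str, Sequence[str]],
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked`` maps gene -> score (any order; sorted descending internally).
    NES divides ES by the mean |permuted ES| of the matching sign; the
    permutation p is the fraction of same-signed permuted ES at least as
    extreme. BH FDR across terms.
    """
    ranked = ranked.sort_values(ascending=False)
    if ranked.index.has_duplicates:
        raise ValueError("duplicate gene ids in ranked list")
    if not np.isfinite(ranked.to_numpy()).all():
        raise ValueError("non-finite scores")
    genes = list(ranked.index)
    scores = ranked.to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for term in sorted(gmt_sets):
        members = [g for g in gmt_sets[term] if g in ranked.index]
        if not members or len(members) >= len(genes):
            continue  # skipped with warning semantics: absent from output
        es, _ = enrichment_score(genes, scores, members, weight)
        k = len(members)
        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.choice(len(genes), size=k, replace=False)
            perm_set = [genes[i] for i in perm]
            perm_es[b], _ = enrichment_score(genes, scores, perm_set, weight)
        same_sign = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 \
            else perm_es
        if len(same_sign):
            p = (np.sum(np.abs(same_sign) >= abs(es)) + 1) / (len(same_sign) + 1)
            nes = es / np.mean(np.abs(same_sign))
        else:
            p, nes = 1.0 / (n_perm + 1), np.sign(es) * abs(es)
        rows.append({"term_id": term, "term_size": k, "es": es,
                     "nes": float(nes), "p_value": float(p)})
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.set_index("term_id")
    return result
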