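"""Lifestyle- and function-association statistics.

The discrimination score compares the within-cluster balance of secreted vs
non-secreted proteins between two lifestyles:

    d(a, b, g) = (a_sp - a_nosp)/(a_sp + a_nosp) - (b_sp - b_nosp)/(b_sp + b_nosp)

for cluster g, bounded in [-2, 2]; values near the extremes mean possession
of a signal peptide separates the two lifestyles in that cluster.  GO-term
enrichment uses one-sided Fisher tests against the pooled background after
annotations are closed upward over is_a edges.  The multivariate two-sample
comparison is an energy-distance permutation test.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import cdist

from .types import DiscriminationResult, EnrichmentResult

log = logging.getLogger(__name__)


def discrimination_score(a_sp: int, a_nosp: int, b_sp: int, b_nosp: int) -> float:
    """d(a, b, g); raises on an empty lifestyle group."""
    if a_sp + a_nosp < 1 or b_sp + b_nosp < 1:
        raise ValueError("both lifestyle groups must be nonempty")
    return (a_sp - a_nosp) / (a_sp + a_nosp) - (b_sp - b_nosp) / (b_sp + b_nosp)


def fisher_exact_2x2(table, sided: str = "two_tailed") -> float:
    """Fisher's exact test on a 2x2 table.

    ``one_greater`` is the upper hypergeometric tail of table[0][0];
    ``two_tailed`` sums the probabilities of all tables with the observed
    margins that are no more probable than the observed one.
    """
    alternative = {"one_greater": "greater", "two_tailed": "two-sided"}[sided]
    _, p = sps.fisher_exact(np.asarray(table, dtype=int), alternative=alternative)
    return float(min(max(p, np.nextafter(0, 1)), 1.0))


def cluster_discrimination(
    cluster_id: str,
    lifestyle_a,
    lifestyle_b,
    sp_by_lifestyle: Mapping[int, tuple[int, int]],
) -> Optional[DiscriminationResult]:
    """DiscriminationResult for one cluster, or None when a group is empty.

    ``sp_by_lifestyle`` maps lifestyle -> (n_with_sp, n_without_sp) over the
    cluster's members.
    """
    a_sp, a_nosp = sp_by_lifestyle.get(int(lifestyle_a), (0, 0))
    b_sp, b_nosp = sp_by_lifestyle.get(int(lifestyle_b), (0, 0))
    if a_sp + a_nosp < 1 or b_sp + b_nosp < 1:
        log.debug("cluster %s skipped: empty lifestyle group", cluster_id)
        return None
    d = discrimination_score(a_sp, a_nosp, b_sp, b_nosp)
    p = fisher_exact_2x2([[a_sp, a_nosp], [b_sp, b_nosp]], sided="two_tailed")
    return DiscriminationResult(cluster_id, lifestyle_a, lifestyle_b,
                                a_sp, a_nosp, b_sp, b_nosp, d, p)


def go_propagate(
    annotations: Mapping[str, Iterable[str]],
    dag: nx.DiGraph,
    relations: tuple[str, ...] = ("is_a",),
) -> dict[str, frozenset]:
    """Close each protein's GO term set upward to the namespace roots.

    ``dag`` follows the obonet convention: edges point child -> parent and
    carry a relation key.  Only ``relations`` edges are traversed (is_a by
    default; add part_of via the argument).  Raises on a cycle.
    """
    sub = nx.DiGraph()
    sub.add_nodes_from(dag.nodes)
    for u, v, key in dag.edges(keys=True) if dag.is_multigraph() else \
            ((u, v, d.get("relation", "is_a")) for u, v, d in dag.edges(data=True)):
        if key in relations:
            sub.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(sub):
        cycle = nx.find_cycle(sub)
        raise ValueError(f"cycle in GO graph: {cycle}")
    closed = {}
    for protein, terms in annotations.items():
        full: set[str] = set()
        for term in terms:
            full.add(term)
            if term in sub:
                full.update(nx.descendants(sub, term))  # child->parent edges
        closed[protein] = frozenset(full)
    return closed


def go_enrichment(
    protein_groups: Mapping[str, Iterable[str]],
    closed_annotations: Mapping[str, frozenset],
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of each term in each group against the
    pooled background of all groups."""
    groups = {g: [p for p in members if p in closed_annotations]
              for g, members in protein_groups.items()}
    background = [p for members in groups.values() for p in members]
    N = len(background)
    term_count_bg: dict[str, int] = {}
    for p in background:
        for t in closed_annotations[p]:
            term_count_bg[t] = term_count_bg.get(t, 0) + 1
    results = []
    for group, members in groups.items():
        n = len(members)
        if n == 0:
            log.debug("group %s empty: no enrichment computed", group)
            continue
        term_count: dict[str, int] = {}
        for p in members:
            for t in closed_annotations[p]:
                term_count[t] = term_count.get(t, 0) + 1
        for term in sorted(term_count):
            k, K = term_count[term], term_count_bg[term]
            p_val = fisher_exact_2x2(
                [[k, n - k], [K - k, N - n - (K - k)]], sided="one_greater")
            results.append(EnrichmentResult(term, group, k, n, K, N, p_val))
    return results


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: sup-norm ECDF distance, asymptotic p."""
    res = sps.ks_2samp(np.asarray(x, float), np.asarray(y, float), method="asymp")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties, t-approximation p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")  # undefined on constant input
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def energy_statistic(X: np.ndarray, Y: np.ndarray) -> float:
    """Szekely-Rizzo energy distance between two multivariate samples."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    n, m = len(X), len(Y)
    d_xy = cdist(X, Y).mean()
    d_xx = cdist(X, X).sum() / (n * n)
    d_yy = cdist(Y, Y).sum() / (m * m)
    return float(2.0 * d_xy - d_xx - d_yy)


def cvm_two_sample_multivariate(
    X, Y, n_permutations: int = 999, seed: int = 0,
) -> tuple[float, float]:
    """Two-sample test for multivariate distributions: energy-distance
    statistic with a label-permutation null.

    p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations),
    so p >= 1/(n_permutations + 1) always.
    """
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if X.ndim == 2 and X.shape[1] != Y.shape[1]:
        raise ValueError("samples must share dimensionality")
    observed = energy_statistic(X, Y)
    pooled = np.vstack([X, Y])
    n = len(X)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(pooled))
        stat = energy_statistic(pooled[perm[:n]], pooled[perm[n:]])
        if stat >= observed - 1e-15:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return observed, float(p)
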