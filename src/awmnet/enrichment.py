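"""Gene-set over-representation of network genes with kappa-based grouping.

Each term (GO-like gene set) is tested by the upper-tail hypergeometric test
against a gene universe, p-values are Benjamini-Hochberg adjusted, and terms
significant at adjusted p < 0.05 are clustered into functional groups by
single linkage on Cohen's kappa > 0.4 between their gene-membership
indicators — the flat-gene-set analogue of a ClueGO analysis (no ontology
hierarchy is traversed; optional per-set size bounds stand in for GO-level
filtering).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_test",
    "bh_adjust",
    "cohens_kappa",
    "kappa_cluster",
    "enrich",
]


@dataclass
class EnrichmentResult:
    """Per-term test table plus the kappa functional groups of significant terms."""

    table: pd.DataFrame  # term, K, k, n, N, p, p_adj, significant, group
    groups: list[list[str]] = field(default_factory=list)

    @property
    def significant_terms(self) -> list[str]:
        return self.table.loc[self.table["significant"], "term"].tolist()


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), on the log scale.

    Drawing ``n`` network genes from a universe of ``N`` of which ``K`` carry
    the term: the enrichment p-value of observing ``k`` or more hits.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    logp = stats.hypergeom.logsf(k - 1, N, K, n)
    return float(min(1.0, np.exp(logp)))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving on input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_kappa(a: set, b: set, universe: set) -> float:
    """Chance-corrected agreement of two gene sets' membership over a universe."""
    N = len(universe)
    if N == 0:
        raise ValueError("empty universe")
    a = a & universe
    b = b & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = N - n11 - n10 - n01
    po = (n11 + n00) / N
    pe = ((n11 + n10) * (n11 + n01) + (n01 + n00) * (n10 + n00)) / N**2
    if pe == 1.0:
        return 1.0  # identical degenerate margins: perfect agreement
    return (po - pe) / (1.0 - pe)


def kappa_cluster(
    term_sets: dict[str, set], universe: set, kappa_cut: float = 0.4
) -> list[list[str]]:
    """Single-linkage functional groups of terms with pairwise kappa > kappa_cut.

    Groups partition the terms (transitive closure of the kappa graph);
    singletons are allowed.  The threshold is strict.
    """
    if not term_sets:
        raise ValueError("no terms to cluster")
    for t, s in term_sets.items():
        if not s:
            raise ValueError(f"term {t!r} has an empty gene set")
    names = sorted(term_sets)
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if cohens_kappa(term_sets[a], term_sets[b], universe) > kappa_cut:
                g.add_edge(a, b)
    return [sorted(c) for c in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])]


def enrich(
    hits: set,
    gene_sets: dict[str, list[str] | set],
    universe: set | None = None,
    alpha: float = 0.05,
    kappa_cut: float = 0.4,
    min_size: int | None = None,
    max_size: int | None = None,
) -> EnrichmentResult:
    """Over-representation of ``hits`` (e.g. the network genes) in every gene set.

    The default universe is the union of all annotated genes; pass the
    AWM-eligible gene list to restrict it.  ``min_size``/``max_size`` bound
    the per-set annotated size (the flat replacement for GO-level filters).
    Terms significant at BH-adjusted p < ``alpha`` are kappa-clustered.
    """
    sets = {t: set(g) for t, g in gene_sets.items()}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    universe = set(universe)
    hits_u = hits & universe
    N, n = len(universe), len(hits_u)
    rows = []
    for term in sorted(sets):
        members = sets[term] & universe
        K = len(members)
        if K == 0:
            continue
        if min_size is not None and K < min_size:
            continue
        if max_size is not None and K > max_size:
            continue
        k = len(hits_u & members)
        rows.append({"term": term, "K": K, "k": k, "n": n, "N": N,
                     "p": hypergeom_test(k, K, n, N)})
    table = pd.DataFrame(rows, columns=["term", "K", "k", "n", "N", "p"])
    if len(table):
        table["p_adj"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = []
        table["significant"] = []

    groups: list[list[str]] = []
    sig = table.loc[table["significant"], "term"].tolist()
    if sig:
        groups = kappa_cluster({t: sets[t] & universe for t in sig}, universe, kappa_cut)
    group_of = {t: i + 1 for i, grp in enumerate(groups) for t in grp}
    table["group"] = [group_of.get(t, 0) for t in table["term"]]
    table = table.sort_values(["p_adj", "term"], kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table, groups=groups)
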