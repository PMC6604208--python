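"""PCIT (partial correlation and information theory) gene-network inference.

For every trio of genes (x, y, z) the three first-order partial correlations

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))   (etc.)

define a trio-specific tolerance eps = mean of the ratios r_xy.z / r_xy,
r_xz.y / r_xz, r_yz.x / r_yz.  The x-y association is flagged non-significant
if for some third gene z both |r_xy| <= |eps * r_xz| and |r_xy| <= |eps *
r_yz|: the direct correlation is then dominated by the tolerance-scaled
indirect paths through z.  Surviving pairs form the edges of a simple
undirected gene network; hubs are read off the degree and (max-normalized)
eigenvector centralities.

The triple loop is O(g^3) but evaluated blockwise with numpy (one g x g slab
per conditioning gene), which keeps networks of a few hundred genes
desk-scale with no approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["GeneNetwork", "pcit_edges", "build_network", "centralities"]

_EPS_DENOM = 1e-12  # ratio terms with |denominator| below this are skipped


@dataclass
class GeneNetwork:
    """Simple undirected gene network with centrality accessors."""

    graph: nx.Graph
    duplicates: list[tuple[str, str]] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v in self.graph.edges]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def eigenvector_centrality(self) -> dict[str, float]:
        return centralities(self)[1]

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def best_trios(self, regulators, top_n: int = 10):
        from .regulators import best_trios

        return best_trios(self, regulators, top_n=top_n)

    def enrich(self, gene_sets, **kwargs):
        from .enrichment import enrich

        return enrich(set(self.nodes), gene_sets, **kwargs)

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            (u, v, d.get("weight", np.nan)) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "correlation"])


def _pcit_keep(corr: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Boolean keep-mask over gene pairs plus the |r| ~ 1 duplicate pairs.

    Vectorized per conditioning gene z: one g x g slab holds r_xy.z for all
    (x, y), a second holds r_xz.y (whose transpose is r_yz.x), so the trio
    tolerance and the elimination test are evaluated for all pairs at once.
    """
    g = corr.shape[0]
    absr = np.abs(corr)
    dup_mask = absr >= 1.0 - 1e-12
    np.fill_diagonal(dup_mask, False)
    duplicates = [(i, j) for i, j in zip(*np.where(np.triu(dup_mask)))]

    keep = np.ones((g, g), dtype=bool)
    np.fill_diagonal(keep, False)
    one_minus_r2 = 1.0 - corr**2

    with np.errstate(divide="ignore", invalid="ignore"):
        for z in range(g):
            rz = corr[:, z]
            dz = one_minus_r2[:, z]
            # r_xy.z for all (x, y)
            pc_z = (corr - np.outer(rz, rz)) / np.sqrt(np.outer(dz, dz))
            # r_xz.y for all (x, y): condition the (x, z) correlation on y
            pc_y = (rz[:, None] - corr * rz[None, :]) / np.sqrt(
                one_minus_r2 * dz[None, :]
            )
            # trio tolerance: average of the valid partial/raw ratios
            t1 = pc_z / corr
            t2 = pc_y / rz[:, None]
            t3 = pc_y.T / rz[None, :]
            terms = np.stack([t1, t2, t3])
            denoms = np.stack(
                [absr, np.broadcast_to(np.abs(rz)[:, None], t1.shape),
                 np.broadcast_to(np.abs(rz)[None, :], t1.shape)]
            )
            valid = np.isfinite(terms) & (denoms > _EPS_DENOM)
            nvalid = valid.sum(axis=0)
            eps = np.where(
                nvalid > 0,
                np.where(valid, terms, 0.0).sum(axis=0) / np.maximum(nvalid, 1),
                np.nan,
            )
            with np.errstate(invalid="ignore"):
                kill = (
                    (absr <= np.abs(eps * rz[:, None]))
                    & (absr <= np.abs(eps * rz[None, :]))
                    & np.isfinite(eps)
                )
            kill[z, :] = False
            kill[:, z] = False
            keep &= ~kill

    keep |= dup_mask  # |r| = 1 pairs stay significant regardless
    np.fill_diagonal(keep, False)
    return keep, duplicates


def pcit_edges(
    z: pd.DataFrame, min_traits_warn: int = 8
) -> list[tuple[str, str, float]]:
    """Significant gene-gene edges from a gene x trait matrix of effects.

    Returns (gene_a, gene_b, raw Pearson correlation) for every surviving
    pair.  Needs >= 3 genes and >= 3 trait columns; zero-variance gene rows
    are rejected, and a warning is emitted when fewer than ``min_traits_warn``
    trait columns are available (partials from very short vectors are noisy).
    """
    if z.shape[0] < 3:
        raise ValueError("PCIT needs at least 3 genes")
    if z.shape[1] < 3:
        raise ValueError("PCIT needs at least 3 trait columns")
    if z.shape[1] < min_traits_warn:
        warnings.warn(
            f"PCIT on only {z.shape[1]} trait columns; partial correlations "
            "from short profiles are noisy",
            stacklevel=2,
        )
    vals = z.to_numpy(dtype=float)
    if np.any(vals.std(axis=1) == 0):
        bad = z.index[vals.std(axis=1) == 0].tolist()
        raise ValueError(f"zero-variance gene rows: {bad}")
    corr = np.corrcoef(vals)
    keep, dup_idx = _pcit_keep(corr)
    genes = list(z.index)
    if dup_idx:
        warnings.warn(
            f"{len(dup_idx)} gene pair(s) with |r| = 1 treated as always-significant duplicates",
            stacklevel=2,
        )
    iu = np.triu_indices(len(genes), k=1)
    edges = [
        (genes[i], genes[j], float(corr[i, j]))
        for i, j in zip(*iu)
        if keep[i, j]
    ]
    return edges


def build_network(
    edges,
    genes: list[str],
    node_attrs: dict[str, dict] | None = None,
) -> GeneNetwork:
    """Assemble a simple undirected network; isolated genes stay as degree-0 nodes."""
    g = nx.Graph()
    g.add_nodes_from(genes)
    known = set(genes)
    for e in edges:
        u, v = e[0], e[1]
        w = float(e[2]) if len(e) > 2 else 1.0
        if u not in known or v not in known:
            raise ValueError(f"edge ({u}, {v}) references unknown gene")
        if u == v:
            continue
        g.add_edge(u, v, weight=w)
    if node_attrs:
        nx.set_node_attributes(g, node_attrs)
    return GeneNetwork(graph=g)


def centralities(
    net: GeneNetwork, tol: float = 1e-10, max_iter: int = 10_000
) -> tuple[dict[str, int], dict[str, float]]:
    """Degree and max-normalized eigenvector centrality of every node.

    Eigenvector centrality is the principal eigenvector of the (unweighted)
    adjacency matrix, found by power iteration to ``tol`` and normalized so
    the most central node scores 1.  Disconnected graphs use the global
    principal eigenvector; an edgeless network scores every node 1 (the
    principal eigenspace of the zero matrix is degenerate, so the uniform
    vector is reported).
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("network has no nodes")
    deg = net.degree()
    A = nx.to_numpy_array(net.graph, nodelist=nodes, weight=None)
    if net.n_edges == 0:
        return deg, {v: 1.0 for v in nodes}
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = A @ x
        norm = np.linalg.norm(y)
        if norm == 0:  # pragma: no cover - impossible with >=1 edge from uniform start
            break
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    x = np.abs(x)
    x /= x.max()
    return deg, dict(zip(nodes, x.tolist()))
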