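"""Regulator-trio search: minimal sets of regulators with maximal network coverage.

Given a gene network and a user-supplied list of candidate regulators (TFs,
miRNAs, lncRNAs), every trio of regulators is scored by the number of network
genes adjacent to at least one member (coverage, 1-hop, trio members excluded
from their own coverage) and, as tie-break, by the number of genes adjacent
to two or more members (overlap — less is better), then lexicographically.
Enumeration is exhaustive: candidate lists are small (tens of genes), and an
exhaustive ranking dominates greedy set-cover, which can be fooled by nested
neighborhoods.  A greedy fallback with a warning engages above 200 candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import pandas as pd

from .pcit import GeneNetwork

__all__ = ["TrioResult", "regulator_connectivity", "best_trios"]

GREEDY_FALLBACK_R = 200


@dataclass(frozen=True)
class TrioResult:
    """One regulator trio with its 1-hop coverage of the network."""

    trio: tuple[str, str, str]
    covered: frozenset[str]
    overlap: int

    @property
    def coverage_size(self) -> int:
        return len(self.covered)


def regulator_connectivity(net: GeneNetwork, regulators) -> pd.Series:
    """Interaction counts (degree) per candidate regulator, sorted descending."""
    regulators = list(regulators)
    unknown = [r for r in regulators if r not in net.graph]
    if unknown:
        raise ValueError(f"regulators not in network: {unknown}")
    deg = net.degree()
    s = pd.Series({r: deg[r] for r in regulators}, dtype=int)
    return s.sort_values(ascending=False, kind="stable")


def _score_trio(trio, nbr: dict[str, set[str]]) -> TrioResult:
    members = set(trio)
    sets = [nbr[m] - members for m in trio]
    covered = sets[0] | sets[1] | sets[2]
    pair_olap = (
        len(sets[0] & sets[1]) + len(sets[0] & sets[2]) + len(sets[1] & sets[2])
        - 2 * len(sets[0] & sets[1] & sets[2])
    )
    return TrioResult(trio=tuple(trio), covered=frozenset(covered), overlap=pair_olap)


def best_trios(net: GeneNetwork, regulators, top_n: int = 10) -> list[TrioResult]:
    """Rank all C(R, 3) regulator trios by coverage (desc), overlap (asc), name.

    The ranking is total and deterministic.  Above ``GREEDY_FALLBACK_R``
    candidates an approximate greedy search is used instead (with a warning):
    the greedy cover's members plus the best exhaustive completion among the
    top-degree candidates.
    """
    regulators = sorted(set(regulators))
    unknown = [r for r in regulators if r not in net.graph]
    if unknown:
        raise ValueError(f"regulators not in network: {unknown}")
    if len(regulators) < 3:
        raise ValueError("need at least 3 candidate regulators")
    nbr = {r: net.neighbors(r) for r in regulators}

    if len(regulators) > GREEDY_FALLBACK_R:
        warnings.warn(
            f"{len(regulators)} regulator candidates: falling back to greedy trio search",
            stacklevel=2,
        )
        regulators = _greedy_pool(regulators, nbr, pool=60)

    scored = [_score_trio(t, nbr) for t in combinations(regulators, 3)]
    scored.sort(key=lambda s: (-s.coverage_size, s.overlap, s.trio))
    return scored[:top_n]


def _greedy_pool(regulators, nbr, pool: int) -> list[str]:
    """Restrict to the candidates with the largest neighborhoods (greedy pre-filter)."""
    order = sorted(regulators, key=lambda r: (-len(nbr[r]), r))
    return order[:pool]


def trios_to_frame(trios: list[TrioResult]) -> pd.DataFrame:
    rows = [
        {
            "regulator_1": t.trio[0],
            "regulator_2": t.trio[1],
            "regulator_3": t.trio[2],
            "coverage": t.coverage_size,
            "overlap": t.overlap,
            "covered_genes": ",".join(sorted(t.covered)),
        }
        for t in trios
    ]
    return pd.DataFrame(rows)
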