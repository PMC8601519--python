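"""Triad census and frustration counting under structural balance theory.

A closed triad of a signed network is *balanced* when the product of its
three link signs is positive (sign patterns +++ and +--) and *frustrated*
(imbalanced) when the product is negative (++- and ---).  Heider's balance
theory holds that frustrated triads press the network to change its links,
so the frustration count of a brain signed network measures its
"requirement to change".

Two interchangeable implementations are provided: an O(n^3) explicit
enumeration (the reference oracle) and a matrix-trace method.  With P and N
the 0/1 adjacencies of the positive and negative subnetworks,

    n(+++) = tr(P^3)/6      n(++-) = tr(P.P.N)/2
    n(+--) = tr(P.N.N)/2    n(---) = tr(N^3)/6

All divisions are exact in integer arithmetic; inexactness signals a
corrupted adjacency and raises.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .network import SignedNetwork

__all__ = [
    "TriadCensus",
    "census_bruteforce",
    "census_trace",
    "frustration",
    "switch_nodes",
]


@dataclass(frozen=True)
class TriadCensus:
    """Counts of closed triads by number of negative links (0, 1, 2, 3)."""

    n_ppp: int
    n_ppn: int
    n_pnn: int
    n_nnn: int

    @property
    def n_closed(self) -> int:
        return self.n_ppp + self.n_ppn + self.n_pnn + self.n_nnn

    @property
    def n_frustrated(self) -> int:
        """Triads whose sign product is negative: (++-) + (---)."""
        return self.n_ppn + self.n_nnn

    @property
    def frustration_fraction(self) -> float:
        """Frustrated share of closed triads; NaN when no triad is closed."""
        if self.n_closed == 0:
            return float("nan")
        return self.n_frustrated / self.n_closed

    def as_dict(self) -> dict[str, int]:
        return {
            "n_ppp": self.n_ppp,
            "n_ppn": self.n_ppn,
            "n_pnn": self.n_pnn,
            "n_nnn": self.n_nnn,
            "n_closed": self.n_closed,
            "n_frustrated": self.n_frustrated,
        }


def census_bruteforce(net: SignedNetwork) -> TriadCensus:
    """Reference O(n^3) census by explicit enumeration of node triples."""
    a = net.adjacency
    counts = [0, 0, 0, 0]  # indexed by number of negative links
    for i, j, k in combinations(range(net.n_nodes), 3):
        e1, e2, e3 = a[i, j], a[j, k], a[i, k]
        if e1 == 0 or e2 == 0 or e3 == 0:
            continue  # open triple, not a closed triad
        counts[int(e1 == -1) + int(e2 == -1) + int(e3 == -1)] += 1
    return TriadCensus(*counts)


def _exact_div(value: int, divisor: int, what: str) -> int:
    q, rem = divmod(int(value), divisor)
    if rem:
        raise RuntimeError(
            f"trace census internal error: {what} = {value} not divisible by {divisor}"
        )
    return q


def census_trace(net: SignedNetwork) -> TriadCensus:
    """Fast census via traces of products of the polarity adjacencies."""
    p = (net.adjacency == 1).astype(np.int64)
    n = (net.adjacency == -1).astype(np.int64)
    pp = p @ p
    nn = n @ n
    n_ppp = _exact_div(np.trace(pp @ p), 6, "tr(P^3)")
    n_ppn = _exact_div(np.trace(pp @ n), 2, "tr(PPN)")
    n_pnn = _exact_div(np.trace(p @ nn), 2, "tr(PNN)")
    n_nnn = _exact_div(np.trace(nn @ n), 6, "tr(N^3)")
    return TriadCensus(n_ppp, n_ppn, n_pnn, n_nnn)


def frustration(net: SignedNetwork) -> int:
    """Number of frustrated (imbalanced) closed triads."""
    return census_trace(net).n_frustrated


def switch_nodes(net: SignedNetwork, node_subset: Iterable[int]) -> SignedNetwork:
    """Negate every edge with exactly one endpoint in ``node_subset``.

    The switching transformation preserves the sign product of every closed
    triad (each triangle crosses the cut an even number of times), hence the
    frustration count is invariant under it.
    """
    subset = sorted(set(int(v) for v in node_subset))
    if subset and (subset[0] < 0 or subset[-1] >= net.n_nodes):
        raise IndexError(f"node index out of range for n={net.n_nodes}")
    s = np.ones(net.n_nodes, dtype=np.int8)
    s[subset] = -1
    switched = (s[:, None] * net.adjacency.astype(np.int64) * s[None, :]).astype(np.int8)
    return SignedNetwork(switched, net.region_labels, net.provenance)
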