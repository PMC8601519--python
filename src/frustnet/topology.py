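"""Global topology of polarity subnetworks.

Three global measures characterize a (typically negative) subnetwork:

* **TMH** (tendency to make hub): sum of squared nodal degrees divided by
  the sum of degrees.  Equals 1 when every node has degree one (a perfect
  matching) and grows as degree mass concentrates on hubs; a k-regular
  graph has TMH = k.
* **ASPL**: mean unweighted shortest-path length over connected unordered
  node pairs.  Disconnected pairs are excluded from both numerator and
  denominator and their count is surfaced so fragmentation is visible.
  Global efficiency is reported as 1/ASPL.
* **Transitivity** (global clustering): 3 x triangles / connected triples,
  with triples counted as sum_i d_i (d_i - 1) / 2.

Degree distributions pooled over the subjects of a group are summarized by
a maximum-likelihood log-normal fit on the (strictly positive) degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import Subnetwork

__all__ = [
    "AsplResult",
    "LogNormalFit",
    "tmh",
    "aspl",
    "efficiency",
    "transitivity",
    "pooled_degree_distribution",
    "fit_lognormal_mle",
]


def tmh(sub: Subnetwork) -> float:
    """Tendency to Make Hub: sum(d_i^2) / sum(d_i)."""
    d = sub.degrees
    total = d.sum()
    if total == 0:
        raise ValueError("TMH undefined on an edgeless subnetwork")
    return float((d.astype(np.float64) ** 2).sum() / total)


@dataclass(frozen=True)
class AsplResult:
    """ASPL plus diagnostics about pairs excluded for disconnection."""

    value: float
    n_connected_pairs: int
    n_excluded_pairs: int

    def __float__(self) -> float:
        return self.value


def aspl(sub: Subnetwork) -> AsplResult:
    """Average shortest path length over connected unordered node pairs."""
    n = sub.n_nodes
    dist = shortest_path(csr_matrix(sub.adjacency), method="D", unweighted=True)
    iu = np.triu_indices(n, k=1)
    lengths = dist[iu]
    finite = np.isfinite(lengths)
    n_connected = int(finite.sum())
    if n_connected == 0:
        raise ValueError("ASPL undefined: no connected node pairs")
    return AsplResult(
        value=float(lengths[finite].mean()),
        n_connected_pairs=n_connected,
        n_excluded_pairs=int(len(lengths) - n_connected),
    )


def efficiency(sub: Subnetwork) -> float:
    """Global efficiency, defined as the inverse of the ASPL."""
    return 1.0 / aspl(sub).value


def transitivity(sub: Subnetwork) -> float:
    """Global clustering coefficient: 3 * N_triangle / N_triple."""
    d = sub.degrees.astype(np.int64)
    n_triples = int((d * (d - 1) // 2).sum())
    if n_triples == 0:
        raise ValueError("transitivity undefined: no node has degree >= 2")
    a = sub.adjacency.astype(np.int64)
    tr3 = int(np.trace(a @ a @ a))
    if tr3 % 6:
        raise RuntimeError("tr(A^3) not divisible by 6 on a simple graph")
    n_triangles = tr3 // 6
    return 3.0 * n_triangles / n_triples


def pooled_degree_distribution(
    subs: list[Subnetwork] | tuple[Subnetwork, ...],
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Density-normalized histogram of degrees pooled across subjects.

    Returns ``(bin_edges, density)`` with bins of the given width anchored at
    the smallest pooled degree; the density integrates to one.
    """
    if not subs:
        raise ValueError("empty subnetwork collection")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    degrees = np.concatenate([s.degrees for s in subs]).astype(float)
    lo = np.floor(degrees.min() / bin_width) * bin_width
    hi = degrees.max()
    edges = np.arange(lo, hi + 2 * bin_width, bin_width)
    density, edges = np.histogram(degrees, bins=edges, density=True)
    return edges, density


@dataclass(frozen=True)
class LogNormalFit:
    """MLE log-normal parameters for a degree sample (natural logs).

    ``sigma`` is the maximum-likelihood (1/n) standard deviation of the
    log-degrees; standard errors are the asymptotic ``sigma/sqrt(n)`` and
    ``sigma/sqrt(2n)``.  ``degenerate`` flags an all-equal sample, for which
    sigma sits on the boundary of the parameter space.
    """

    mu: float
    sigma: float
    se_mu: float
    se_sigma: float
    n_obs: int
    degenerate: bool = False

    def loglik(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if self.sigma == 0:
            raise ValueError("log-likelihood undefined for degenerate fit")
        z = (np.log(x) - self.mu) / self.sigma
        return float(
            -np.sum(np.log(x))
            - self.n_obs * np.log(self.sigma * np.sqrt(2 * np.pi))
            - 0.5 * np.sum(z**2)
        )


def fit_lognormal_mle(degrees) -> LogNormalFit:
    """Closed-form MLE of a log-normal on strictly positive degrees.

    Zero degrees must be excluded by the caller (the log is undefined); a
    non-positive value here is an error, not silently dropped.
    """
    x = np.asarray(list(degrees), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations to fit")
    if np.any(x <= 0):
        raise ValueError("log-normal fit requires strictly positive degrees")
    logs = np.log(x)
    n = x.size
    mu = float(logs.mean())
    sigma = float(np.sqrt(((logs - mu) ** 2).mean()))  # 1/n MLE variance
    degenerate = sigma == 0.0
    return LogNormalFit(
        mu=mu,
        sigma=sigma,
        se_mu=sigma / np.sqrt(n),
        se_sigma=sigma / np.sqrt(2 * n),
        n_obs=int(n),
        degenerate=degenerate,
    )
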