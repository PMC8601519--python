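"""Signed functional network construction.

A resting-state functional network is built from regional (ROI) activity
time series: every pair of regions is linked by the Pearson correlation of
their series, and the link is *binarized to its sign* (+1 for synchrony,
-1 for anti-synchrony).  Without a threshold the resulting signed network
is fully connected; an optional absolute-value threshold ``tau`` zeroes out
weak links and yields a partially connected signed network.

The signed network splits into a *positive subnetwork* (the +1 links) and a
*negative subnetwork* (the -1 links); the negative subnetwork carries the
topology measures of interest downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RegionalTimeSeries",
    "FunctionalConnectivity",
    "SignedNetwork",
    "Subnetwork",
    "truncate_to_common_length",
    "pearson_connectivity",
    "binarize_signs",
    "split_subnetworks",
    "merge_subnetworks",
    "negative_link_density",
]


@dataclass(frozen=True)
class RegionalTimeSeries:
    """Activity matrix of one subject: ``n_regions x n_timepoints``."""

    values: np.ndarray
    region_labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D (regions x timepoints) matrix")
        if values.shape[0] != len(self.region_labels):
            raise ValueError(
                f"{values.shape[0]} rows but {len(self.region_labels)} region labels"
            )
        if values.shape[1] < 3:
            raise ValueError("need at least 3 timepoints for a Pearson correlation")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains missing/non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FunctionalConnectivity:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    r: np.ndarray
    region_labels: tuple[str, ...]
    subject_id: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if not np.array_equal(r, r.T):
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-12:
            raise ValueError("correlation coefficients must lie in [-1, 1]")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "region_labels", tuple(self.region_labels))


@dataclass(frozen=True)
class SignedNetwork:
    """Symmetric signed adjacency with entries in {+1, -1, 0}, zero diagonal."""

    adjacency: np.ndarray
    region_labels: tuple[str, ...] = ()
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (-1, 0, 1)).all():
            bad = np.argwhere(~np.isin(a, (-1, 0, 1)))[0]
            raise ValueError(
                f"adjacency entry at ({bad[0]}, {bad[1]}) is outside {{+1, -1, 0}}"
            )
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("signed adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("signed adjacency must have a zero diagonal")
        labels = tuple(self.region_labels) or tuple(str(i) for i in range(a.shape[0]))
        if len(labels) != a.shape[0]:
            raise ValueError("label count does not match adjacency size")
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "region_labels", labels)
        object.__setattr__(self, "provenance", dict(self.provenance))

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def n_negative_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1) == -1))

    @property
    def n_positive_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1) == 1))


@dataclass(frozen=True)
class Subnetwork:
    """Unsigned 0/1 subnetwork obtained from one polarity of a signed network."""

    adjacency: np.ndarray
    region_labels: tuple[str, ...] = ()
    polarity: str = "negative"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("subnetwork adjacency must be binary 0/1")
        a = a.astype(np.int8)
        if not np.array_equal(a, a.T):
            raise ValueError("subnetwork adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("subnetwork must have no self-loops")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        labels = tuple(self.region_labels) or tuple(str(i) for i in range(a.shape[0]))
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "region_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0).astype(np.int64)


def truncate_to_common_length(
    cohort: Sequence[RegionalTimeSeries],
) -> list[RegionalTimeSeries]:
    """Truncate every subject to the cohort's shortest scan.

    Unequal scan lengths distort the comparability of Pearson correlations, so
    only the *initial* timepoints, up to the length of the shortest series in
    the cohort, are retained for every subject.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    t_min = min(ts.n_timepoints for ts in cohort)
    if t_min < 3:
        raise ValueError(f"shortest series has {t_min} timepoints; need >= 3")
    return [
        RegionalTimeSeries(ts.values[:, :t_min], ts.region_labels, ts.subject_id)
        for ts in cohort
    ]


def pearson_connectivity(ts: RegionalTimeSeries) -> FunctionalConnectivity:
    """Sample Pearson correlation between every pair of regional series."""
    sd = ts.values.std(axis=1)
    if np.any(sd == 0):
        bad = ts.region_labels[int(np.argmin(sd != 0))]
        zero = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance region(s): {zero!r} (first: {bad!r})")
    r = np.corrcoef(ts.values)
    r = np.clip(r, -1.0, 1.0)
    # enforce exact symmetry: keep one value per unordered pair
    r = np.triu(r, k=1)
    r = r + r.T + np.eye(ts.n_regions)
    return FunctionalConnectivity(r, ts.region_labels, ts.subject_id)


def binarize_signs(
    conn: FunctionalConnectivity, tau: float | None = None
) -> SignedNetwork:
    """Binarize correlations to a signed network by sign.

    With ``tau=None`` every off-diagonal correlation maps to its sign and the
    network is fully connected (up to exact zeros, which map to absent links
    and raise a warning).  With a threshold ``tau``, links with ``|r| < tau``
    are absent.
    """
    if tau is not None and not (0 <= tau < 1):
        raise ValueError("threshold tau must lie in [0, 1)")
    r = conn.r.copy()
    np.fill_diagonal(r, 0.0)
    signs = np.sign(r).astype(np.int8)
    if tau is not None and tau > 0:
        signs[np.abs(r) < tau] = 0
    else:
        off = np.triu_indices_from(r, k=1)
        n_zero = int(np.sum(r[off] == 0.0))
        if n_zero:
            warnings.warn(
                f"{n_zero} exactly-zero correlation(s) mapped to absent links",
                stacklevel=2,
            )
    return SignedNetwork(
        signs,
        conn.region_labels,
        provenance={"subject_id": conn.subject_id, "threshold": tau},
    )


def split_subnetworks(net: SignedNetwork) -> tuple[Subnetwork, Subnetwork]:
    """Split into (positive, negative) binary subnetworks on the same nodes."""
    pos = (net.adjacency == 1).astype(np.int8)
    neg = (net.adjacency == -1).astype(np.int8)
    return (
        Subnetwork(pos, net.region_labels, polarity="positive"),
        Subnetwork(neg, net.region_labels, polarity="negative"),
    )


def merge_subnetworks(positive: Subnetwork, negative: Subnetwork) -> SignedNetwork:
    """Recombine polarity subnetworks into the signed network (inverse of split)."""
    if positive.adjacency.shape != negative.adjacency.shape:
        raise ValueError("subnetworks must share the node set")
    if np.any(positive.adjacency & negative.adjacency):
        raise ValueError("subnetwork edge sets overlap")
    return SignedNetwork(
        positive.adjacency.astype(np.int8) - negative.adjacency.astype(np.int8),
        positive.region_labels,
    )


def negative_link_density(net: SignedNetwork) -> float:
    """Fraction of present links that are negative.

    For a fully connected signed network this equals
    ``n_negative / C(n, 2)``.
    """
    n_edges = net.n_edges
    if n_edges == 0:
        raise ValueError("network has no present edges")
    return net.n_negative_edges / n_edges
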