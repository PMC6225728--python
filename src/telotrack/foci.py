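"""3D foci aggregation and two-channel colocalization.

Aggregation follows the rule: at least two foci clustering together with a
maximum spot-to-spot distance of half a spot diameter, read as single-linkage
clustering at cutoff diameter/2 on 3D Euclidean distance in physical units
(complete linkage available by flag).  Colocalization is one-to-one greedy
matching by ascending centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

__all__ = ["AggregationResult", "ColocResult", "count_aggregations",
           "colocalize", "foci_count_histogram"]


@dataclass
class AggregationResult:
    nucleus_id: int
    n_foci: int
    n_aggregates: int
    cluster_sizes: list[int]
    threshold_nm: float


@dataclass
class ColocResult:
    nucleus_id: int
    n_a: int
    n_b: int
    n_coloc: int
    fraction: Optional[float]
    threshold_nm: float


def _cluster_labels(positions: np.ndarray, cutoff: float, method: str) -> np.ndarray:
    if method == "single":
        # connected components of the <=cutoff proximity graph
        n = len(positions)
        d = cdist(positions, positions)
        adj = d <= cutoff
        labels = np.full(n, -1)
        current = 0
        for i in range(n):
            if labels[i] >= 0:
                continue
            stack = [i]
            labels[i] = current
            while stack:
                j = stack.pop()
                for k in np.flatnonzero(adj[j]):
                    if labels[k] < 0:
                        labels[k] = current
                        stack.append(k)
            current += 1
        return labels
    if method == "complete":
        z = linkage(pdist(positions), method="complete")
        return fcluster(z, t=cutoff, criterion="distance") - 1
    raise ValueError("method must be 'single' or 'complete'")


def count_aggregations(foci: np.ndarray, spot_diameter: float,
                       nucleus_id: int = 0,
                       method: str = "single") -> AggregationResult:
    """Count clusters of >= 2 foci within spot_diameter/2 of each other.

    ``foci`` is (n, 3) in nm with z already in physical units.  The cutoff is
    half the spot diameter; cluster sizes of all aggregates (size >= 2) are
    reported.
    """
    if spot_diameter <= 0:
        raise ValueError("spot_diameter must be > 0")
    foci = np.atleast_2d(np.asarray(foci, dtype=float))
    if foci.size == 0:
        return AggregationResult(nucleus_id, 0, 0, [], spot_diameter / 2.0)
    if foci.shape[1] != 3:
        raise ValueError("foci must be (n, 3)")
    n = len(foci)
    cutoff = spot_diameter / 2.0
    if n < 2:
        return AggregationResult(nucleus_id, n, 0, [], cutoff)
    labels = _cluster_labels(foci, cutoff, method)
    sizes = np.bincount(labels)
    cluster_sizes = sorted((int(s) for s in sizes if s >= 2), reverse=True)
    return AggregationResult(nucleus_id, n, len(cluster_sizes), cluster_sizes,
                             cutoff)


def colocalize(foci_a: np.ndarray, foci_b: np.ndarray, threshold: float,
               nucleus_id: int = 0) -> ColocResult:
    """One-to-one greedy matching of channel-A foci to channel-B foci.

    Pairs are accepted in ascending distance order while the distance is at
    most ``threshold`` (nm); each focus is used at most once.  The fraction
    is matched-A / total-A (None when channel A is empty).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    a = np.atleast_2d(np.asarray(foci_a, dtype=float))
    b = np.atleast_2d(np.asarray(foci_b, dtype=float))
    if a.size == 0:
        a = np.empty((0, 3))
    if b.size == 0:
        b = np.empty((0, 3))
    n_a, n_b = len(a), len(b)
    if n_a == 0:
        return ColocResult(nucleus_id, 0, n_b, 0, None, threshold)
    if n_b == 0:
        return ColocResult(nucleus_id, n_a, 0, 0, 0.0, threshold)
    d = cdist(a, b)
    ia, ib = np.nonzero(d <= threshold)
    order = np.lexsort((ib, ia, d[ia, ib]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    n_match = 0
    for k in order:
        i, j = int(ia[k]), int(ib[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        n_match += 1
    return ColocResult(nucleus_id, n_a, n_b, n_match, n_match / n_a, threshold)


def foci_count_histogram(counts: Sequence[int],
                         bins: Sequence[float]) -> np.ndarray:
    """Histogram of per-nucleus foci counts over user-fixed bin edges."""
    counts = np.asarray(list(counts))
    if counts.size == 0:
        raise ValueError("need at least one nucleus")
    return np.histogram(counts, bins=np.asarray(bins, dtype=float))[0]
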