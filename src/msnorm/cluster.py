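"""Clustering ratio: centroid separation over summed cluster sizes.

For a two-class set of spectra the clustering ratio C_R is the Euclidean
distance between the two class centroids divided by the sum of the two
cluster sizes, where a cluster's size is the standard deviation (sample,
n-1) of its members' Euclidean distances from their centroid.  Large C_R
means tight, well-separated classes.  The ratio is computed in the full
feature space of the processed matrix; no dimensionality reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import SpectrumMatrix

__all__ = ["ClusterMetricResult", "clustering_ratio"]


@dataclass(frozen=True)
class ClusterMetricResult:
    """C_R together with its constituents."""

    centroid_separation: float
    cluster_size_1: float
    cluster_size_2: float
    C_R: float
    labels: tuple[str, str]


def _cluster_size(points: np.ndarray, centroid: np.ndarray) -> float:
    distances = np.linalg.norm(points - centroid, axis=1)
    if distances.size < 2:
        raise ValueError("cluster size needs >= 2 members per class")
    return float(distances.std(ddof=1))


def clustering_ratio(matrix: SpectrumMatrix) -> ClusterMetricResult:
    """Compute the clustering ratio C_R of a binary-labelled matrix.

    If both clusters have zero size (all members coincide with their
    centroid) while the centroids are separated, C_R is +inf and a
    warning is emitted, so that grid evaluations over many method
    combinations can complete.
    """
    labels = matrix.require_binary_labels()
    names = sorted({str(v) for v in labels.tolist()})
    masks = [np.array([str(v) == name for v in labels.tolist()]) for name in names]
    for name, mask in zip(names, masks):
        if mask.sum() < 2:
            raise ValueError(f"class {name!r} has fewer than 2 members")

    points = [matrix.intensities[m] for m in masks]
    centroids = [p.mean(axis=0) for p in points]
    separation = float(np.linalg.norm(centroids[0] - centroids[1]))
    sizes = [_cluster_size(p, c) for p, c in zip(points, centroids)]

    denom = sizes[0] + sizes[1]
    if denom > 0:
        ratio = separation / denom
    elif separation > 0:
        warnings.warn(
            "both clusters have zero size with separated centroids; C_R = +inf",
            RuntimeWarning,
            stacklevel=2,
        )
        ratio = float("inf")
    else:
        # fully degenerate: identical points everywhere
        ratio = float("nan")
    return ClusterMetricResult(
        centroid_separation=separation,
        cluster_size_1=sizes[0],
        cluster_size_2=sizes[1],
        C_R=ratio,
        labels=(names[0], names[1]),
    )
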