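"""Spot-wise correlation fields, bootstrap confidence intervals, and
clustering of gene-pair correlation patterns.

A correlation field is the kernel estimate of the correlation between one
gene pair at every spot — the quantity the tests probe, useful on its own
for visualization and for grouping pairs that co-vary spatially.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .data import GeneSet, KernelConfig, SpatialDataset, DistanceProvider, pairwise_distances
from .errors import InvalidConfigError, NotEstimableError
from .kernel import (
    KernelWeights,
    compute_kernel_weights,
    estimate_spot_covariances,
    estimate_spot_means,
    kernel_function,
)

__all__ = [
    "CorrelationField",
    "correlation_field",
    "bootstrap_correlation_ci",
    "cluster_pair_patterns",
]


@dataclass
class CorrelationField:
    """Per-spot correlation estimates for one gene pair, with optional CIs."""

    pair: tuple[str, str]
    values: np.ndarray  # (n,), clipped to [-1, 1]
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None


def correlation_field(
    dataset: SpatialDataset,
    pair: tuple[str, str],
    kernel_config: KernelConfig,
    provider: DistanceProvider | None = None,
    *,
    weights: KernelWeights | None = None,
) -> CorrelationField:
    """Kernel correlation between two genes at every spot:
    ``r_i = cov_i[g, g'] / sqrt(var_i,g * var_i,g')``, clipped to [-1, 1]."""
    gs = GeneSet(f"{pair[0]}|{pair[1]}", list(pair))
    if weights is None:
        D = pairwise_distances(dataset, provider)
        weights = compute_kernel_weights(dataset, D, kernel_config)
    mu = estimate_spot_means(dataset, weights, gs)
    cov = estimate_spot_covariances(dataset, weights, mu, gs)
    r = cov[:, 0, 1] / np.sqrt(cov[:, 0, 0] * cov[:, 1, 1])
    return CorrelationField(pair=tuple(pair), values=np.clip(r, -1.0, 1.0))


def _local_correlation(
    Y: np.ndarray, coords: np.ndarray, focal_coord: np.ndarray, config: KernelConfig
) -> float:
    """Kernel correlation estimate at a focal location from a working set of
    spots (used per bootstrap resample).  Kernel means are recomputed within
    the working set; the focal estimate weights spots by their distance to
    the focal location."""
    D = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    W = np.asarray(kernel_function(D, config.family, config.bandwidth))
    Wn = W / W.sum(axis=1, keepdims=True)
    mu = Wn @ Y
    resid = Y - mu
    d_focal = np.sqrt(((coords - focal_coord) ** 2).sum(-1))
    w = np.asarray(kernel_function(d_focal, config.family, config.bandwidth))
    w = w / w.sum()
    cov = (w[:, None] * resid[:, 0:1] * resid).sum(axis=0)  # [var_g, cov_gg']
    var2 = (w * resid[:, 1] ** 2).sum()
    denom = np.sqrt(cov[0] * var2)
    if denom == 0:
        return np.nan
    return float(np.clip(cov[1] / denom, -1.0, 1.0))


def bootstrap_correlation_ci(
    dataset: SpatialDataset,
    pair: tuple[str, str],
    spot: int | str,
    radius: float,
    n_boot: int,
    level: float,
    rng: np.random.Generator,
    kernel_config: KernelConfig | None = None,
) -> tuple[float, float]:
    """Nonparametric bootstrap CI for the kernel correlation at one spot.

    The neighborhood is every same-region spot within ``radius`` of the focal
    spot (a sensible default radius is twice the kernel bandwidth); it is
    resampled with replacement ``n_boot`` times, the kernel correlation at
    the focal location is recomputed per resample, and the empirical
    ``(1-level)/2`` / ``1-(1-level)/2`` percentiles are returned.
    """
    if not (0.0 < level < 1.0):
        raise InvalidConfigError(f"level must lie in (0, 1), got {level}")
    if radius <= 0:
        raise InvalidConfigError("radius must be positive")
    if n_boot < 1:
        raise InvalidConfigError("n_boot must be >= 1")
    if kernel_config is None:
        kernel_config = KernelConfig()
    if isinstance(spot, str):
        hits = np.flatnonzero(dataset.spot_ids == spot)
        if hits.size == 0:
            raise KeyError(f"spot {spot!r} not found")
        spot = int(hits[0])
    coords = dataset.coordinates
    if coords is None:
        raise InvalidConfigError("bootstrap CI requires coordinates")
    focal = coords[spot]
    same_region = dataset.region_labels == dataset.region_labels[spot]
    dist = np.sqrt(((coords - focal) ** 2).sum(-1))
    nbhd = np.flatnonzero(same_region & (dist <= radius))
    if nbhd.size < 3:
        raise NotEstimableError(
            f"neighborhood of spot {dataset.spot_ids[spot]!r} has {nbhd.size} "
            f"spots within radius {radius}; >=3 required"
        )
    gidx = dataset.gene_index(list(pair))
    Y = dataset.expression[np.ix_(nbhd, gidx)]
    C = coords[nbhd]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, nbhd.size, size=nbhd.size)
        stats[b] = _local_correlation(Y[take], C[take], focal, kernel_config)
    stats = stats[np.isfinite(stats)]
    if stats.size == 0:
        raise NotEstimableError("all bootstrap resamples were degenerate")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lower), float(upper)


def cluster_pair_patterns(
    fields: list[CorrelationField],
    n_clusters: int | None = None,
    cut_height: float | None = None,
    metric: str = "euclidean",
    method: str = "average",
) -> tuple[dict[tuple[str, str], int], np.ndarray]:
    """Group gene pairs by the similarity of their correlation patterns
    across the slide.

    Hierarchical agglomerative clustering (Euclidean distance, average
    linkage by default) of the per-pair correlation vectors.  Returns a
    ``pair -> subgroup`` mapping plus the scipy linkage (merge-tree) matrix.
    """
    if len(fields) < 2:
        raise InvalidConfigError("need >=2 correlation fields to cluster")
    lengths = {f.values.shape[0] for f in fields}
    if len(lengths) != 1:
        raise InvalidConfigError(
            f"fields cover differing spot sets (lengths {sorted(lengths)})"
        )
    if (n_clusters is None) == (cut_height is None):
        raise InvalidConfigError("specify exactly one of n_clusters / cut_height")
    X = np.stack([f.values for f in fields])
    Z = hierarchy.linkage(X, method=method, metric=metric)
    if n_clusters is not None:
        labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    assignment = {f.pair: int(lab) for f, lab in zip(fields, labels)}
    return assignment, Z
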