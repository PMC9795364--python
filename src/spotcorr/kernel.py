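"""Region-masked kernel weighting and spot-wise moment estimation.

Every estimate at spot *i* is a kernel-weighted average over spots *j* in the
same tissue region, with weight ``1[c_i = c_j] * K(s_i, s_j; γ)``.  The
region mask conditions all estimates on the region assignment, which is what
shields the tests downstream from between-region differences in mean
expression.  Note the Gaussian kernel here decays with the *unsquared*
distance, ``exp(-D/γ)`` — unlike the squared-exponential RBF used by the
simulator's Gaussian process.

The kernel-weight sum at a spot is its "effective neighbors": a continuous
analogue of neighborhood size.  Spots with few effective neighbors produce
high-variance estimates and are removed by :func:`filter_spots` (default
threshold 10); after filtering, the weights must be recomputed on the
surviving spots because removal changes every neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import GeneSet, KernelConfig, SpatialDataset
from .errors import DegenerateGeneError, EmptyResultError, InvalidConfigError

__all__ = [
    "KernelWeights",
    "SpotEstimates",
    "RegionCorrelations",
    "kernel_function",
    "compute_kernel_weights",
    "filter_spots",
    "estimate_spot_means",
    "estimate_spot_variances",
    "estimate_spot_covariances",
    "estimate_region_correlations",
]

# relative eigenvalue tolerance below which a kernel covariance is treated as
# PSD; more negative curvature gets a small diagonal jitter
_PSD_RTOL = 1e-8
_PSD_JITTER = 1e-10


@dataclass
class KernelWeights:
    """Region-masked kernel weights and per-spot effective-neighbor counts."""

    weights: np.ndarray  # (n, n), weights[i, j] = 1[c_i=c_j] K(D_ij; γ)
    effective_neighbors: np.ndarray  # (n,), row sums of `weights`

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized weights (each row sums to 1)."""
        return self.weights / self.effective_neighbors[:, None]


@dataclass
class SpotEstimates:
    """Spot-wise kernel moments for a gene set."""

    means: np.ndarray  # (n, m)
    variances: np.ndarray  # (n, m)
    covariances: np.ndarray  # (n, m, m)


@dataclass
class RegionCorrelations:
    """Pearson correlation matrices per region, optionally pooled globally."""

    per_region: dict[str, np.ndarray]
    global_: np.ndarray | None = None


def kernel_function(
    distance: float | np.ndarray, family: str, bandwidth: float
) -> float | np.ndarray:
    """Evaluate the spatial kernel at a (nonnegative) distance.

    gaussian: ``exp(-D/γ)``; triangular: ``max(1 - D/γ, 0)``; uniform:
    ``1`` if ``D < γ`` else ``0`` (boundary excluded).
    """
    if not bandwidth > 0:
        raise InvalidConfigError(f"bandwidth must be > 0, got {bandwidth}")
    D = np.asarray(distance, dtype=float)
    if family == "gaussian":
        out = np.exp(-D / bandwidth)
    elif family == "triangular":
        out = np.maximum(1.0 - D / bandwidth, 0.0)
    elif family == "uniform":
        out = (D < bandwidth).astype(float)
    else:
        raise InvalidConfigError(f"unknown kernel family {family!r}")
    return out if out.ndim else float(out)


def compute_kernel_weights(
    dataset: SpatialDataset, distances: np.ndarray, config: KernelConfig
) -> KernelWeights:
    """Region-masked kernel weight matrix and effective-neighbor counts."""
    n = dataset.n_spots
    D = np.asarray(distances, dtype=float)
    if D.shape != (n, n):
        raise InvalidConfigError(f"distance matrix shape {D.shape} != ({n}, {n})")
    K = np.asarray(kernel_function(D, config.family, config.bandwidth))
    labels = dataset.region_labels
    same_region = labels[:, None] == labels[None, :]
    W = np.where(same_region, K, 0.0)
    return KernelWeights(weights=W, effective_neighbors=W.sum(axis=1))


def filter_spots(
    dataset: SpatialDataset, weights: KernelWeights, threshold: float
) -> tuple[SpatialDataset, np.ndarray]:
    """Drop spots whose effective-neighbor count falls below ``threshold``.

    Returns the filtered dataset and the boolean kept-spot mask.  The caller
    must recompute kernel weights on the filtered dataset before estimating
    anything: removing spots changes the neighborhoods of the survivors.
    """
    if threshold < 0:
        raise InvalidConfigError("threshold must be >= 0")
    mask = weights.effective_neighbors >= threshold
    if not mask.any():
        raise EmptyResultError(
            f"all {dataset.n_spots} spots fall below the effective-neighbors "
            f"threshold {threshold}"
        )
    return dataset.subset_spots(mask), mask


def _geneset_matrix(dataset: SpatialDataset, geneset: GeneSet | None) -> np.ndarray:
    if geneset is None:
        return dataset.expression
    return dataset.expression[:, dataset.gene_index(geneset.genes)]


def estimate_spot_means(
    dataset: SpatialDataset, weights: KernelWeights, geneset: GeneSet | None = None
) -> np.ndarray:
    """Kernel mean ``μ_i`` per spot and gene: the weighted average of
    same-region expression rows (a convex combination, so bounded by the
    region's per-gene min/max)."""
    Y = _geneset_matrix(dataset, geneset)
    return weights.normalized @ Y


def estimate_spot_variances(
    dataset: SpatialDataset,
    weights: KernelWeights,
    means: np.ndarray,
    geneset: GeneSet | None = None,
) -> np.ndarray:
    """Kernel variance per spot and gene.

    Each contributing spot's residual is taken against *its own* kernel mean
    ``μ_j`` (not the focal spot's), mirroring the mean-smoothing step.
    """
    Y = _geneset_matrix(dataset, geneset)
    resid = Y - means
    return weights.normalized @ (resid**2)


def estimate_spot_covariances(
    dataset: SpatialDataset,
    weights: KernelWeights,
    means: np.ndarray,
    geneset: GeneSet | None = None,
    *,
    check_degenerate: bool = True,
) -> np.ndarray:
    """Kernel covariance matrix per spot: the weighted average of residual
    outer products ``(y_j - μ_j)(y_j - μ_j)^T`` over same-region spots.

    Returns an ``(n, m, m)`` stack of symmetric PSD matrices whose diagonals
    equal :func:`estimate_spot_variances`.  Raises
    :class:`DegenerateGeneError` if any gene has exactly zero variance at a
    spot (its correlation there is undefined).
    """
    Y = _geneset_matrix(dataset, geneset)
    n, m = Y.shape
    resid = Y - means
    outer = resid[:, :, None] * resid[:, None, :]  # (n, m, m)
    cov = (weights.normalized @ outer.reshape(n, m * m)).reshape(n, m, m)
    cov = 0.5 * (cov + cov.transpose(0, 2, 1))
    if check_degenerate:
        diag = np.diagonal(cov, axis1=1, axis2=2)
        # a constant gene produces residuals at float rounding scale, not an
        # exact zero; anything this far below the data scale is degenerate
        floor = 1e-24 * max(1.0, float((Y**2).mean()))
        degenerate = diag <= floor
        if degenerate.any():
            i, g = np.argwhere(degenerate)[0]
            gene = (geneset.genes[g] if geneset is not None else dataset.gene_ids[g])
            raise DegenerateGeneError(
                f"gene {gene!r} has zero kernel variance at spot "
                f"{dataset.spot_ids[i]!r}; correlation undefined"
            )
    return _ensure_psd(cov)


def _ensure_psd(cov: np.ndarray) -> np.ndarray:
    """Jitter covariance stacks whose smallest eigenvalue dips below the
    relative PSD tolerance; leaves well-behaved stacks untouched."""
    eig = np.linalg.eigvalsh(cov)
    lo, hi = eig[:, 0], eig[:, -1]
    bad = lo < -_PSD_RTOL * np.maximum(hi, 1.0)
    if bad.any():
        cov = cov.copy()
        m = cov.shape[1]
        cov[bad] += (_PSD_JITTER - lo[bad, None, None]) * np.eye(m)
    return cov


def estimate_region_correlations(
    dataset: SpatialDataset,
    geneset: GeneSet | None = None,
    scope: str = "per-region",
    regions: list[str] | None = None,
) -> RegionCorrelations:
    """Pearson correlation matrices over designated spot sets.

    ``scope``:
      - ``"per-region"``: one matrix per region (all spots of that region);
      - ``"global"``: a single matrix pooling the designated regions (all
        regions by default) — the BR-test's null correlation;
      - ``"region-pair"``: per-region matrices *and* the pooled matrix over
        ``regions`` (which must name the pair).
    """
    if scope not in ("per-region", "global", "region-pair"):
        raise InvalidConfigError(f"unknown scope {scope!r}")
    Y = _geneset_matrix(dataset, geneset)
    use_regions = regions if regions is not None else dataset.regions
    if scope == "region-pair" and (regions is None or len(regions) != 2):
        raise InvalidConfigError("region-pair scope requires exactly two regions")

    per_region: dict[str, np.ndarray] = {}
    if scope in ("per-region", "region-pair"):
        for r in use_regions:
            idx = dataset.region_indices(r)
            per_region[r] = _pearson(Y[idx], dataset, geneset, f"region {r!r}")

    global_ = None
    if scope in ("global", "region-pair"):
        sel = np.isin(dataset.region_labels, use_regions)
        global_ = _pearson(Y[sel], dataset, geneset, "pooled scope")
    return RegionCorrelations(per_region=per_region, global_=global_)


def _pearson(
    Y: np.ndarray, dataset: SpatialDataset, geneset: GeneSet | None, where: str
) -> np.ndarray:
    if Y.shape[0] < 3:
        raise InvalidConfigError(
            f"{where} has {Y.shape[0]} spots; >=3 required for Pearson correlation"
        )
    sd = Y.std(axis=0)
    if (sd == 0).any():
        g = int(np.argwhere(sd == 0)[0][0])
        gene = geneset.genes[g] if geneset is not None else dataset.gene_ids[g]
        raise DegenerateGeneError(
            f"gene {gene!r} has zero variance within {where}"
        )
    R = np.corrcoef(Y, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return np.clip(0.5 * (R + R.T), -1.0, 1.0)
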