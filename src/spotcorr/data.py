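"""Core data model: spatial expression datasets, gene sets, distances, kernels.

A :class:`SpatialDataset` bundles an ``n x m`` expression matrix with 2-D spot
coordinates (or an arbitrary precomputed spot-spot distance matrix via
:class:`DistanceProvider`) and a categorical region label per spot.  Regions
are opaque strings: they are cluster ids or annotated tissue domains, and no
ordering between them is assumed.  Coordinates are kept in the slide's native
units — on the 10x Visium platform the conventional unit is the array
row/column index, which is what the default kernel bandwidth of 5 refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import InvalidConfigError, InvalidDistanceError

__all__ = [
    "SpatialDataset",
    "GeneSet",
    "DistanceProvider",
    "KernelConfig",
    "validate_dataset",
    "pairwise_distances",
]


@dataclass
class SpatialDataset:
    """Normalized expression + coordinates + region labels for one slide.

    Parameters
    ----------
    expression
        ``(n_spots, n_genes)`` float matrix.  For the testing modules this is
        *normalized* expression (e.g. log-CPM); the simulator also uses this
        container for raw UMI counts.
    coordinates
        ``(n_spots, d)`` real matrix of spot positions (``d = 2`` for slides).
        May be ``None`` when a precomputed distance matrix is supplied.
    region_labels
        Length-``n_spots`` array of region ids (strings).
    spot_ids, gene_ids
        Identifier arrays matching the matrix axes.
    size_factors
        Optional per-spot positive exposures (total UMI counts); used by the
        simulator and by count normalization.
    """

    expression: np.ndarray
    coordinates: np.ndarray | None
    region_labels: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    size_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        if self.coordinates is not None:
            self.coordinates = np.asarray(self.coordinates, dtype=float)
        # labels may arrive as a pandas Categorical with declared-but-unused
        # categories; remember those so validation can flag empty regions
        cats = getattr(self.region_labels, "categories", None)
        self._declared_regions = None if cats is None else tuple(cats)
        self.region_labels = np.asarray(self.region_labels, dtype=object)
        self.spot_ids = np.asarray(self.spot_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)

    @property
    def n_spots(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def regions(self) -> list[str]:
        """Distinct region labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.region_labels:
            seen.setdefault(r, None)
        return list(seen)

    def region_indices(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_labels == region)

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not present in dataset: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_spots(self, mask_or_index: np.ndarray) -> "SpatialDataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SpatialDataset(
            expression=self.expression[idx],
            coordinates=None if self.coordinates is None else self.coordinates[idx],
            region_labels=self.region_labels[idx],
            spot_ids=self.spot_ids[idx],
            gene_ids=self.gene_ids,
            size_factors=None if self.size_factors is None else self.size_factors[idx],
        )

    def subset_genes(self, genes: Sequence[str]) -> "SpatialDataset":
        idx = self.gene_index(genes)
        return replace(
            self,
            expression=self.expression[:, idx],
            gene_ids=self.gene_ids[idx],
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (scanpy interoperability)."""
        import anndata
        import pandas as pd

        adata = anndata.AnnData(
            X=self.expression.copy(),
            obs=pd.DataFrame(
                {"region": pd.Categorical(self.region_labels.astype(str))},
                index=self.spot_ids.astype(str),
            ),
            var=pd.DataFrame(index=self.gene_ids.astype(str)),
        )
        if self.coordinates is not None:
            adata.obsm["spatial"] = self.coordinates.copy()
        if self.size_factors is not None:
            adata.obs["size_factor"] = self.size_factors
        return adata

    @classmethod
    def from_anndata(cls, adata, region_key: str = "region") -> "SpatialDataset":
        X = adata.X
        if hasattr(X, "toarray"):
            X = X.toarray()
        size = None
        if "size_factor" in adata.obs:
            size = adata.obs["size_factor"].to_numpy(dtype=float)
        return cls(
            expression=np.asarray(X, dtype=float),
            coordinates=adata.obsm.get("spatial"),
            region_labels=adata.obs[region_key].to_numpy(dtype=object),
            spot_ids=adata.obs_names.to_numpy(dtype=object),
            gene_ids=adata.var_names.to_numpy(dtype=object),
            size_factors=size,
        )


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered collection of >= 2 distinct gene identifiers."""

    name: str
    genes: tuple[str, ...]

    def __init__(self, name: str, genes: Sequence[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "genes", tuple(genes))
        if len(self.genes) < 2:
            raise InvalidConfigError(
                f"gene set {name!r} needs >=2 genes, got {len(self.genes)}"
            )
        if len(set(self.genes)) != len(self.genes):
            raise InvalidConfigError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class DistanceProvider:
    """Pluggable spot-spot distance: Euclidean or an arbitrary precomputed
    matrix (e.g. shortest-path distances along a k-nearest-neighbor graph,
    which need not satisfy the triangle inequality on the slide plane)."""

    mode: Literal["euclidean", "precomputed"] = "euclidean"
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("euclidean", "precomputed"):
            raise InvalidConfigError(f"unknown distance mode {self.mode!r}")
        if self.mode == "precomputed":
            if self.distances is None:
                raise InvalidConfigError("precomputed mode requires a distance matrix")
            D = np.asarray(self.distances, dtype=float)
            if D.ndim != 2 or D.shape[0] != D.shape[1]:
                raise InvalidDistanceError("distance matrix must be square")
            if not np.allclose(D, D.T, atol=1e-12):
                raise InvalidDistanceError("distance matrix must be symmetric")
            if (D < 0).any():
                raise InvalidDistanceError("distances must be nonnegative")
            if not np.allclose(np.diag(D), 0.0, atol=1e-12):
                raise InvalidDistanceError("distance matrix diagonal must be zero")
            object.__setattr__(self, "distances", D)


@dataclass(frozen=True)
class KernelConfig:
    """Spatial weighting kernel configuration.

    ``bandwidth`` (γ) is the decay scale of the kernel in coordinate units;
    the default of 5 is calibrated to Visium array row/column coordinates.
    ``effective_neighbors_threshold`` is the minimum kernel-weight sum a spot
    must reach to be retained (default 10).
    """

    family: Literal["gaussian", "triangular", "uniform"] = "gaussian"
    bandwidth: float = 5.0
    effective_neighbors_threshold: float = 10.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "triangular", "uniform"):
            raise InvalidConfigError(f"unknown kernel family {self.family!r}")
        if not self.bandwidth > 0:
            raise InvalidConfigError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.effective_neighbors_threshold < 0:
            raise InvalidConfigError("effective_neighbors_threshold must be >= 0")


def validate_dataset(dataset: SpatialDataset) -> list[str]:
    """Check the dataset invariants; return one diagnostic string per violation.

    Never raises and never mutates its input — an empty list means the dataset
    is internally consistent.
    """
    diags: list[str] = []
    Y = dataset.expression
    n = Y.shape[0] if Y.ndim == 2 else -1
    if Y.ndim != 2:
        diags.append(f"expression must be 2-D, got ndim={Y.ndim}")
        return diags
    if n < 1:
        diags.append("dataset must contain at least one spot")
    if Y.shape[1] < 1:
        diags.append("dataset must contain at least one gene")
    if not np.isfinite(Y).all():
        diags.append("expression contains non-finite values")
    if dataset.region_labels.shape[0] != n:
        diags.append(
            f"region_labels has {dataset.region_labels.shape[0]} entries "
            f"but expression has {n} rows"
        )
    if dataset.spot_ids.shape[0] != n:
        diags.append(
            f"spot_ids has {dataset.spot_ids.shape[0]} entries "
            f"but expression has {n} rows"
        )
    if dataset.gene_ids.shape[0] != Y.shape[1]:
        diags.append(
            f"gene_ids has {dataset.gene_ids.shape[0]} entries "
            f"but expression has {Y.shape[1]} columns"
        )
    if dataset.coordinates is not None:
        C = dataset.coordinates
        if C.ndim != 2 or C.shape[0] != n:
            diags.append(
                f"coordinates shape {C.shape} inconsistent with {n} spots"
            )
        elif not np.isfinite(C).all():
            diags.append("coordinates contain non-finite values")
    if dataset.size_factors is not None:
        s = dataset.size_factors
        if s.shape[0] != n:
            diags.append(f"size_factors has {s.shape[0]} entries for {n} spots")
        elif not (s > 0).all():
            diags.append("size_factors must be strictly positive")
    # every declared region label must name >=1 spot (only checkable when the
    # labels arrived as a categorical with declared categories)
    cats = getattr(dataset, "_declared_regions", None)
    if cats is not None:
        present = set(dataset.region_labels)
        for c in cats:
            if c not in present:
                diags.append(f"region {c!r} names zero spots")
    return diags


def pairwise_distances(
    dataset: SpatialDataset, provider: DistanceProvider | None = None
) -> np.ndarray:
    """Full ``n x n`` spot-spot distance matrix.

    Euclidean mode computes ``||s_i - s_j||_2`` from the stored coordinates;
    precomputed mode validates shape against the dataset and returns the
    provider's matrix.
    """
    if provider is None:
        provider = DistanceProvider()
    n = dataset.n_spots
    if provider.mode == "euclidean":
        if dataset.coordinates is None:
            raise InvalidConfigError("euclidean distances require coordinates")
        if n == 1:
            return np.zeros((1, 1))
        return squareform(pdist(dataset.coordinates, metric="euclidean"))
    D = provider.distances
    if D.shape != (n, n):
        raise InvalidDistanceError(
            f"precomputed distance matrix shape {D.shape} != ({n}, {n})"
        )
    return D
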