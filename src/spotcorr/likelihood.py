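"""Null/alternative spot-wise covariance models and the likelihood-ratio
statistic for the within-region (WR) and between-region (BR) tests.

Both tests model the normalized expression rows as independent multivariate
normals, ``y_i ~ MVN(μ_i, S_i R_i S_i)``, with kernel-smoothed means and
standard deviations shared between null and alternative so that the
likelihood ratio isolates *correlation* structure:

* WR: the alternative uses the full kernel covariance at each spot (its own
  local correlation), the null replaces every off-diagonal by the region's
  single Pearson correlation scaled by the kernel standard deviations.
  A large statistic means the local correlation varies within the region.
* BR: the alternative uses each spot's own *region-level* Pearson
  correlation, the null uses a single Pearson correlation pooled over the
  scope (a region pair or the whole slide).  A large statistic means the
  regions differ in correlation.

The statistic ``T(Y)`` is the summed per-spot log-density difference; it is
calibrated by permutation (see :mod:`spotcorr.inference`), not by asymptotic
theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import linalg as sla

from .data import GeneSet, KernelConfig, SpatialDataset
from .errors import InvalidConfigError, SingularCovarianceError
from .kernel import (
    KernelWeights,
    estimate_region_correlations,
    estimate_spot_covariances,
    estimate_spot_means,
    estimate_spot_variances,
)

__all__ = [
    "CovarianceModel",
    "StatisticValue",
    "mvn_logdensity",
    "assemble_wr_models",
    "assemble_br_models",
    "likelihood_ratio_statistic",
]

# symmetric diagonal jitter applied to null AND alt covariances so that the
# statistic stays ~0 when the two models coincide near singularity
_JITTER = 1e-10
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class CovarianceModel:
    """Spot-wise MVN model: shared means plus one covariance per spot."""

    means: np.ndarray  # (n, m)
    covariances: np.ndarray  # (n, m, m)
    label: Literal["wr_null", "wr_alt", "br_null", "br_alt"]


@dataclass
class StatisticValue:
    """A likelihood-ratio statistic T(Y) for one tested scope."""

    value: float
    scope: str
    n_spots: int
    geneset: str = ""


def mvn_logdensity(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    """Log density of a multivariate normal at ``y`` (Cholesky-based)."""
    y = np.asarray(y, dtype=float).ravel()
    mu = np.asarray(mu, dtype=float).ravel()
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    m = y.size
    try:
        c, low = sla.cho_factor(sigma, lower=True)
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(f"covariance not SPD: {exc}") from exc
    z = sla.cho_solve((c, low), y - mu)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (m * _LOG_2PI + logdet + (y - mu) @ z))


def _stack_logdensity(resid: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Per-spot MVN log densities for an (n, m, m) covariance stack.

    ``resid`` holds ``y_i - μ_i`` rows.  Uses batched solve/slogdet; raises
    on any singular member.
    """
    m = resid.shape[1]
    sign, logdet = np.linalg.slogdet(cov)
    if not (sign > 0).all():
        raise SingularCovarianceError(
            "singular per-spot covariance encountered (after jitter)"
        )
    z = np.linalg.solve(cov, resid[:, :, None])[:, :, 0]
    quad = np.einsum("ij,ij->i", resid, z)
    return -0.5 * (m * _LOG_2PI + logdet + quad)


def _jitter(cov: np.ndarray) -> np.ndarray:
    m = cov.shape[-1]
    return cov + _JITTER * np.eye(m)


def _scale_correlation(R: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-spot covariance ``R[g,g'] * sd_i,g * sd_i,g'`` from a single
    correlation matrix and an (n, m) array of standard deviations."""
    return R[None, :, :] * sd[:, :, None] * sd[:, None, :]


def assemble_wr_models(
    dataset: SpatialDataset,
    geneset: GeneSet,
    region: str,
    weights: KernelWeights,
) -> tuple[CovarianceModel, CovarianceModel]:
    """Null and alternative covariance models for the WR-test on one region.

    ``dataset``/``weights`` cover the filtered slide; the returned models are
    restricted to the region's spots.  Null: kernel variances on the diagonal
    with the region Pearson correlation on the off-diagonals; alternative:
    the full kernel covariance.  Means are kernel means shared by both.
    """
    idx = dataset.region_indices(region)
    if idx.size < 3:
        raise InvalidConfigError(f"region {region!r} has {idx.size} spots; >=3 required")
    mu = estimate_spot_means(dataset, weights, geneset)
    cov_alt = estimate_spot_covariances(dataset, weights, mu, geneset)
    var = np.diagonal(cov_alt, axis1=1, axis2=2)
    R_C = estimate_region_correlations(dataset, geneset, "per-region", [region])
    sd = np.sqrt(var[idx])
    cov_null = _scale_correlation(R_C.per_region[region], sd)
    null = CovarianceModel(mu[idx], _jitter(cov_null), "wr_null")
    alt = CovarianceModel(mu[idx], _jitter(cov_alt[idx]), "wr_alt")
    return null, alt


def assemble_br_models(
    dataset: SpatialDataset,
    geneset: GeneSet,
    scope: list[str],
    weights: KernelWeights,
) -> tuple[CovarianceModel, CovarianceModel]:
    """Null and alternative covariance models for the BR-test over a scope
    (two or more regions).

    Alternative: each spot uses its *own region's* Pearson correlation; null:
    every spot uses the Pearson correlation pooled over the scope.  Both use
    kernel variances on the diagonal and kernel means.
    """
    if len(scope) < 2:
        raise InvalidConfigError("BR scope must contain at least two regions")
    sel = np.isin(dataset.region_labels, scope)
    mu = estimate_spot_means(dataset, weights, geneset)
    var = estimate_spot_variances(dataset, weights, mu, geneset)
    corr = estimate_region_correlations(
        dataset, geneset, "region-pair" if len(scope) == 2 else "per-region", scope
    )
    if corr.global_ is None:  # >2 regions: pool over the whole scope
        corr.global_ = estimate_region_correlations(
            dataset, geneset, "global", scope
        ).global_
    idx = np.flatnonzero(sel)
    sd = np.sqrt(var[idx])
    labels = dataset.region_labels[idx]
    cov_alt = np.empty((idx.size, len(geneset), len(geneset)))
    for r in scope:
        where = labels == r
        cov_alt[where] = _scale_correlation(corr.per_region[r], sd[where])
    cov_null = _scale_correlation(corr.global_, sd)
    null = CovarianceModel(mu[idx], _jitter(cov_null), "br_null")
    alt = CovarianceModel(mu[idx], _jitter(cov_alt), "br_alt")
    return null, alt


def likelihood_ratio_statistic(
    Y: np.ndarray,
    null: CovarianceModel,
    alt: CovarianceModel,
    scope: str = "",
    geneset: str = "",
) -> StatisticValue:
    """``T = Σ_i [log MVN(y_i; μ_i, Σ_alt,i) - log MVN(y_i; μ_i, Σ_null,i)]``
    over the scope's spots.  ``Y`` must be the expression rows the models
    were assembled on (same order)."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape != null.means.shape:
        raise InvalidConfigError(
            f"expression shape {Y.shape} != model shape {null.means.shape}"
        )
    resid = Y - null.means
    ll_alt = _stack_logdensity(Y - alt.means, alt.covariances)
    ll_null = _stack_logdensity(resid, null.covariances)
    return StatisticValue(
        value=float(np.sum(ll_alt - ll_null)),
        scope=scope,
        n_spots=Y.shape[0],
        geneset=geneset,
    )


# ---------------------------------------------------------------------------
# Fast statistic engines for the permutation loops.
#
# The permutation null recomputes every kernel estimate on each shuffled
# dataset.  Coordinates and region labels never move, so the row-normalized
# weight matrix is fixed and each draw reduces to a handful of matrix
# products.  These engines pre-extract everything permutation-invariant.
# ---------------------------------------------------------------------------


class WRStatisticEngine:
    """Recomputes the WR statistic for one region from (permuted) expression.

    Construct once per region with the region's row-normalized same-region
    weights; call with any row-permuted copy of the region's expression.
    """

    def __init__(self, normalized_weights: np.ndarray):
        self.Wn = normalized_weights  # (n_r, n_r)

    def __call__(self, Y: np.ndarray) -> float:
        Wn = self.Wn
        n, m = Y.shape
        mu = Wn @ Y
        resid = Y - mu
        outer = resid[:, :, None] * resid[:, None, :]
        cov_alt = (Wn @ outer.reshape(n, m * m)).reshape(n, m, m)
        var = np.diagonal(cov_alt, axis1=1, axis2=2)
        sd = np.sqrt(var)
        R = np.corrcoef(Y, rowvar=False)
        cov_null = R[None, :, :] * sd[:, :, None] * sd[:, None, :]
        eye = _JITTER * np.eye(m)
        ll_alt = _stack_logdensity(resid, cov_alt + eye)
        ll_null = _stack_logdensity(resid, cov_null + eye)
        return float(np.sum(ll_alt - ll_null))


class BRStatisticEngine:
    """Recomputes the BR statistic over a scope from (permuted) expression.

    Holds the scope's row-normalized region-masked weights and the per-region
    row index lists; expression rows may have been shuffled across regions
    (the residual-permutation null), in which case each row is evaluated
    under the region of the spot it landed on.
    """

    def __init__(self, normalized_weights: np.ndarray, region_rows: list[np.ndarray]):
        self.Wn = normalized_weights  # (n_scope, n_scope)
        self.region_rows = region_rows

    def __call__(self, Y: np.ndarray) -> float:
        Wn = self.Wn
        n, m = Y.shape
        mu = Wn @ Y
        resid = Y - mu
        outer = resid[:, :, None] * resid[:, None, :]
        var = Wn @ (resid**2)
        sd = np.sqrt(var)
        cov_alt = np.empty((n, m, m))
        for rows in self.region_rows:
            R_r = np.corrcoef(Y[rows], rowvar=False)
            cov_alt[rows] = R_r[None, :, :] * sd[rows, :, None] * sd[rows, None, :]
        R_pool = np.corrcoef(Y, rowvar=False)
        cov_null = R_pool[None, :, :] * sd[:, :, None] * sd[:, None, :]
        eye = _JITTER * np.eye(m)
        ll_alt = _stack_logdensity(resid, cov_alt + eye)
        ll_null = _stack_logdensity(resid, cov_null + eye)
        return float(np.sum(ll_alt - ll_null))
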