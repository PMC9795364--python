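"""Poisson-lognormal simulator for spatial UMI counts with controlled,
smoothly varying latent gene-gene correlation.

The count model at spot *i* with size factor (total-UMI exposure) ``s_i``:

    y_{i,g} ~ Poisson(s_i * λ_{i,g}),    log λ_i ~ MVN(μ, Σ_i)

Spots are mutually independent; all dependence lives between genes within a
spot, through the per-spot latent covariance Σ_i.  Two constructions supply
spatially smooth Σ_i fields:

* pair mode — the Fisher-transformed correlation is a Gaussian-process draw,
  ``atanh(r) ~ MVN(0, cK)``, with ``K`` a squared-exponential (RBF) kernel
  over spot coordinates and ``c`` the "covariance strength".  Then
  ``σ_{1,2,i} = r_i σ_1 σ_2``.
* multi-gene mode — one GP vector ``v_g ~ MVN(0, cK)`` per gene, stacked
  per spot into ``z_i``; the latent covariance ``Φ + z_i z_iᵀ`` (diagonal
  ``Φ`` plus a rank-one update) is PSD by construction and varies smoothly
  elementwise.

Note the simulator's RBF uses the *squared* distance, unlike the test-side
kernel's ``exp(-D/γ)``.

The module also provides the six preset scenarios used to benchmark the
tests, per-region marginal-parameter estimation from raw counts, and the
diagnostic comparing simulated to reference correlation variability.  It
doubles as the repository's synthetic-data generator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import KernelConfig, SpatialDataset
from .errors import InvalidConfigError, SimulationConfigError
from .kernel import compute_kernel_weights
from .patterns import correlation_field

__all__ = [
    "MarginalParams",
    "GPConfig",
    "LatentField",
    "EXPRESSION_LEVELS",
    "rbf_kernel_matrix",
    "sample_pair_correlation_field",
    "sample_multigene_covariance_field",
    "simulate_counts",
    "estimate_marginals",
    "generate_scenario",
    "correlation_level_diagnostic",
    "make_lattice",
    "normalize_log_cpm",
    "lognormal_size_factors",
]

# Target mean UMI count per spot (at the median library size) for the four
# expression tiers the benchmarks span, emulating genes drawn from high to
# low expression ranks of a typical Visium sample.
EXPRESSION_LEVELS: dict[str, float] = {
    "high": 30.0,
    "moderately_high": 15.0,
    "moderately_low": 6.0,
    "low": 2.0,
}

# default latent log-rate variance (CV of λ ≈ 0.53): typical per-gene
# biological variability for a moderately expressed gene
DEFAULT_LATENT_VAR = 0.25
DEFAULT_MEDIAN_SIZE = 10_000.0
DEFAULT_SIZE_SIGMA = 0.25  # lognormal sd of library sizes
DEFAULT_GP_BANDWIDTH = 25.0  # squared-distance scale; length ~5 lattice units


@dataclass
class MarginalParams:
    """Per-region, per-gene latent (μ_g, σ_g²) plus per-spot size factors."""

    regions: list[str]
    mu: np.ndarray  # (n_regions, n_genes)
    var: np.ndarray  # (n_regions, n_genes)
    size_factors: np.ndarray | None = None  # (n_spots,)
    fallback_flags: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.var = np.atleast_2d(np.asarray(self.var, dtype=float))
        if self.mu.shape != self.var.shape:
            raise SimulationConfigError("mu and var shapes differ")
        if not (self.var > 0).all():
            raise SimulationConfigError("latent variances must be > 0")
        if self.size_factors is not None:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if not (self.size_factors > 0).all():
                raise SimulationConfigError("size factors must be > 0")

    def region_row(self, region: str) -> int:
        return self.regions.index(region)

    @classmethod
    def uniform(
        cls,
        regions: list[str],
        mu: np.ndarray,
        var: np.ndarray,
        size_factors: np.ndarray | None = None,
    ) -> "MarginalParams":
        """Same (μ, σ²) per gene in every region."""
        mu = np.asarray(mu, dtype=float)
        var = np.asarray(var, dtype=float)
        R = len(regions)
        return cls(
            regions=list(regions),
            mu=np.tile(mu, (R, 1)),
            var=np.tile(var, (R, 1)),
            size_factors=size_factors,
        )


@dataclass(frozen=True)
class GPConfig:
    """Gaussian-process configuration for latent correlation fields.

    ``bandwidth`` is the squared-distance decay scale of the RBF kernel (the
    default of 25 gives a correlation length of ~5 lattice units);
    ``strength`` (c >= 0) scales the GP covariance — larger values push the
    latent correlations toward ±1.
    """

    bandwidth: float = DEFAULT_GP_BANDWIDTH
    strength: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.bandwidth > 0:
            raise InvalidConfigError("GP bandwidth must be > 0")
        if self.strength < 0:
            raise InvalidConfigError("covariance strength must be >= 0")


@dataclass
class LatentField:
    """Per-spot latent correlation/covariance structure.

    Pair mode: ``r`` holds the per-spot correlation in (-1, 1).  Multi-gene
    mode: ``z`` holds the stacked GP values (one column per gene) and
    ``phi`` the per-spot diagonal of the latent covariance ``Φ + z zᵀ``.
    """

    mode: str  # "pair" | "multigene"
    r: np.ndarray | None = None  # (n,)
    z: np.ndarray | None = None  # (n, G)
    phi: np.ndarray | None = None  # (n, G)

    @property
    def n_spots(self) -> int:
        return (self.r if self.mode == "pair" else self.z).shape[0]

    def covariance_at(self, i: int, variances: np.ndarray | None = None) -> np.ndarray:
        """Latent covariance matrix at spot ``i``.  Pair mode needs the two
        marginal variances."""
        if self.mode == "pair":
            if variances is None:
                raise SimulationConfigError("pair mode needs marginal variances")
            s1, s2 = np.sqrt(variances)
            c12 = self.r[i] * s1 * s2
            return np.array([[variances[0], c12], [c12, variances[1]]])
        return np.diag(self.phi[i]) + np.outer(self.z[i], self.z[i])

    def pairwise_correlation(self, g1: int = 0, g2: int = 1) -> np.ndarray:
        """Per-spot latent correlation between two genes."""
        if self.mode == "pair":
            return self.r.copy()
        num = self.z[:, g1] * self.z[:, g2]
        den = np.sqrt(
            (self.phi[:, g1] + self.z[:, g1] ** 2)
            * (self.phi[:, g2] + self.z[:, g2] ** 2)
        )
        return num / den


def rbf_kernel_matrix(coordinates: np.ndarray, bandwidth: float) -> np.ndarray:
    """Squared-exponential kernel ``exp(-||s_i - s_j||² / γ)`` over spots."""
    if not bandwidth > 0:
        raise InvalidConfigError("bandwidth must be > 0")
    C = np.asarray(coordinates, dtype=float)
    sq = ((C[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    return np.exp(-sq / bandwidth)


def _gp_draw(K: np.ndarray, c: float, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """``size`` independent draws from MVN(0, cK); returns (size, n)."""
    n = K.shape[0]
    if c == 0.0:
        return np.zeros((size, n))
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
    return np.sqrt(c) * (rng.standard_normal((size, n)) @ L.T)


def sample_pair_correlation_field(
    K: np.ndarray, c: float, rng: np.random.Generator
) -> LatentField:
    """Draw a smooth per-spot correlation field for a gene pair:
    ``atanh(r) ~ MVN(0, cK)``, ``r = tanh(·) ∈ (-1, 1)``."""
    fisher = _gp_draw(K, c, rng)[0]
    return LatentField(mode="pair", r=np.tanh(fisher))


def sample_multigene_covariance_field(
    K: np.ndarray, c: float, phi: np.ndarray, n_genes: int, rng: np.random.Generator
) -> LatentField:
    """Draw per-spot latent covariances ``Φ + z_i z_iᵀ`` for ``n_genes``
    genes: one GP vector ``v_g ~ MVN(0, cK)`` per gene, stacked per spot.

    ``phi`` is the positive diagonal of Φ, either one value per gene or a
    full (n_spots, n_genes) array.
    """
    phi = np.asarray(phi, dtype=float)
    n = K.shape[0]
    if phi.ndim == 1:
        if phi.shape[0] != n_genes:
            raise SimulationConfigError("phi length must equal n_genes")
        phi = np.tile(phi, (n, 1))
    if not (phi > 0).all():
        raise SimulationConfigError("phi entries must be > 0")
    z = _gp_draw(K, c, rng, size=n_genes).T  # (n, G)
    return LatentField(mode="multigene", z=z, phi=phi)


def constant_pair_field(n_spots: int, r: float | np.ndarray) -> LatentField:
    """Pair field with a prescribed (possibly per-spot) constant correlation."""
    r = np.broadcast_to(np.asarray(r, dtype=float), (n_spots,)).copy()
    if (np.abs(r) >= 1).any():
        raise SimulationConfigError("pair correlations must lie in (-1, 1)")
    return LatentField(mode="pair", r=r)


def equicorrelated_multigene_field(
    n_spots: int, variances: np.ndarray, rho: float | np.ndarray
) -> LatentField:
    """Multi-gene field with constant pairwise correlation ``rho`` (>= 0)
    between all genes, expressed in the rank-one ``Φ + z zᵀ`` form:
    ``z_g = σ_g sqrt(ρ)``, ``Φ_g = σ_g² (1 - ρ)``."""
    var = np.asarray(variances, dtype=float)
    rho_arr = np.broadcast_to(np.asarray(rho, dtype=float), (n_spots,))
    if ((rho_arr < 0) | (rho_arr >= 1)).any():
        raise SimulationConfigError("equicorrelation requires 0 <= rho < 1")
    sd = np.sqrt(var)
    z = np.sqrt(rho_arr)[:, None] * sd[None, :]
    phi = (1.0 - rho_arr)[:, None] * var[None, :]
    return LatentField(mode="multigene", z=z, phi=phi)


def simulate_counts(
    marginals: MarginalParams,
    latent: LatentField,
    region_labels: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw the Poisson-lognormal count matrix.

    Pair mode draws ``log λ_i`` from the bivariate normal with the region's
    (μ, σ²) and the field's per-spot correlation; multi-gene mode draws from
    ``MVN(μ_region, Φ_i + z_i z_iᵀ)`` (the zero-mean rank-one construction
    shifted by the region means).  Spots are independent.
    """
    labels = np.asarray(region_labels, dtype=object)
    n = labels.shape[0]
    if latent.n_spots != n:
        raise SimulationConfigError(
            f"latent field covers {latent.n_spots} spots, labels cover {n}"
        )
    s = marginals.size_factors
    if s is None:
        s = np.full(n, DEFAULT_MEDIAN_SIZE)
    if s.shape[0] != n:
        raise SimulationConfigError("size factors length mismatch")
    rows = np.array([marginals.region_row(r) for r in labels])
    mu = marginals.mu[rows]  # (n, G)
    var = marginals.var[rows]

    if latent.mode == "pair":
        if mu.shape[1] != 2:
            raise SimulationConfigError("pair mode requires exactly two genes")
        r = latent.r
        if (np.abs(r) >= 1).any():
            raise SimulationConfigError("pair correlations must lie in (-1, 1)")
        u = rng.standard_normal((n, 2))
        sd = np.sqrt(var)
        log_lam = np.empty((n, 2))
        log_lam[:, 0] = mu[:, 0] + sd[:, 0] * u[:, 0]
        log_lam[:, 1] = mu[:, 1] + sd[:, 1] * (
            r * u[:, 0] + np.sqrt(1.0 - r**2) * u[:, 1]
        )
    else:
        G = latent.z.shape[1]
        if mu.shape[1] != G:
            raise SimulationConfigError("marginals/genes mismatch in multigene mode")
        if not (latent.phi > 0).all():
            raise SimulationConfigError("non-PSD latent covariance (phi <= 0)")
        u = rng.standard_normal((n, G))
        w = rng.standard_normal(n)
        log_lam = mu + np.sqrt(latent.phi) * u + latent.z * w[:, None]
    lam = np.exp(log_lam)
    return rng.poisson(s[:, None] * lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Marginal-parameter estimation (hierarchical Bayes, grid posterior)
# ---------------------------------------------------------------------------


def _mom_init(y: np.ndarray, s: np.ndarray) -> tuple[float, float]:
    """Method-of-moments (μ, σ²) under the Poisson-lognormal with exposures."""
    m = y.sum() / s.sum()  # estimate of e^{μ + σ²/2}
    num = ((y - s * m) ** 2 - s * m).sum()
    phi = num / max(m**2 * (s**2).sum(), 1e-300)  # e^{σ²} - 1
    phi = float(np.clip(phi, 1e-3, 50.0))
    var = float(np.log1p(phi))
    return float(np.log(m) - 0.5 * var), var


def _pln_gene_posterior(
    y: np.ndarray,
    s: np.ndarray,
    prior_mu_scale: float,
    cauchy_scale: float,
    sigma_max: float,
    n_grid: int,
    n_quad: int,
) -> tuple[float, float]:
    """Posterior means of (μ, σ²) for one gene in one region.

    Normal prior on μ centered at the log naive rate; half-Cauchy prior on σ
    truncated to (0, sigma_max].  The Poisson-lognormal likelihood is
    integrated per spot by Gauss-Hermite quadrature and the posterior by a
    grid centered at method-of-moments estimates.
    """
    mu0, var0 = _mom_init(y, s)
    naive = np.log(max(y.sum(), 0.5) / s.sum())
    sd0 = np.sqrt(var0)
    n = y.size

    hw = max(0.5, 6.0 * np.sqrt(var0 / n + 1.0 / (y.sum() + 1.0)))
    mu_grid = np.linspace(mu0 - hw, mu0 + hw, n_grid)
    sig_lo = max(sd0 / 5.0, 0.02)
    sig_hi = min(max(sd0 * 5.0, 0.5), sigma_max)
    sig_grid = np.geomspace(sig_lo, sig_hi, n_grid)

    nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(wts) - 0.5 * np.log(np.pi)
    # offsets o[b, k] = sqrt(2) σ_b x_k; M[b, k, i] = logw_k + y_i o_bk
    o = np.sqrt(2.0) * sig_grid[:, None] * nodes[None, :]
    M = logw[None, :, None] + y[None, None, :] * o[:, :, None]
    E = np.exp(o)  # (B, K)
    const = float((y * np.log(s)).sum() - gammaln(y + 1.0).sum())

    loglik = np.empty((n_grid, n_grid))
    sE = E[:, :, None] * s[None, None, :]  # (B, K, n)
    for a, mu_a in enumerate(mu_grid):
        T = M - np.exp(mu_a) * sE  # (B, K, n)
        mx = T.max(axis=1)  # (B, n)
        lse = mx + np.log(np.exp(T - mx[:, None, :]).sum(axis=1))
        loglik[a] = lse.sum(axis=1) + y.sum() * mu_a + const

    log_prior = (
        -0.5 * ((mu_grid[:, None] - naive) / prior_mu_scale) ** 2
        - np.log1p((sig_grid[None, :] / cauchy_scale) ** 2)
    )
    logpost = loglik + log_prior
    logpost -= logpost.max()
    w = np.exp(logpost)
    w /= w.sum()
    mu_hat = float((w.sum(axis=1) * mu_grid).sum())
    var_hat = float((w.sum(axis=0) * sig_grid**2).sum())
    return mu_hat, var_hat


def estimate_marginals(
    counts: np.ndarray,
    size_factors: np.ndarray,
    region_labels: np.ndarray,
    *,
    prior_mu_scale: float = 2.0,
    cauchy_scale: float = 1.0,
    sigma_max: float = 5.0,
    n_grid: int = 41,
    n_quad: int = 25,
) -> MarginalParams:
    """Per-region, per-gene posterior means of the latent (μ_g, σ_g²).

    A gene with zero counts throughout a region cannot inform the posterior;
    it falls back to the prior center (flagged in ``fallback_flags`` and via
    a warning).
    """
    Y = np.asarray(counts)
    if (Y < 0).any() or not np.issubdtype(Y.dtype, np.number):
        raise SimulationConfigError("counts must be nonnegative")
    s = np.asarray(size_factors, dtype=float)
    labels = np.asarray(region_labels, dtype=object)
    regions = list(dict.fromkeys(labels))
    R, G = len(regions), Y.shape[1]
    mu = np.empty((R, G))
    var = np.empty((R, G))
    flags: list[tuple[str, int]] = []
    for ri, region in enumerate(regions):
        idx = np.flatnonzero(labels == region)
        for g in range(G):
            y = Y[idx, g].astype(float)
            if y.sum() == 0:
                warnings.warn(
                    f"gene index {g} has zero counts in region {region!r}; "
                    "falling back to the prior center"
                )
                mu[ri, g] = np.log(0.5 / s[idx].sum())
                var[ri, g] = 1.0
                flags.append((region, g))
                continue
            mu[ri, g], var[ri, g] = _pln_gene_posterior(
                y, s[idx], prior_mu_scale, cauchy_scale, sigma_max, n_grid, n_quad
            )
    return MarginalParams(
        regions=regions, mu=mu, var=var, size_factors=s, fallback_flags=flags
    )


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def make_lattice(nx: int, ny: int) -> np.ndarray:
    """Integer (x, y) coordinates of an ``nx × ny`` grid, row-major order."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


def vertical_bands(coords: np.ndarray, n_bands: int) -> np.ndarray:
    """Split the lattice into ``n_bands`` vertical bands by x coordinate."""
    x = coords[:, 0]
    edges = np.quantile(x, np.linspace(0, 1, n_bands + 1)[1:-1])
    band = np.searchsorted(edges, x, side="right")
    return np.array([f"R{b}" for b in band], dtype=object)


def lognormal_size_factors(
    n: int,
    rng: np.random.Generator,
    median: float = DEFAULT_MEDIAN_SIZE,
    sigma: float = DEFAULT_SIZE_SIGMA,
) -> np.ndarray:
    """Library sizes drawn lognormal around ``median`` (sd ``sigma`` on the
    log scale), emulating spot-to-spot depth variation."""
    return median * np.exp(sigma * rng.standard_normal(n))


def _level_params(level: str, latent_var: float, median_size: float) -> tuple[float, float]:
    """(μ, σ²) giving the level's target mean count at the median library."""
    try:
        target = EXPRESSION_LEVELS[level]
    except KeyError:
        raise InvalidConfigError(
            f"unknown expression level {level!r}; choose from "
            f"{sorted(EXPRESSION_LEVELS)}"
        ) from None
    return float(np.log(target / median_size) - 0.5 * latent_var), latent_var


def generate_scenario(
    name: str,
    rng: np.random.Generator | int | None = None,
    **options,
) -> tuple[SpatialDataset, dict]:
    """Generate one dataset from a preset scenario.

    Scenarios (five vertical-band regions on the lattice unless noted):

    * ``SimI`` — gene pair, GP-varying correlation within each region
      (``c`` in {0, 0.05, 0.1, 0.2, 0.4}; ``c=0`` is a within-region null).
    * ``SimII`` — multi-gene (``n_genes``, default 9) GP covariance fields,
      ``c=0.1``.
    * ``SimIII`` — gene pair, constant correlation within regions, two
      region groups whose correlation differs by ``diff`` (0/0.2/0.4/0.8;
      ``diff=0`` is a between-region null).
    * ``SimIV`` — multi-gene version of SimIII: one group with all pairwise
      correlations 0, the other ``diff`` (default 0.2).
    * ``SimV`` — gene pair, two half-slide regions, no correlation anywhere
      but strongly differing mean expression (a mean-shift robustness null).
    * ``SimVI`` — gene pair, single whole-slide region, GP-varying
      correlation (``c`` in {0.025, 0.05, 0.1}).

    Returns the raw-count :class:`SpatialDataset` (size factors included)
    and a truth dict with the latent field, per-spot latent correlation of
    the first gene pair, and an ``is_null`` flag.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nx, ny = options.pop("lattice", (32, 32))
    level = options.pop("expression_level", "moderately_low")
    latent_var = options.pop("latent_var", DEFAULT_LATENT_VAR)
    median_size = options.pop("median_size", DEFAULT_MEDIAN_SIZE)
    size_sigma = options.pop("size_factor_sigma", DEFAULT_SIZE_SIGMA)
    gp_bandwidth = options.pop("gp_bandwidth", DEFAULT_GP_BANDWIDTH)

    coords = make_lattice(nx, ny)
    n = coords.shape[0]
    sizes = lognormal_size_factors(n, rng, median_size, size_sigma)

    def _pair_marginals(regions, levels=None):
        mu_g, var_g = _level_params(level, latent_var, median_size)
        base = MarginalParams.uniform(
            regions, np.array([mu_g, mu_g]), np.array([var_g, var_g]), sizes
        )
        return base

    if name == "SimI":
        c = options.pop("c", 0.05)
        labels = vertical_bands(coords, options.pop("n_regions", 5))
        _check_no_extra(options, name)
        regions = list(dict.fromkeys(labels))
        r = np.empty(n)
        for region in regions:
            idx = np.flatnonzero(labels == region)
            K = rbf_kernel_matrix(coords[idx], gp_bandwidth)
            r[idx] = sample_pair_correlation_field(K, c, rng).r
        field_ = LatentField(mode="pair", r=r)
        marg = _pair_marginals(regions)
        is_null = c == 0.0
    elif name == "SimII":
        c = options.pop("c", 0.1)
        G = options.pop("n_genes", 9)
        labels = vertical_bands(coords, options.pop("n_regions", 5))
        _check_no_extra(options, name)
        regions = list(dict.fromkeys(labels))
        mu_g, var_g = _level_params(level, latent_var, median_size)
        z = np.empty((n, G))
        for region in regions:
            idx = np.flatnonzero(labels == region)
            K = rbf_kernel_matrix(coords[idx], gp_bandwidth)
            z[idx] = sample_multigene_covariance_field(
                K, c, np.full(G, var_g), G, rng
            ).z
        field_ = LatentField(mode="multigene", z=z, phi=np.full((n, G), var_g))
        marg = MarginalParams.uniform(regions, np.full(G, mu_g), np.full(G, var_g), sizes)
        is_null = c == 0.0
    elif name == "SimIII":
        diff = options.pop("diff", 0.2)
        labels = vertical_bands(coords, options.pop("n_regions", 5))
        _check_no_extra(options, name)
        regions = list(dict.fromkeys(labels))
        group_b = set(regions[len(regions) // 2 + 1 :]) or {regions[-1]}
        r = np.where([lab in group_b for lab in labels], diff, 0.0)
        field_ = constant_pair_field(n, r)
        marg = _pair_marginals(regions)
        is_null = diff == 0.0
    elif name == "SimIV":
        diff = options.pop("diff", 0.2)
        G = options.pop("n_genes", 9)
        labels = vertical_bands(coords, options.pop("n_regions", 5))
        _check_no_extra(options, name)
        regions = list(dict.fromkeys(labels))
        mu_g, var_g = _level_params(level, latent_var, median_size)
        group_b = set(regions[len(regions) // 2 + 1 :]) or {regions[-1]}
        rho = np.where([lab in group_b for lab in labels], diff, 0.0)
        field_ = equicorrelated_multigene_field(n, np.full(G, var_g), rho)
        marg = MarginalParams.uniform(regions, np.full(G, mu_g), np.full(G, var_g), sizes)
        is_null = diff == 0.0
    elif name == "SimV":
        level_b = options.pop("expression_level_b", "low")
        _check_no_extra(options, name)
        labels = vertical_bands(coords, 2)
        regions = list(dict.fromkeys(labels))
        mu_a, var_g = _level_params(level, latent_var, median_size)
        mu_b, _ = _level_params(level_b, latent_var, median_size)
        marg = MarginalParams(
            regions=regions,
            mu=np.array([[mu_a, mu_a], [mu_b, mu_b]]),
            var=np.full((2, 2), var_g),
            size_factors=sizes,
        )
        field_ = constant_pair_field(n, 0.0)
        is_null = True
    elif name == "SimVI":
        c = options.pop("c", 0.05)
        _check_no_extra(options, name)
        labels = np.array(["R0"] * n, dtype=object)
        regions = ["R0"]
        K = rbf_kernel_matrix(coords, gp_bandwidth)
        field_ = sample_pair_correlation_field(K, c, rng)
        marg = _pair_marginals(regions)
        is_null = c == 0.0
    else:
        raise InvalidConfigError(f"unknown scenario {name!r}")

    counts = simulate_counts(marg, field_, labels, rng)
    dataset = SpatialDataset(
        expression=counts.astype(float),
        coordinates=coords,
        region_labels=labels,
        spot_ids=np.array([f"spot{i}" for i in range(n)], dtype=object),
        gene_ids=np.array([f"G{g}" for g in range(counts.shape[1])], dtype=object),
        size_factors=sizes,
    )
    truth = {
        "scenario": name,
        "field": field_,
        "latent_correlation": field_.pairwise_correlation(0, 1),
        "is_null": bool(is_null),
        "marginals": marg,
    }
    return dataset, truth


def _check_no_extra(options: dict, name: str) -> None:
    if options:
        raise InvalidConfigError(f"unknown options for {name}: {sorted(options)}")


def normalize_log_cpm(dataset: SpatialDataset, scale: float = 1e4) -> SpatialDataset:
    """Log counts-per-``scale`` normalization: ``log1p(count / library * scale)``.

    Uses the dataset's size factors as library sizes when present (the
    simulator records the true exposures), else per-spot total counts.
    """
    counts = dataset.expression
    lib = dataset.size_factors
    if lib is None:
        lib = counts.sum(axis=1)
        lib = np.where(lib > 0, lib, 1.0)
    Y = np.log1p(counts / lib[:, None] * scale)
    out = SpatialDataset(
        expression=Y,
        coordinates=dataset.coordinates,
        region_labels=dataset.region_labels,
        spot_ids=dataset.spot_ids,
        gene_ids=dataset.gene_ids,
        size_factors=dataset.size_factors,
    )
    return out


def correlation_level_diagnostic(
    simulated: list[SpatialDataset],
    reference: SpatialDataset,
    reference_pairs: list[tuple[str, str]],
    kernel_config: KernelConfig,
):
    """Compare the spatial variability of kernel correlation estimates
    between simulated replicates and reference gene pairs.

    For each simulated replicate (its first two genes) and each reference
    pair, computes the variance over spots of the spot-wise kernel
    correlation estimates; returns a tidy DataFrame with columns
    ``source`` ('simulated'/'reference'), ``id`` and ``variance``.
    """
    import pandas as pd

    from .inference import preprocess

    rows = []
    for k, ds in enumerate(simulated):
        pair = (ds.gene_ids[0], ds.gene_ids[1])
        filtered, weights, _ = preprocess(ds, kernel_config)
        fld = correlation_field(filtered, pair, kernel_config, weights=weights)
        rows.append(
            {"source": "simulated", "id": f"rep{k}", "variance": float(np.var(fld.values))}
        )
    filtered, weights, _ = preprocess(reference, kernel_config)
    for pair in reference_pairs:
        fld = correlation_field(filtered, pair, kernel_config, weights=weights)
        rows.append(
            {
                "source": "reference",
                "id": f"{pair[0]}|{pair[1]}",
                "variance": float(np.var(fld.values)),
            }
        )
    return pd.DataFrame(rows)
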