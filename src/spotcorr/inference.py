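"""Permutation nulls, sequential Monte Carlo p-values, FDR control, and the
WR/BR test drivers.

Both tests calibrate the likelihood-ratio statistic nonparametrically:

* WR null: within a region, no spatially varying correlation means the
  normalized expression profiles are exchangeable across the region's spots,
  so rows are shuffled within each region.
* BR null: each region's rows are first mean-centered (removing the
  between-region mean differences the test must not react to), then the
  residual rows are shuffled across the whole scope.

P-values use sequential Monte Carlo (SMC) early stopping: draws continue
until ``t`` null statistics reach the observed value (``p = t/l`` with ``l``
the number of draws) or the cap ``g - 1`` is hit (``p = (u+1)/g`` with ``u``
the exceedance count).  Large p-values therefore cost only a handful of
permutations.  Ties between a null statistic and the observed value count as
exceedances, which is the conservative direction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import GeneSet, KernelConfig, SpatialDataset
from .errors import EmptyResultError, InvalidConfigError, NotTestableError
from .kernel import compute_kernel_weights, filter_spots
from .likelihood import BRStatisticEngine, WRStatisticEngine
from .data import DistanceProvider, pairwise_distances

__all__ = [
    "SMCConfig",
    "TestResult",
    "permute_within_regions",
    "center_and_permute_residuals",
    "smc_pvalue",
    "benjamini_hochberg",
    "run_wr_test",
    "run_br_test",
    "rank_gene_pairs",
    "preprocess",
]

_SMC_CHUNK = 64  # permutations evaluated per batch; reduction stays in draw order


@dataclass(frozen=True)
class SMCConfig:
    """Sequential Monte Carlo permutation settings.

    ``exceedance_target`` (t, default 20): null draws reaching the observed
    statistic before stopping.  ``max_permutations`` (g, default 10,000):
    cap; at ``g - 1`` draws the p-value falls back to ``(u+1)/g``.
    ``alpha`` is the BH FDR level used for reporting and for the WR screen.
    """

    exceedance_target: int = 20
    max_permutations: int = 10_000
    seed: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.exceedance_target < 1:
            raise InvalidConfigError("exceedance_target must be >= 1")
        if self.max_permutations <= self.exceedance_target:
            raise InvalidConfigError("max_permutations must exceed exceedance_target")
        if not (0.0 < self.alpha < 1.0):
            raise InvalidConfigError("alpha must lie in (0, 1)")


@dataclass
class TestResult:
    """Outcome of a WR or BR run: one row per tested scope."""

    test: Literal["wr", "br"]
    table: pd.DataFrame  # scope, n_spots, statistic, p_value, n_permutations, q_value, status
    geneset: str = ""
    excluded_regions: list[str] = field(default_factory=list)


def permute_within_regions(
    dataset: SpatialDataset, rng: np.random.Generator
) -> SpatialDataset:
    """Shuffle expression rows among spots sharing a region label.

    Coordinates, labels and ids stay put; the per-region multiset of
    expression profiles is preserved.
    """
    perm = np.arange(dataset.n_spots)
    for r in dataset.regions:
        idx = dataset.region_indices(r)
        perm[idx] = idx[rng.permutation(idx.size)]
    out = SpatialDataset(
        expression=dataset.expression[perm],
        coordinates=dataset.coordinates,
        region_labels=dataset.region_labels,
        spot_ids=dataset.spot_ids,
        gene_ids=dataset.gene_ids,
        size_factors=dataset.size_factors,
    )
    return out


def center_residuals(dataset: SpatialDataset, scope: list[str] | None = None) -> np.ndarray:
    """Per-region mean-centered expression over the scope's spots (scope
    order = original row order restricted to the scope)."""
    regions = scope if scope is not None else dataset.regions
    sel = np.isin(dataset.region_labels, regions)
    Y = dataset.expression[sel].copy()
    labels = dataset.region_labels[sel]
    for r in regions:
        rows = labels == r
        Y[rows] -= Y[rows].mean(axis=0)
    return Y


def center_and_permute_residuals(
    dataset: SpatialDataset, scope: list[str], rng: np.random.Generator
) -> SpatialDataset:
    """BR permutation null: center each region's rows at its mean, then
    shuffle the residual rows across all scope spots regardless of region."""
    sel = np.flatnonzero(np.isin(dataset.region_labels, scope))
    Yc = center_residuals(dataset, scope)
    perm = rng.permutation(sel.size)
    sub = dataset.subset_spots(sel)
    sub.expression = Yc[perm]
    return sub


def smc_pvalue(
    observed: float,
    sampler: Callable[[int], np.ndarray],
    config: SMCConfig,
) -> tuple[float, int]:
    """Sequential Monte Carlo permutation p-value.

    ``sampler(k)`` must return the next ``k`` i.i.d. null statistics in draw
    order.  Stops as soon as ``t`` draws reach ``observed`` (``p = t/l``) or
    after ``g - 1`` draws (``p = (u+1)/g``).  Returns ``(p, l)``.
    """
    t, g = config.exceedance_target, config.max_permutations
    exceed = 0
    drawn = 0
    while drawn < g - 1:
        k = min(_SMC_CHUNK, g - 1 - drawn)
        stats = np.asarray(sampler(k), dtype=float)
        for value in stats:
            drawn += 1
            if value >= observed:
                exceed += 1
                if exceed == t:
                    return t / drawn, drawn
    return (exceed + 1) / g, drawn


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------


def preprocess(
    dataset: SpatialDataset,
    kernel_config: KernelConfig,
    provider: DistanceProvider | None = None,
):
    """Weights → effective-neighbors filter → recomputed weights.

    Returns ``(filtered dataset, kernel weights on the filtered dataset,
    kept mask)``.  Filtering is single-pass.
    """
    D = pairwise_distances(dataset, provider)
    w0 = compute_kernel_weights(dataset, D, kernel_config)
    filtered, mask = filter_spots(
        dataset, w0, kernel_config.effective_neighbors_threshold
    )
    D2 = D[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
    weights = compute_kernel_weights(filtered, D2, kernel_config)
    return filtered, weights, mask


def _testable_regions(dataset: SpatialDataset, min_spots: int = 3) -> list[str]:
    return [r for r in dataset.regions if dataset.region_indices(r).size >= min_spots]


def run_wr_test(
    dataset: SpatialDataset,
    geneset: GeneSet,
    kernel_config: KernelConfig,
    smc_config: SMCConfig,
    provider: DistanceProvider | None = None,
    *,
    weights=None,
) -> TestResult:
    """Within-region test: for each region, is the local correlation of the
    gene set spatially constant?

    ``dataset`` must already have passed the effective-neighbors filter (see
    :func:`preprocess`).  Per region: the observed statistic is computed,
    then SMC permutations shuffle the region's rows, refitting every kernel
    estimate per draw.  BH q-values are computed across regions.
    """
    if weights is None:
        D = pairwise_distances(dataset, provider)
        weights = compute_kernel_weights(dataset, D, kernel_config)
    regions = _testable_regions(dataset)
    if not regions:
        raise EmptyResultError("no region has enough spots to test")
    gidx = dataset.gene_index(geneset.genes)
    Wn = weights.normalized
    seeds = np.random.SeedSequence(smc_config.seed).spawn(len(regions))
    rows = []
    for r, seq in zip(regions, seeds):
        idx = dataset.region_indices(r)
        engine = WRStatisticEngine(Wn[np.ix_(idx, idx)])
        Yr = dataset.expression[np.ix_(idx, gidx)]
        observed = engine(Yr)
        rng = np.random.default_rng(seq)

        def sampler(k: int, _Yr=Yr, _engine=engine, _rng=rng) -> np.ndarray:
            out = np.empty(k)
            for j in range(k):
                out[j] = _engine(_Yr[_rng.permutation(_Yr.shape[0])])
            return out

        p, n_perm = smc_pvalue(observed, sampler, smc_config)
        rows.append(
            {
                "scope": r,
                "n_spots": int(idx.size),
                "statistic": observed,
                "p_value": p,
                "n_permutations": n_perm,
                "status": "ok",
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    return TestResult(test="wr", table=table, geneset=geneset.name)


def _br_engine(
    dataset: SpatialDataset, scope: list[str], Wn: np.ndarray
) -> tuple[BRStatisticEngine, np.ndarray]:
    sel = np.flatnonzero(np.isin(dataset.region_labels, scope))
    labels = dataset.region_labels[sel]
    region_rows = [np.flatnonzero(labels == r) for r in scope]
    engine = BRStatisticEngine(Wn[np.ix_(sel, sel)], region_rows)
    return engine, sel


def run_br_test(
    dataset: SpatialDataset,
    geneset: GeneSet,
    kernel_config: KernelConfig,
    smc_config: SMCConfig,
    wr_results: TestResult | None = None,
    mode: Literal["pairwise", "all-regions"] = "pairwise",
    provider: DistanceProvider | None = None,
    *,
    weights=None,
) -> TestResult:
    """Between-region test: does the gene set's correlation structure differ
    between regions whose internal correlation is constant?

    Regions significant in the WR screen (BH q < alpha) are excluded — the
    between-region comparison is undefined for regions whose correlation
    already varies internally.  Pairwise mode tests every unordered pair of
    surviving regions (BH across pairs); all-regions mode forms one statistic
    over all survivors with residuals permuted across the slide.
    """
    if weights is None:
        D = pairwise_distances(dataset, provider)
        weights = compute_kernel_weights(dataset, D, kernel_config)
    regions = _testable_regions(dataset)
    excluded: list[str] = []
    if wr_results is not None:
        wr_q = dict(zip(wr_results.table["scope"], wr_results.table["q_value"]))
        excluded = [r for r in regions if wr_q.get(r, 1.0) < smc_config.alpha]
        regions = [r for r in regions if r not in excluded]
    if len(regions) < 2:
        raise NotTestableError(
            f"BR-test needs >=2 surviving regions, have {len(regions)} "
            f"(WR screen excluded {excluded})"
        )
    gidx = dataset.gene_index(geneset.genes)
    Wn = weights.normalized
    scopes: list[list[str]]
    if mode == "pairwise":
        scopes = [list(pair) for pair in itertools.combinations(regions, 2)]
    elif mode == "all-regions":
        scopes = [regions]
    else:
        raise InvalidConfigError(f"unknown BR mode {mode!r}")
    seeds = np.random.SeedSequence(smc_config.seed).spawn(len(scopes))
    rows = []
    for scope, seq in zip(scopes, seeds):
        engine, sel = _br_engine(dataset, scope, Wn)
        # observed statistic on centered data: the identity permutation of
        # the residual null must reproduce the observed value
        Yc = center_residuals_for_rows(dataset, scope, sel, gidx)
        observed = engine(Yc)
        rng = np.random.default_rng(seq)

        def sampler(k: int, _Yc=Yc, _engine=engine, _rng=rng) -> np.ndarray:
            out = np.empty(k)
            for j in range(k):
                out[j] = _engine(_Yc[_rng.permutation(_Yc.shape[0])])
            return out

        p, n_perm = smc_pvalue(observed, sampler, smc_config)
        rows.append(
            {
                "scope": " | ".join(scope),
                "n_spots": int(sel.size),
                "statistic": observed,
                "p_value": p,
                "n_permutations": n_perm,
                "status": "ok",
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    return TestResult(
        test="br", table=table, geneset=geneset.name, excluded_regions=excluded
    )


def center_residuals_for_rows(
    dataset: SpatialDataset, scope: list[str], sel: np.ndarray, gidx: np.ndarray
) -> np.ndarray:
    """Region-centered expression for the given scope rows and gene columns."""
    Y = dataset.expression[np.ix_(sel, gidx)].copy()
    labels = dataset.region_labels[sel]
    for r in scope:
        rows = labels == r
        Y[rows] -= Y[rows].mean(axis=0)
    return Y


def rank_gene_pairs(
    dataset: SpatialDataset,
    geneset: GeneSet,
    test: Literal["wr", "br"],
    kernel_config: KernelConfig,
    smc_config: SMCConfig,
    provider: DistanceProvider | None = None,
) -> pd.DataFrame:
    """Run the designated test on every unordered gene pair of the set and
    rank pairs by their minimum p-value over scopes (ascending; ties broken
    by lexicographic gene-id order).  For the BR ranking each pair is first
    screened by its own WR result."""
    if len(geneset) < 2:
        raise InvalidConfigError("need >=2 genes to rank pairs")
    D = pairwise_distances(dataset, provider)
    weights = compute_kernel_weights(dataset, D, kernel_config)
    rows = []
    for g1, g2 in itertools.combinations(geneset.genes, 2):
        pair = GeneSet(f"{g1}|{g2}", [g1, g2])
        wr = run_wr_test(dataset, pair, kernel_config, smc_config, weights=weights)
        if test == "wr":
            p = float(wr.table["p_value"].min())
        else:
            try:
                br = run_br_test(
                    dataset, pair, kernel_config, smc_config, wr, weights=weights
                )
                p = float(br.table["p_value"].min())
            except NotTestableError:
                p = np.nan
        a, b = sorted((g1, g2))
        rows.append({"gene_a": a, "gene_b": b, "p_value": p})
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["p_value", "gene_a", "gene_b"], kind="mergesort"
    ).reset_index(drop=True)
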