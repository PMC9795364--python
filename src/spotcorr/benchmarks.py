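"""Simulation benchmark protocols: type-I error and power of the WR/BR
tests under the preset scenarios.

Each protocol simulates replicate datasets from one scenario (cycling the
four expression tiers), normalizes them (log counts-per-10k), applies the
effective-neighbors filter, runs the designated test, and aggregates:

* false-positive rate — the fraction of all scope-level p-values below 0.05
  on null data;
* power — the fraction of replicate datasets in which *any* scope-level
  p-value falls below 0.05.

Replicates run on a 32 x 32 spot lattice (~1,000 spots, five vertical-band
regions) by default; SMC permutation budgets are reduced relative to the
analysis defaults (the decision boundary at p = 0.05 only needs resolution
well below 0.05).  All randomness derives from a single seed.
"""

from __future__ import annotations

import numpy as np

from .data import GeneSet, KernelConfig
from .errors import NotTestableError
from .inference import SMCConfig, preprocess, run_br_test, run_wr_test
from .simulate import generate_scenario, normalize_log_cpm

__all__ = [
    "wr_null_fpr",
    "br_null_fpr",
    "wr_power",
    "br_power",
    "simv_wr_pvalues",
]

LEVELS = ("high", "moderately_high", "moderately_low", "low")
DEFAULT_LATTICE = (32, 32)
ALPHA = 0.05


def _child_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _run_replicate(scenario, rep_rng, smc_seed, lattice, max_permutations,
                   n_genes=None, **scenario_opts):
    options = dict(lattice=lattice, **scenario_opts)
    if n_genes is not None:
        options["n_genes"] = n_genes
    ds, _ = generate_scenario(scenario, rep_rng, **options)
    norm = normalize_log_cpm(ds)
    kcfg = KernelConfig()
    filtered, weights, _ = preprocess(norm, kcfg)
    genes = [f"G{i}" for i in range(ds.n_genes)]
    gs = GeneSet("bench", genes)
    scfg = SMCConfig(seed=smc_seed, max_permutations=max_permutations)
    wr = run_wr_test(filtered, gs, kcfg, scfg, weights=weights)
    return filtered, weights, gs, kcfg, scfg, wr


def wr_null_fpr(
    n_datasets: int = 200,
    seed: int = 0,
    lattice: tuple[int, int] = DEFAULT_LATTICE,
    max_permutations: int = 1000,
) -> float:
    """Fraction of region-level WR p-values below 0.05 on SimI nulls (c=0)."""
    rngs = _child_seeds(seed, n_datasets)
    pvals = []
    for rep, rng in enumerate(rngs):
        _, _, _, _, _, wr = _run_replicate(
            "SimI", rng, rep, lattice, max_permutations,
            c=0.0, expression_level=LEVELS[rep % 4],
        )
        pvals.extend(wr.table["p_value"])
    return float((np.asarray(pvals) < ALPHA).mean())


def br_null_fpr(
    n_datasets: int = 200,
    seed: int = 0,
    lattice: tuple[int, int] = DEFAULT_LATTICE,
    max_permutations: int = 1000,
) -> float:
    """Fraction of pairwise BR p-values below 0.05 on SimIII nulls (equal
    correlation in both region groups)."""
    rngs = _child_seeds(seed, n_datasets)
    pvals = []
    for rep, rng in enumerate(rngs):
        filtered, weights, gs, kcfg, scfg, wr = _run_replicate(
            "SimIII", rng, rep, lattice, max_permutations,
            diff=0.0, expression_level=LEVELS[rep % 4],
        )
        try:
            br = run_br_test(filtered, gs, kcfg, scfg, wr, weights=weights)
        except NotTestableError:
            continue
        pvals.extend(br.table["p_value"])
    return float((np.asarray(pvals) < ALPHA).mean())


def wr_power(
    n_datasets: int = 30,
    seed: int = 0,
    n_genes: int | None = None,
    c: float = 0.05,
    lattice: tuple[int, int] = DEFAULT_LATTICE,
    max_permutations: int = 500,
) -> float:
    """WR power: fraction of replicates with any region-level p < 0.05.

    ``n_genes=None`` runs the gene-pair scenario (SimI); otherwise the
    multi-gene GP-field scenario (SimII) with that set size.
    """
    rngs = _child_seeds(seed, n_datasets)
    hits = 0
    for rep, rng in enumerate(rngs):
        scenario = "SimI" if n_genes is None else "SimII"
        _, _, _, _, _, wr = _run_replicate(
            scenario, rng, rep, lattice, max_permutations,
            c=c, expression_level=LEVELS[rep % 4],
            n_genes=n_genes,
        )
        hits += bool((wr.table["p_value"] < ALPHA).any())
    return hits / n_datasets


def br_power(
    n_datasets: int = 30,
    seed: int = 0,
    n_genes: int | None = None,
    diff: float = 0.2,
    lattice: tuple[int, int] = DEFAULT_LATTICE,
    max_permutations: int = 500,
) -> float:
    """BR power: fraction of replicates with any pairwise-region p < 0.05.

    ``n_genes=None`` runs gene pairs (SimIII); otherwise SimIV multi-gene
    sets.  Replicates where the WR screen leaves <2 regions count as misses.
    """
    rngs = _child_seeds(seed, n_datasets)
    hits = 0
    for rep, rng in enumerate(rngs):
        scenario = "SimIII" if n_genes is None else "SimIV"
        filtered, weights, gs, kcfg, scfg, wr = _run_replicate(
            scenario, rng, rep, lattice, max_permutations,
            diff=diff, expression_level=LEVELS[rep % 4],
            n_genes=n_genes,
        )
        try:
            br = run_br_test(filtered, gs, kcfg, scfg, wr, weights=weights)
        except NotTestableError:
            continue
        hits += bool((br.table["p_value"] < ALPHA).any())
    return hits / n_datasets


def simv_wr_pvalues(
    n_datasets: int = 50,
    seed: int = 0,
    lattice: tuple[int, int] = DEFAULT_LATTICE,
    max_permutations: int = 1000,
) -> np.ndarray:
    """Pooled WR p-values on SimV (mean shift between regions, no
    correlation anywhere): conditioning on region should keep them uniform."""
    rngs = _child_seeds(seed, n_datasets)
    pvals = []
    for rep, rng in enumerate(rngs):
        # one region high or moderately-high, the other low: a strong mean
        # shift in every replicate
        _, _, _, _, _, wr = _run_replicate(
            "SimV", rng, rep, lattice, max_permutations,
            expression_level=LEVELS[rep % 2],
        )
        pvals.extend(wr.table["p_value"])
    return np.asarray(pvals)
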