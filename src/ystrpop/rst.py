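"""Slatkin's Rst between population pairs by AMOVA on repeat counts.

Rst is the microsatellite analogue of Fst: molecular variance is measured
as squared differences in repeat counts, partitioned within and among
groups by a two-group AMOVA, and ``Rst = sigma2_among / (sigma2_among +
sigma2_within)``. Significance is assessed by permuting individuals
between the two groups and recomputing Rst; multiple pairwise comparisons
are handled with a Bonferroni correction.

Before analysis, datasets pass a YHRD-style filter: haplotypes carrying a
null allele, a partial/intermediate (microvariant) allele, or a duplicated
(multi-allelic) pattern at any included single-copy locus are removed —
DYS385a/b, a naturally duplicated locus, is exempt — and configured loci
(by default DYS458, whose frequent .2 microvariants would otherwise discard
many haplotypes) are dropped entirely.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import Haplotype, PopulationDataset
from .distance import DistanceMatrix
from .panel import DYS385_PAIR, LocusPanel, YFILER_17

__all__ = [
    "RstConfig",
    "RstResult",
    "FilterResult",
    "yhrd_filter",
    "pairwise_rst",
    "permutation_test",
    "rst_matrix_with_bonferroni",
]


@dataclass(frozen=True)
class RstConfig:
    """Settings for the Rst/AMOVA stage."""

    excluded_loci: frozenset = frozenset({"DYS458"})
    n_permutations: int = 10_000
    alpha: float = 0.05
    bonferroni_m: Optional[int] = None  # defaults to k(k-1)/2 pairwise tests
    rng_seed: int = 0
    #: "proportion" (#{perm >= obs}/M) or "plus_one" ((k+1)/(M+1))
    p_estimator: str = "proportion"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.bonferroni_m is not None and self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")


@dataclass
class RstResult:
    pop_a: str
    pop_b: str
    rst: float
    sigma2_among: float
    sigma2_within: float
    p_value: Optional[float] = None
    significant_raw: Optional[bool] = None
    significant_bonferroni: Optional[bool] = None


@dataclass
class FilterResult:
    dataset: PopulationDataset
    removed: List[Tuple[str, str]] = field(default_factory=list)  # (sample, reason)

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def yhrd_filter(
    dataset: PopulationDataset,
    config: RstConfig = RstConfig(),
    panel: LocusPanel = YFILER_17,
) -> FilterResult:
    """Apply the YHRD submission filter and drop excluded loci.

    A haplotype is removed when any included locus other than DYS385a/b
    carries a null, a microvariant, or a multi-allelic pattern. Alleles at
    ``config.excluded_loci`` are dropped for everyone first, so an
    irregularity confined to an excluded locus does not cost the haplotype.
    A null inside the DYS385 pair also forces removal (its repeat count is
    undefined for distance purposes); the log records every removal.
    """
    excluded = set(config.excluded_loci)
    kept: List[Haplotype] = []
    removed: List[Tuple[str, str]] = []
    check_loci = [
        l for l in panel.loci if l not in excluded and l not in DYS385_PAIR
    ]
    pair = [l for l in DYS385_PAIR if l in panel.loci and l not in excluded]
    for hap in dataset:
        reason = None
        for locus in check_loci:
            call = hap.calls[locus]
            if call.is_null:
                reason = f"null allele at {locus}"
            elif call.is_microvariant:
                reason = f"intermediate allele {call.serialize()} at {locus}"
            elif call.is_multi:
                reason = f"duplicated allele {call.serialize()} at {locus}"
            if reason:
                break
        if reason is None:
            for locus in pair:
                if hap.calls[locus].is_null:
                    reason = f"null allele at {locus}"
                    break
        if reason is None:
            kept.append(hap.drop_loci(excluded))
        else:
            removed.append((hap.sample_id, reason))
    return FilterResult(PopulationDataset(dataset.name, kept), removed)


# ---------------------------------------------------------------------------
# AMOVA machinery
# ---------------------------------------------------------------------------

def repeat_matrix(
    dataset: PopulationDataset, loci: Sequence[str]
) -> np.ndarray:
    """n x L matrix of allele sizes (DYS385 pseudo-loci enter separately,
    already canonicalized ascending)."""
    rows = []
    for hap in dataset:
        row = []
        for locus in loci:
            call = hap.calls[locus]
            if call.is_null or call.is_multi:
                raise ValueError(
                    f"sample {hap.sample_id}: non-scalar allele at {locus}; "
                    "run yhrd_filter first"
                )
            row.append(call.size())
        rows.append(row)
    return np.asarray(rows, dtype=float)


def _squared_distance_matrix(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _rst_components(
    d: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
) -> Tuple[float, float, float]:
    """Variance components (sigma2_among, sigma2_within, rst) for one
    two-group split of the pooled squared-distance matrix *d*."""
    n_a, n_b = len(idx_a), len(idx_b)
    n_tot = n_a + n_b
    ss_total = d.sum() / 2.0 / n_tot
    ss_within = (
        d[np.ix_(idx_a, idx_a)].sum() / 2.0 / n_a
        + d[np.ix_(idx_b, idx_b)].sum() / 2.0 / n_b
    )
    ss_among = ss_total - ss_within
    sigma2_within = ss_within / (n_tot - 2)
    n_prime = n_tot - (n_a * n_a + n_b * n_b) / n_tot
    sigma2_among = (ss_among - sigma2_within) / n_prime
    denom = sigma2_among + sigma2_within
    if denom == 0.0:
        raise ValueError("degenerate AMOVA: zero total molecular variance")
    return sigma2_among, sigma2_within, sigma2_among / denom


def _prepare_pair(
    pop_a: PopulationDataset, pop_b: PopulationDataset, loci: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    for pop in (pop_a, pop_b):
        if pop.n < 2:
            raise ValueError(f"population {pop.name!r} has n < 2 after filtering")
    x = np.vstack(
        [repeat_matrix(pop_a, loci), repeat_matrix(pop_b, loci)]
    )
    d = _squared_distance_matrix(x)
    idx_a = np.arange(pop_a.n)
    idx_b = np.arange(pop_a.n, pop_a.n + pop_b.n)
    return d, idx_a, idx_b


def _shared_loci(pop_a: PopulationDataset, pop_b: PopulationDataset) -> List[str]:
    loci_a = set(pop_a.haplotypes[0].calls)
    loci_b = set(pop_b.haplotypes[0].calls)
    shared = [l for l in pop_a.haplotypes[0].calls if l in loci_b]
    if not shared:
        raise ValueError("populations share no loci")
    if loci_a != loci_b:
        shared = [l for l in shared if all(l in h.calls for h in pop_b)]
    return shared


def pairwise_rst(
    pop_a: PopulationDataset,
    pop_b: PopulationDataset,
    config: RstConfig = RstConfig(),
    loci: Optional[Sequence[str]] = None,
) -> RstResult:
    """Slatkin's Rst between two filtered populations (no permutation P).

    Negative Rst (sampling noise around zero differentiation) is reported
    as computed, not clipped.
    """
    loci = list(loci) if loci is not None else _shared_loci(pop_a, pop_b)
    d, idx_a, idx_b = _prepare_pair(pop_a, pop_b, loci)
    s_among, s_within, rst = _rst_components(d, idx_a, idx_b)
    return RstResult(pop_a.name, pop_b.name, rst, s_among, s_within)


def permutation_test(
    pop_a: PopulationDataset,
    pop_b: PopulationDataset,
    config: RstConfig = RstConfig(),
    loci: Optional[Sequence[str]] = None,
    exhaustive: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> RstResult:
    """Rst with a permutation P-value.

    Individuals are pooled and randomly reassigned to groups of the
    original sizes; ``p = #{Rst_perm >= Rst_obs} / M`` (ties counted as >=,
    the conservative choice). With ``exhaustive=True`` every distinct
    assignment of the pooled samples into groups of sizes (n_a, n_b) is
    enumerated instead — the exact permutation distribution, feasible for
    tiny pools.
    """
    loci = list(loci) if loci is not None else _shared_loci(pop_a, pop_b)
    d, idx_a, idx_b = _prepare_pair(pop_a, pop_b, loci)
    s_among, s_within, rst_obs = _rst_components(d, idx_a, idx_b)
    n_tot = len(idx_a) + len(idx_b)
    tol = 1e-12

    if exhaustive:
        n_ge = 0
        n_all = 0
        universe = list(range(n_tot))
        for comb in itertools.combinations(universe, len(idx_a)):
            ia = np.asarray(comb)
            ib = np.asarray([i for i in universe if i not in comb])
            try:
                _, _, r = _rst_components(d, ia, ib)
            except ValueError:
                r = -math.inf
            n_all += 1
            if r >= rst_obs - tol:
                n_ge += 1
        p = n_ge / n_all
    else:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        m = config.n_permutations
        n_ge = 0
        pool = np.arange(n_tot)
        for _ in range(m):
            perm = rng.permutation(pool)
            ia, ib = perm[: len(idx_a)], perm[len(idx_a):]
            try:
                _, _, r = _rst_components(d, ia, ib)
            except ValueError:
                r = -math.inf
            if r >= rst_obs - tol:
                n_ge += 1
        if config.p_estimator == "plus_one":
            p = (n_ge + 1) / (m + 1)
        else:
            p = n_ge / m

    return RstResult(pop_a.name, pop_b.name, rst_obs, s_among, s_within, p_value=p)


def rst_matrix_with_bonferroni(
    datasets: Sequence[PopulationDataset],
    config: RstConfig = RstConfig(),
    loci: Optional[Sequence[str]] = None,
) -> Tuple[DistanceMatrix, Dict[Tuple[str, str], RstResult]]:
    """All pairwise Rst values with permutation P and Bonferroni flags.

    ``bonferroni_m`` defaults to k(k-1)/2 for k datasets; a result is
    significant after correction iff ``p < alpha / bonferroni_m``.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    k = len(datasets)
    m_tests = config.bonferroni_m or k * (k - 1) // 2
    labels = [ds.name for ds in datasets]
    values = np.zeros((k, k))
    results: Dict[Tuple[str, str], RstResult] = {}
    rng = np.random.default_rng(config.rng_seed)
    for i in range(k):
        for j in range(i + 1, k):
            res = permutation_test(datasets[i], datasets[j], config, loci=loci, rng=rng)
            res.significant_raw = res.p_value < config.alpha
            res.significant_bonferroni = res.p_value < config.alpha / m_tests
            values[i, j] = values[j, i] = res.rst
            results[(labels[i], labels[j])] = res
    return DistanceMatrix(labels, values), results


def bonferroni_threshold(alpha: float, m: int, digits: int = 4) -> float:
    """Per-test significance threshold alpha/m, rounded for display."""
    return round(alpha / m, digits)


__all__.append("bonferroni_threshold")
__all__.append("repeat_matrix")
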