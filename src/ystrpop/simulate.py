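"""Synthetic Y-STR data with the statistical structure the analyses assume.

Generates haplotype datasets under a strict single-step mutation model
(SMM): each mutation changes a locus by +/-1 repeat with equal probability,
and the number of mutations a lineage accumulates at a locus over t
generations is Poisson(mu * t). Two genealogies are provided:

* a star: every sampled male descends independently from one founder at
  depth t (the regime in which the rho statistic is calibrated);
* a split: one ancestor diverges for t_split generations into each
  population's founder, each of which then radiates as a star — which
  creates genuine among-population allele-size variance for Rst.

Typing artifacts (null alleles, .2 microvariants, duplication patterns)
can be injected at configurable rates, with a truth log of every change,
to exercise the census and filtering machinery. Everything is
reproducible from the configured seed, and the truth records are rich
enough to compute expected statistics without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .alleles import AlleleValue
from .core import Haplotype, PopulationDataset
from .mjnet import MJNetwork
from .panel import DYS385_PAIR, LocusPanel, YFILER_17

__all__ = [
    "SimulationConfig",
    "StarTruth",
    "SplitTruth",
    "simulate_star_population",
    "simulate_divergent_populations",
    "inject_typing_artifacts",
    "true_star_network",
    "DEFAULT_FOUNDER",
]

#: A modal Yfiler-like founder haplotype (mid-range repeats per locus).
DEFAULT_FOUNDER: Dict[str, int] = {
    "DYS19": 14,
    "DYS385a": 11,
    "DYS385b": 14,
    "DYS389I": 13,
    "DYS389II": 29,
    "DYS390": 23,
    "DYS391": 10,
    "DYS392": 11,
    "DYS393": 12,
    "DYS437": 15,
    "DYS438": 10,
    "DYS439": 11,
    "DYS448": 19,
    "DYS456": 15,
    "DYS458": 17,
    "DYS635": 23,
    "Y_GATA_H4": 12,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the SMM simulators.

    ``mu`` is the per-locus per-generation mutation rate (the pedigree
    Y-STR rate 0.00267 by default); ``t_generations`` the star depth;
    ``t_split`` the divergence time between populations; artifact rates
    are per-call probabilities.
    """

    panel: LocusPanel = YFILER_17
    sizes: Tuple[int, ...] = (102, 104, 86, 102, 106)
    population_names: Tuple[str, ...] = (
        "PopA",
        "PopB",
        "PopC",
        "PopD",
        "PopE",
    )
    mu: float = 0.00267
    t_generations: float = 1000.0
    t_split: float = 1000.0
    founder: Optional[Dict[str, int]] = None
    null_rate: float = 0.0
    microvariant_rate: float = 0.0
    duplication_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("population sizes must be positive")
        for r in (self.null_rate, self.microvariant_rate, self.duplication_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("artifact rates must lie in [0, 1]")

    def founder_vector(self) -> Dict[str, int]:
        if self.founder is not None:
            return dict(self.founder)
        return {l: DEFAULT_FOUNDER.get(l, 12) for l in self.panel.loci}


@dataclass
class StarTruth:
    """Ground truth of a star simulation."""

    founder: Dict[str, int]
    t_generations: float
    mu: float
    #: per sample: total mutation count over all loci
    mutation_counts: Dict[str, int] = field(default_factory=dict)


@dataclass
class SplitTruth:
    t_split: float
    t_within: float
    mu: float
    founders: Dict[str, Dict[str, int]] = field(default_factory=dict)
    star_truths: Dict[str, StarTruth] = field(default_factory=dict)


def _mutate(
    repeats: np.ndarray, mu: float, t: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Apply Poisson(mu*t) +/-1 mutations per locus; returns (new repeats,
    mutation counts per locus)."""
    k = rng.poisson(mu * t, size=repeats.shape)
    steps = np.zeros_like(repeats)
    flat_k = k.ravel()
    flat_steps = steps.ravel()
    for i, ki in enumerate(flat_k):
        if ki:
            flat_steps[i] = rng.choice([-1, 1], size=ki).sum()
    return repeats + steps, k


def _star(
    name: str,
    n: int,
    founder: Dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
    id_prefix: str,
) -> Tuple[PopulationDataset, StarTruth]:
    loci = list(config.panel.loci)
    base = np.asarray([founder[l] for l in loci], dtype=int)
    truth = StarTruth(
        founder=dict(founder), t_generations=config.t_generations, mu=config.mu
    )
    haps: List[Haplotype] = []
    for i in range(n):
        reps, k = _mutate(base.copy(), config.mu, config.t_generations, rng)
        reps = np.maximum(reps, 1)  # repeat counts stay positive
        sample_id = f"{id_prefix}{i+1:04d}"
        calls = {l: AlleleValue.integer(int(r)) for l, r in zip(loci, reps)}
        haps.append(Haplotype(sample_id, name, calls))
        truth.mutation_counts[sample_id] = int(k.sum())
    return PopulationDataset(name, haps), truth


def simulate_star_population(
    config: SimulationConfig = SimulationConfig(),
) -> Tuple[PopulationDataset, StarTruth]:
    """One population radiating from a single founder at depth
    ``t_generations`` (strict SMM; deterministic given ``rng_seed``)."""
    rng = np.random.default_rng(config.rng_seed)
    name = config.population_names[0]
    n = config.sizes[0]
    return _star(name, n, config.founder_vector(), config, rng, f"{name}-")


def simulate_divergent_populations(
    config: SimulationConfig = SimulationConfig(),
    n_populations: Optional[int] = None,
) -> Tuple[List[PopulationDataset], SplitTruth]:
    """Populations that split ``t_split`` generations ago, then each
    radiate as a star of depth ``t_generations``."""
    k = n_populations if n_populations is not None else len(config.sizes)
    if k < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(config.rng_seed)
    loci = list(config.panel.loci)
    ancestor = config.founder_vector()
    base = np.asarray([ancestor[l] for l in loci], dtype=int)
    truth = SplitTruth(
        t_split=config.t_split, t_within=config.t_generations, mu=config.mu
    )
    datasets: List[PopulationDataset] = []
    for p in range(k):
        name = (
            config.population_names[p]
            if p < len(config.population_names)
            else f"Pop{p+1}"
        )
        n = config.sizes[p % len(config.sizes)]
        fr, _ = _mutate(base.copy(), config.mu, config.t_split, rng)
        fr = np.maximum(fr, 1)
        founder = {l: int(r) for l, r in zip(loci, fr)}
        ds, star_truth = _star(name, n, founder, config, rng, f"{name}-")
        truth.founders[name] = founder
        truth.star_truths[name] = star_truth
        datasets.append(ds)
    return datasets, truth


def inject_typing_artifacts(
    dataset: PopulationDataset,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PopulationDataset, List[Tuple[str, str, str]]]:
    """Randomly convert calls to nulls, .2 microvariants, or bi-allelic
    duplication patterns at the configured per-call rates.

    Returns the modified dataset and a truth log of
    ``(sample_id, locus, artifact_kind)`` for every injection.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    log: List[Tuple[str, str, str]] = []
    out: List[Haplotype] = []
    for hap in dataset:
        calls = dict(hap.calls)
        for locus in config.panel.loci:
            call = calls.get(locus)
            if call is None or not call.is_integer:
                continue
            u = rng.random()
            if u < config.null_rate:
                calls[locus] = AlleleValue.null()
                log.append((hap.sample_id, locus, "null"))
            elif u < config.null_rate + config.microvariant_rate:
                calls[locus] = AlleleValue.microvariant(call.repeats, 2)
                log.append((hap.sample_id, locus, "microvariant"))
            elif (
                u < config.null_rate + config.microvariant_rate + config.duplication_rate
                and locus not in DYS385_PAIR
            ):
                calls[locus] = AlleleValue.multi(
                    call, AlleleValue.integer(call.repeats + 1)
                )
                log.append((hap.sample_id, locus, "duplication"))
        out.append(Haplotype(hap.sample_id, hap.population, calls))
    return PopulationDataset(dataset.name, out), log


def null_rejection_rate(
    n_pairs: int = 400,
    n_per_group: int = 50,
    n_permutations: int = 199,
    alpha: float = 0.05,
    rng_seed: int = 0,
    mu: float = 0.00267,
    t_generations: float = 300.0,
) -> float:
    """Type-I-error calibration of the Rst permutation test.

    Each trial simulates one panmictic pool (a single star population of
    2 * n_per_group males) and splits it arbitrarily into two "populations";
    under this null the permutation P should be uniform, so the fraction of
    trials with p < alpha estimates the test's size.
    """
    from .rst import RstConfig, permutation_test

    rng = np.random.default_rng(rng_seed)
    cfg_perm = RstConfig(n_permutations=n_permutations, excluded_loci=frozenset())
    rejections = 0
    for trial in range(n_pairs):
        seed = int(rng.integers(0, 2 ** 31))
        sim_cfg = SimulationConfig(
            sizes=(2 * n_per_group,),
            population_names=("Pool",),
            mu=mu,
            t_generations=t_generations,
            rng_seed=seed,
        )
        pool, _ = simulate_star_population(sim_cfg)
        pa = PopulationDataset("a", pool.haplotypes[:n_per_group])
        pb = PopulationDataset("b", pool.haplotypes[n_per_group:])
        res = permutation_test(
            pa, pb, cfg_perm, rng=np.random.default_rng(seed + 1)
        )
        if res.p_value < alpha:
            rejections += 1
    return rejections / n_pairs


__all__.append("null_rejection_rate")


def true_star_network(truth: StarTruth, n_loci: int) -> MJNetwork:
    """The generating star genealogy as a network: the founder at the
    center, each sample attached by an edge whose length is its true total
    mutation count. Used to calibrate the rho clock against known truth."""
    g = nx.Graph()
    g.add_node("founder", is_median=True, multiplicity=0)
    for sample_id, k in truth.mutation_counts.items():
        g.add_node(sample_id, is_median=False, multiplicity=1)
        g.add_edge("founder", sample_id, length=k)
    return MJNetwork(
        graph=g,
        loci=[f"L{i+1}" for i in range(n_loci)],
        weights=np.ones(n_loci, dtype=int),
    )


def mean_pairwise_asd(dataset: PopulationDataset, loci: Sequence[str]) -> float:
    """Average squared difference in repeat counts over all sample pairs,
    summed over loci. Under the symmetric SMM its expectation for a star
    of depth t is 2 * L * mu * t."""
    x = np.asarray(
        [[h.calls[l].repeats for l in loci] for h in dataset], dtype=float
    )
    n = len(x)
    diff = x[:, None, :] - x[None, :, :]
    total = (diff ** 2).sum()
    return float(total / (n * (n - 1)))


__all__.append("mean_pairwise_asd")
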