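"""Bayesian Y-STR haplogroup prediction and predictor-vs-predictor
discrepancy accounting.

A Y-chromosomal haplogroup is a SNP-defined lineage; given per-haplogroup
allele-frequency tables, an STR profile can be assigned probabilistically:
the likelihood of a haplogroup is the product of its allele frequencies at
the scored loci, the posterior follows from Bayes' rule over the haplogroup
priors, and a "fitness" score compares the profile's likelihood against the
haplogroup's modal (most frequent) profile. Calls whose fitness or
posterior fall below configured thresholds are flagged ambiguous.

The module ships only a small synthetic toy reference table; real
frequency tables (e.g. a 21-haplogroup panel) are loaded from user CSVs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .core import Haplotype, PopulationDataset

__all__ = [
    "HaplogroupRefTable",
    "PredictorConfig",
    "HaplogroupCall",
    "predict_haplogroup",
    "batch_predict_with_thresholds",
    "discrepancy_rates",
    "toy_reference",
]


@dataclass
class HaplogroupRefTable:
    """Per-haplogroup, per-locus allele relative frequencies with priors."""

    frequencies: Dict[str, Dict[str, Dict[str, float]]]  # hg -> locus -> allele -> f
    priors: Dict[str, float]

    def __post_init__(self) -> None:
        for hg, loci in self.frequencies.items():
            for locus, freqs in loci.items():
                s = sum(freqs.values())
                if not math.isclose(s, 1.0, abs_tol=1e-6):
                    raise ValueError(
                        f"frequencies at {hg}/{locus} sum to {s}, expected 1"
                    )
        s = sum(self.priors.values())
        if not math.isclose(s, 1.0, abs_tol=1e-6):
            raise ValueError(f"priors sum to {s}, expected 1")

    @property
    def haplogroups(self) -> List[str]:
        return list(self.frequencies)

    def loci(self, haplogroup: str) -> List[str]:
        return list(self.frequencies[haplogroup])

    @staticmethod
    def from_csv(freq_path, priors_path=None) -> "HaplogroupRefTable":
        """Load from a CSV with columns haplogroup, locus, allele,
        frequency (and optionally a priors CSV with haplogroup, prior);
        without priors, haplogroups are equiprobable."""
        df = pd.read_csv(freq_path)
        freqs: Dict[str, Dict[str, Dict[str, float]]] = {}
        for row in df.itertuples(index=False):
            freqs.setdefault(row.haplogroup, {}).setdefault(row.locus, {})[
                str(row.allele)
            ] = float(row.frequency)
        if priors_path is not None:
            pdf = pd.read_csv(priors_path)
            priors = {
                row.haplogroup: float(row.prior) for row in pdf.itertuples(index=False)
            }
        else:
            k = len(freqs)
            priors = {hg: 1.0 / k for hg in freqs}
        return HaplogroupRefTable(freqs, priors)

    def to_csv(self, freq_path, priors_path=None) -> None:
        rows = [
            (hg, locus, allele, f)
            for hg, loci in self.frequencies.items()
            for locus, freqs in loci.items()
            for allele, f in freqs.items()
        ]
        pd.DataFrame(
            rows, columns=["haplogroup", "locus", "allele", "frequency"]
        ).to_csv(freq_path, index=False)
        if priors_path is not None:
            pd.DataFrame(
                self.priors.items(), columns=["haplogroup", "prior"]
            ).to_csv(priors_path, index=False)


@dataclass(frozen=True)
class PredictorConfig:
    """Thresholds below which a call is flagged ambiguous."""

    fitness_threshold: float = 25.0  # score units, 0-100
    probability_threshold: float = 50.0  # posterior percent
    unseen_allele_floor: float = 1e-4

    def __post_init__(self) -> None:
        if self.fitness_threshold <= 0 or self.probability_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class HaplogroupCall:
    sample_id: str
    best: str
    posterior_percent: float
    fitness: float
    ambiguous: bool
    posteriors: Dict[str, float] = field(default_factory=dict)


def predict_haplogroup(
    haplotype: Haplotype,
    ref: HaplogroupRefTable,
    config: PredictorConfig = PredictorConfig(),
) -> HaplogroupCall:
    """Assign a haplogroup to one STR profile.

    Loci with null or multi-allelic calls are skipped (they carry no usable
    repeat value); unseen alleles are floored at a small frequency so a
    single off-table allele cannot zero the likelihood. Fitness is the
    per-locus geometric-mean likelihood ratio against the best haplogroup's
    modal profile, scaled to 100. Posterior ties break alphabetically and
    force the ambiguous flag.
    """
    loglik: Dict[str, float] = {}
    scored_loci: Dict[str, List[str]] = {}
    for hg in ref.haplogroups:
        ll = 0.0
        used: List[str] = []
        for locus in ref.loci(hg):
            call = haplotype.calls.get(locus)
            if call is None or call.is_null or call.is_multi:
                continue
            allele = call.serialize()
            f = ref.frequencies[hg][locus].get(allele, config.unseen_allele_floor)
            ll += math.log(max(f, config.unseen_allele_floor))
            used.append(locus)
        if not used:
            continue
        loglik[hg] = ll
        scored_loci[hg] = used
    if not loglik:
        raise ValueError(
            f"sample {haplotype.sample_id!r}: no scorable loci against reference"
        )

    max_ll = max(
        loglik[hg] + math.log(ref.priors.get(hg, 0.0) or 1e-300) for hg in loglik
    )
    post_unnorm = {
        hg: math.exp(loglik[hg] + math.log(ref.priors.get(hg, 0.0) or 1e-300) - max_ll)
        for hg in loglik
    }
    z = sum(post_unnorm.values())
    posteriors = {hg: 100.0 * p / z for hg, p in post_unnorm.items()}

    best_post = max(posteriors.values())
    tied = sorted(hg for hg, p in posteriors.items() if math.isclose(p, best_post, rel_tol=1e-12))
    best = tied[0]
    tie = len(tied) > 1

    # fitness: geometric-mean likelihood ratio vs the modal profile of best
    used = scored_loci[best]
    log_modal = sum(
        math.log(max(ref.frequencies[best][locus].values()))
        for locus in used
    )
    fitness = 100.0 * math.exp((loglik[best] - log_modal) / len(used))

    ambiguous = (
        tie
        or fitness < config.fitness_threshold
        or best_post < config.probability_threshold
    )
    return HaplogroupCall(
        sample_id=haplotype.sample_id,
        best=best,
        posterior_percent=best_post,
        fitness=fitness,
        ambiguous=ambiguous,
        posteriors=posteriors,
    )


def batch_predict_with_thresholds(
    dataset: PopulationDataset,
    ref: HaplogroupRefTable,
    config: PredictorConfig = PredictorConfig(),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Predict every sample; tabulate the haplogroup distribution.

    Returns ``(calls, distribution)``. Percentages in the distribution are
    computed over unambiguous calls only; ambiguous calls are listed in the
    call table with their flag set.
    """
    calls = [predict_haplogroup(h, ref, config) for h in dataset]
    call_df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "population": [h.population for h in dataset],
            "haplogroup": [c.best for c in calls],
            "posterior_percent": [round(c.posterior_percent, 2) for c in calls],
            "fitness": [round(c.fitness, 2) for c in calls],
            "ambiguous": [c.ambiguous for c in calls],
        }
    )
    unamb = call_df[~call_df["ambiguous"]]
    if unamb.empty:
        import logging

        logging.getLogger(__name__).warning(
            "all calls ambiguous; empty haplogroup distribution"
        )
        dist = pd.DataFrame(columns=["haplogroup", "count", "percent"])
    else:
        counts = unamb["haplogroup"].value_counts().sort_index()
        dist = pd.DataFrame(
            {
                "haplogroup": counts.index,
                "count": counts.to_numpy(),
                "percent": (100.0 * counts / len(unamb)).round(2).to_numpy(),
            }
        )
    return call_df, dist


_MACRO_RE = re.compile(r"^[A-Za-z]+\d")


def _subclade_only(a: str, b: str) -> bool:
    """True when two differing labels agree down to at least the
    macro-haplogroup letter plus first digit (e.g. J2a1 vs J2a2)."""
    prefix_len = 0
    for ca, cb in zip(a, b):
        if ca != cb:
            break
        prefix_len += 1
    prefix = a[:prefix_len]
    return bool(_MACRO_RE.match(prefix))


def discrepancy_rates(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> Tuple[float, float]:
    """Gross and corrected disagreement rates between two call tables.

    gross = 100 * (#label mismatches) / N over all shared samples;
    corrected = 100 * (#full mismatches among calls unambiguous in table A)
    / (#unambiguous in A), where mismatches that agree at the
    macro-haplogroup level (shared letter+digit prefix, e.g. J2a1 vs J2a2)
    count as sub-clade-level only, not full.
    """
    a = calls_a.set_index("sample_id")
    b = calls_b.set_index("sample_id")
    if set(a.index) != set(b.index):
        raise ValueError("call tables cover different sample IDs")
    b = b.loc[a.index]
    mismatch = a["haplogroup"].to_numpy() != b["haplogroup"].to_numpy()
    gross = 100.0 * mismatch.sum() / len(a)

    unamb_mask = ~a["ambiguous"].to_numpy()
    full = 0
    for ha, hb, mm, un in zip(
        a["haplogroup"], b["haplogroup"], mismatch, unamb_mask
    ):
        if mm and un and not _subclade_only(ha, hb):
            full += 1
    n_unamb = int(unamb_mask.sum())
    if n_unamb == 0:
        raise ValueError("no unambiguous calls in table A")
    corrected = 100.0 * full / n_unamb
    return gross, corrected


def toy_reference() -> HaplogroupRefTable:
    """A small synthetic two-haplogroup reference table for demos/tests.

    Synthetic: the frequencies are invented for illustration, not drawn
    from any published haplogroup panel.
    """
    freqs = {
        "H1": {
            "locus1": {"14": 0.9, "15": 0.1},
            "locus2": {"12": 0.8, "13": 0.2},
        },
        "H2": {
            "locus1": {"14": 0.2, "15": 0.8},
            "locus2": {"12": 0.3, "13": 0.7},
        },
    }
    priors = {"H1": 0.5, "H2": 0.5}
    return HaplogroupRefTable(freqs, priors)
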