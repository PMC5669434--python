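"""Forensic summary statistics and the rare-variant census.

Implements the direct-counting frequency estimates and the standard
parameters of forensic interest for Y-STR datasets:

* gene diversity, Nei's unbiased estimator ``GD = n/(n-1) * (1 - sum p_i^2)``,
  which equals the probability that two samples drawn without replacement
  carry different alleles;
* haplotype diversity (HD), the same estimator applied to whole-haplotype
  frequencies;
* unique haplotypes (UH, % of samples whose haplotype occurs once) and
  discrimination capacity (DC, % of distinct haplotypes among samples);
* a census of irregular calls (microvariants, off-ladder alleles,
  bi-allelic duplication patterns, null alleles) with per-population counts
  and overall frequencies.

DYS385a/b is treated as a single compound category (the unordered pair) for
per-locus gene diversity, with a switch to score the pseudo-loci separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .alleles import AlleleValue
from .core import Haplotype, PopulationDataset, combine
from .panel import DYS385_LABEL, DYS385_PAIR, LocusPanel, YFILER_17

__all__ = [
    "gene_diversity",
    "allele_frequencies",
    "forensic_summary",
    "variant_census",
    "average_gene_diversity",
    "FrequencyTable",
    "ForensicSummary",
    "VariantCensus",
]


def gene_diversity(counts: Iterable[int]) -> float:
    """Nei's gene diversity from category counts.

    ``GD = (n/(n-1)) * (1 - sum((c_i/n)^2))`` with ``n = sum(c_i)``.
    Requires n >= 2 (the unbiased correction divides by n-1).
    """
    counts = [int(c) for c in counts if c > 0]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    n = sum(counts)
    if n < 2:
        raise ValueError(f"gene diversity needs n >= 2 observations, got {n}")
    ss = sum((c / n) ** 2 for c in counts)
    return (n / (n - 1)) * (1.0 - ss)


def _dys385_category(hap: Haplotype) -> str:
    a, b = DYS385_PAIR
    return f"{hap.calls[a].serialize()},{hap.calls[b].serialize()}"


@dataclass
class FrequencyTable:
    """Per-locus allele counts and direct-count relative frequencies."""

    counts: Dict[str, Counter]
    n_typed: Dict[str, int]

    def frequencies(self, locus: str) -> Dict[str, float]:
        n = self.n_typed[locus]
        return {a: c / n for a, c in self.counts[locus].items()}

    @property
    def loci(self) -> Tuple[str, ...]:
        return tuple(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus, ctr in self.counts.items():
            n = self.n_typed[locus]
            for allele, c in sorted(ctr.items()):
                rows.append((locus, allele, c, c / n))
        return pd.DataFrame(rows, columns=["locus", "allele", "count", "frequency"])


def allele_frequencies(
    dataset: PopulationDataset,
    panel: LocusPanel = YFILER_17,
    joint_dys385: bool = True,
) -> FrequencyTable:
    """Direct-count allele frequencies per locus.

    Nulls and multi-allelic patterns count as their own categories; with
    ``joint_dys385`` (default) the DYS385 pair is one compound category
    reported under ``DYS385a/b``.
    """
    if dataset.n == 0:
        raise ValueError("cannot compute frequencies of an empty dataset")
    counts: Dict[str, Counter] = {}
    loci = list(panel.loci)
    use_joint = joint_dys385 and panel.has_dys385_pair
    if use_joint:
        loci = [l for l in loci if l not in DYS385_PAIR]
    for locus in loci:
        counts[locus] = Counter(h.calls[locus].serialize() for h in dataset)
    if use_joint:
        counts[DYS385_LABEL] = Counter(_dys385_category(h) for h in dataset)
    n_typed = {l: dataset.n for l in counts}
    return FrequencyTable(counts=counts, n_typed=n_typed)


@dataclass
class ForensicSummary:
    """Bundle of forensic parameters for one population dataset."""

    name: str
    n: int
    hd: float
    gd: Dict[str, float]
    avg_gd_with_385: float
    avg_gd_without_385: float
    n_unique: int
    n_different: int

    @property
    def uh_percent(self) -> float:
        return 100.0 * self.n_unique / self.n

    @property
    def dc_percent(self) -> float:
        return 100.0 * self.n_different / self.n

    def to_series(self) -> pd.Series:
        data = {
            "Population": self.name,
            "n": self.n,
            "HD": round(self.hd, 5),
            "Average GD (w/ DYS385a/b)": round(self.avg_gd_with_385, 4),
            "Average GD (w/o DYS385a/b)": round(self.avg_gd_without_385, 4),
            "Unique haplotypes": self.n_unique,
            "UH (%)": round(self.uh_percent, 2),
            "Different haplotypes": self.n_different,
            "DC (%)": round(self.dc_percent, 2),
        }
        for locus, g in self.gd.items():
            data[f"GD {locus}"] = round(g, 4)
        return pd.Series(data)


def average_gene_diversity(
    gd: Mapping[str, float]
) -> Tuple[float, float]:
    """Average a per-locus GD mapping with and without the DYS385a/b entry.

    Returns ``(avg_with_385, avg_without_385)``; the "with" average treats
    the DYS385a/b compound category as one locus among the others.
    """
    without = [v for k, v in gd.items() if k != DYS385_LABEL and k not in DYS385_PAIR]
    if not without:
        raise ValueError("no single-copy loci to average")
    avg_without = sum(without) / len(without)
    with_items = list(without)
    for k in (DYS385_LABEL, *DYS385_PAIR):
        if k in gd:
            with_items.append(gd[k])
    avg_with = sum(with_items) / len(with_items)
    return avg_with, avg_without


def forensic_summary(
    dataset: PopulationDataset, panel: LocusPanel = YFILER_17
) -> ForensicSummary:
    """Compute HD, per-locus GD, GD averages, UH and DC for one dataset.

    Haplotype identity is the full serialized profile over the panel's loci,
    including nulls and multi-allelic patterns.
    """
    if dataset.n < 2:
        raise ValueError("forensic summary needs n >= 2 samples")
    freq = allele_frequencies(dataset, panel, joint_dys385=True)
    gd = {locus: gene_diversity(ctr.values()) for locus, ctr in freq.counts.items()}
    avg_with, avg_without = average_gene_diversity(gd)

    profile_counts = Counter(h.profile(panel.loci) for h in dataset)
    hd = gene_diversity(profile_counts.values())
    n_unique = sum(1 for c in profile_counts.values() if c == 1)
    n_different = len(profile_counts)
    return ForensicSummary(
        name=dataset.name,
        n=dataset.n,
        hd=hd,
        gd=gd,
        avg_gd_with_385=avg_with,
        avg_gd_without_385=avg_without,
        n_unique=n_unique,
        n_different=n_different,
    )


# ---------------------------------------------------------------------------
# variant census
# ---------------------------------------------------------------------------

VARIANT = "allelic_variant"      # microvariant or off-ladder integer
BIALLELIC = "biallelic_pattern"  # duplication at a normally single-copy locus
NULL = "null_allele"


def _classify(call: AlleleValue, locus: str, panel: LocusPanel) -> Optional[str]:
    if call.is_null:
        return NULL
    if call.is_multi:
        return BIALLELIC
    if call.is_microvariant:
        return VARIANT
    if not panel.in_ladder(locus, call.repeats):
        return VARIANT
    return None


@dataclass
class VariantCensus:
    """Per-locus, per-population tally of irregular allele calls."""

    table: pd.DataFrame  # locus, variant, class, <pop counts...>, overall_frequency
    total_n: int

    def entries(self, vclass: str) -> pd.DataFrame:
        return self.table[self.table["class"] == vclass]

    @property
    def n_allelic_variants(self) -> int:
        return len(self.entries(VARIANT))

    @property
    def n_variant_loci(self) -> int:
        return self.entries(VARIANT)["locus"].nunique()

    @property
    def n_biallelic_patterns(self) -> int:
        return len(self.entries(BIALLELIC))

    @property
    def n_biallelic_loci(self) -> int:
        return self.entries(BIALLELIC)["locus"].nunique()

    @property
    def n_null_loci(self) -> int:
        return self.entries(NULL)["locus"].nunique()

    def overall_frequency(self, locus: str, variant: str) -> float:
        sel = self.table[
            (self.table["locus"] == locus) & (self.table["variant"] == variant)
        ]
        if sel.empty:
            raise KeyError(f"no census entry for {variant!r} at {locus}")
        return float(sel["overall_frequency"].iloc[0])


def variant_census(
    datasets: Sequence[PopulationDataset] | PopulationDataset,
    panel: LocusPanel = YFILER_17,
) -> VariantCensus:
    """Enumerate microvariants, off-ladder alleles, bi-allelic patterns and
    null alleles, per locus and per population, with overall frequencies
    (= total count / total sample count).

    Bi-allelic patterns at DYS385a/b are normal (duplicated locus) and not
    censused, but a microvariant or off-ladder value inside the DYS385 pair
    is reported under the joint ``DYS385a/b`` label.
    """
    if isinstance(datasets, PopulationDataset):
        datasets = [datasets]
    pops = [ds.name for ds in datasets]
    total_n = sum(ds.n for ds in datasets)
    counts: Dict[Tuple[str, str, str], Counter] = {}

    a385, b385 = DYS385_PAIR
    for ds in datasets:
        for hap in ds:
            for locus in panel.single_copy_loci():
                if locus not in hap.calls:
                    continue
                call = hap.calls[locus]
                vclass = _classify(call, locus, panel)
                if vclass is not None:
                    key = (locus, call.serialize(), vclass)
                    counts.setdefault(key, Counter())[ds.name] += 1
            if panel.has_dys385_pair and a385 in hap.calls and b385 in hap.calls:
                pair = (hap.calls[a385], hap.calls[b385])
                classes = {
                    _classify(c, a385, panel) for c in pair
                }
                classes.discard(None)
                classes.discard(BIALLELIC)
                if classes:
                    vclass = NULL if NULL in classes else VARIANT
                    label = f"{pair[0].serialize()}, {pair[1].serialize()}"
                    key = (DYS385_LABEL, label, vclass)
                    counts.setdefault(key, Counter())[ds.name] += 1

    order = {l: i for i, l in enumerate(list(panel.loci) + [DYS385_LABEL])}
    rows = []
    for (locus, variant, vclass), ctr in sorted(
        counts.items(), key=lambda kv: (order.get(kv[0][0], 99), kv[0][1])
    ):
        total = sum(ctr.values())
        row = {"locus": locus, "variant": variant, "class": vclass}
        for pop in pops:
            row[pop] = ctr.get(pop, 0)
        row["total"] = total
        row["overall_frequency"] = round(total / total_n, 4)
        rows.append(row)
    cols = ["locus", "variant", "class", *pops, "total", "overall_frequency"]
    table = pd.DataFrame(rows, columns=cols)
    return VariantCensus(table=table, total_n=total_n)
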