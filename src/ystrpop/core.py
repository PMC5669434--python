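"""Core containers: a sample's haplotype and a named population of them."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .alleles import AlleleValue
from .panel import DYS385_PAIR, LocusPanel

__all__ = ["Haplotype", "PopulationDataset"]


@dataclass(frozen=True)
class Haplotype:
    """A sample's multi-locus Y-STR profile with its population label.

    The DYS385 pseudo-loci are canonicalized so DYS385a <= DYS385b
    (microvariants ordered by (repeats, partial), so 15.2 sorts between
    15 and 16).
    """

    sample_id: str
    population: str
    calls: Dict[str, AlleleValue]

    def __post_init__(self) -> None:
        a, b = DYS385_PAIR
        if a in self.calls and b in self.calls:
            va, vb = self.calls[a], self.calls[b]
            # nulls sort first; a null pair member stays in slot a
            if vb < va:
                new = dict(self.calls)
                new[a], new[b] = vb, va
                object.__setattr__(self, "calls", new)

    def validate(self, panel: LocusPanel) -> None:
        missing = [l for l in panel.loci if l not in self.calls]
        if missing:
            raise ValueError(
                f"sample {self.sample_id!r} missing loci: {missing}"
            )

    def profile(self, loci: Iterable[str]) -> Tuple[str, ...]:
        """Serialized calls over *loci*, the identity used for haplotype
        matching (includes nulls and multi-allelic patterns verbatim)."""
        return tuple(self.calls[l].serialize() for l in loci)

    def with_calls(self, **updates: AlleleValue) -> "Haplotype":
        new = dict(self.calls)
        new.update(updates)
        return Haplotype(self.sample_id, self.population, new)

    def drop_loci(self, excluded) -> "Haplotype":
        excluded = set(excluded)
        return Haplotype(
            self.sample_id,
            self.population,
            {k: v for k, v in self.calls.items() if k not in excluded},
        )


@dataclass
class PopulationDataset:
    """A named collection of haplotypes (one population sample)."""

    name: str
    haplotypes: List[Haplotype] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [h.sample_id for h in self.haplotypes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample IDs in {self.name!r}: {dupes}")

    @property
    def n(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def __len__(self) -> int:
        return self.n

    def validate(self, panel: LocusPanel) -> None:
        for h in self.haplotypes:
            h.validate(panel)

    def subset(self, keep) -> "PopulationDataset":
        """New dataset with only the haplotypes for which *keep* is true."""
        return PopulationDataset(self.name, [h for h in self.haplotypes if keep(h)])

    def drop_loci(self, excluded) -> "PopulationDataset":
        return PopulationDataset(
            self.name, [h.drop_loci(excluded) for h in self.haplotypes]
        )


def combine(datasets: Iterable[PopulationDataset], name: str = "Combined") -> PopulationDataset:
    """Pool several populations into one dataset (IDs must stay unique)."""
    haps: List[Haplotype] = []
    for ds in datasets:
        haps.extend(ds.haplotypes)
    return PopulationDataset(name, haps)


__all__.append("combine")
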