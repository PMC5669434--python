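"""Locus panel definitions.

The default panel is the 17-locus AmpFlSTR Yfiler set. DYS385 is a
duplicated locus typed as an unordered pair; it is stored as the two
pseudo-loci ``DYS385a``/``DYS385b`` with the convention a <= b after
canonicalization. Each single-copy locus carries the integer allele range
spanned by the kit's allelic ladder, which the variant census uses to flag
rare off-ladder alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import yaml

__all__ = ["LocusPanel", "YFILER_17", "DYS385_PAIR", "DYS385_LABEL"]

DYS385_PAIR = ("DYS385a", "DYS385b")
#: Label under which the unordered DYS385 pair is reported jointly.
DYS385_LABEL = "DYS385a/b"

# Allelic-ladder integer ranges of the Yfiler kit, per locus.
_YFILER_LADDER: Dict[str, Tuple[int, int]] = {
    "DYS19": (10, 19),
    "DYS385a": (7, 25),
    "DYS385b": (7, 25),
    "DYS389I": (10, 15),
    "DYS389II": (24, 34),
    "DYS390": (18, 27),
    "DYS391": (7, 13),
    "DYS392": (7, 18),
    "DYS393": (8, 16),
    "DYS437": (13, 17),
    "DYS438": (8, 13),
    "DYS439": (8, 15),
    "DYS448": (17, 24),
    "DYS456": (13, 18),
    "DYS458": (14, 20),
    "DYS635": (20, 26),
    "Y_GATA_H4": (8, 13),
}

_YFILER_ORDER = (
    "DYS19",
    "DYS385a",
    "DYS385b",
    "DYS389I",
    "DYS389II",
    "DYS390",
    "DYS391",
    "DYS392",
    "DYS393",
    "DYS437",
    "DYS438",
    "DYS439",
    "DYS448",
    "DYS456",
    "DYS458",
    "DYS635",
    "Y_GATA_H4",
)


@dataclass(frozen=True)
class LocusPanel:
    """An ordered set of Y-STR loci with multi-copy annotations.

    Parameters
    ----------
    loci:
        Ordered locus names (pseudo-loci for multi-copy markers).
    multi_copy:
        Subset treated as unordered pairs (the DYS385a/b pseudo-loci).
    ladder:
        Optional per-locus integer allele range of the typing kit's
        allelic ladder; integers outside it are off-ladder variants.
    """

    loci: Tuple[str, ...]
    multi_copy: Tuple[str, ...] = ()
    ladder: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        missing = set(self.multi_copy) - set(self.loci)
        if missing:
            raise ValueError(f"multi_copy loci not in panel: {sorted(missing)}")

    @property
    def total_locus_count(self) -> int:
        return len(self.loci)

    @property
    def has_dys385_pair(self) -> bool:
        return all(l in self.loci for l in DYS385_PAIR)

    def single_copy_loci(self) -> Tuple[str, ...]:
        return tuple(l for l in self.loci if l not in self.multi_copy)

    def drop(self, excluded) -> "LocusPanel":
        """Return a panel without the loci in *excluded*."""
        excluded = set(excluded)
        return LocusPanel(
            loci=tuple(l for l in self.loci if l not in excluded),
            multi_copy=tuple(l for l in self.multi_copy if l not in excluded),
            ladder={k: v for k, v in self.ladder.items() if k not in excluded},
        )

    def in_ladder(self, locus: str, repeats: int) -> bool:
        """Whether an integer allele lies inside the kit ladder range.

        Loci without a configured range accept everything.
        """
        lo_hi = self.ladder.get(locus)
        if lo_hi is None:
            return True
        return lo_hi[0] <= repeats <= lo_hi[1]

    # -- config I/O -------------------------------------------------------
    @staticmethod
    def from_config(path) -> "LocusPanel":
        """Load a panel from a YAML/JSON mapping with keys ``loci``,
        optional ``multi_copy`` and ``ladder``."""
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        ladder = {k: tuple(v) for k, v in (doc.get("ladder") or {}).items()}
        return LocusPanel(
            loci=tuple(doc["loci"]),
            multi_copy=tuple(doc.get("multi_copy", ())),
            ladder=ladder,
        )

    def to_config(self, path) -> None:
        doc = {
            "loci": list(self.loci),
            "multi_copy": list(self.multi_copy),
            "ladder": {k: list(v) for k, v in self.ladder.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


#: The 17-locus AmpFlSTR Yfiler panel (DYS385 as two sorted pseudo-loci).
YFILER_17 = LocusPanel(
    loci=_YFILER_ORDER,
    multi_copy=DYS385_PAIR,
    ladder=dict(_YFILER_LADDER),
)
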