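"""Y-STR allele values and their text representation.

A Y-STR allele call is normally a plain repeat count (``"14"``). Capillary
electrophoresis also produces three classes of irregular call that forensic
tables report verbatim:

* microvariants / intermediate alleles with a partial repeat, written
  ``"18.2"`` (18 full repeats plus 2 bp);
* null alleles (no amplification product, usually a primer-site mutation or
  deletion), written ``"Null"``;
* multi-allelic (duplication) patterns at normally single-copy loci, written
  as a comma-separated list such as ``"19,20"``.

:class:`AlleleValue` models all four kinds with an exact round-tripping
serialization and a total order so that unordered pairs (DYS385a/b) can be
canonicalized; ``15.2`` sorts between ``15`` and ``16``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import total_ordering
from typing import Optional, Tuple

__all__ = ["AlleleValue", "AlleleParseError", "parse_allele", "NULL_TOKENS"]

#: Input spellings accepted for a null allele (case-insensitive).
NULL_TOKENS = frozenset({"null", "-", "0", "null allele"})

#: Canonical output spelling of a null allele.
NULL_OUT = "Null"

_SIMPLE_RE = re.compile(r"^(\d+)(?:\.(\d))?$")


class AlleleParseError(ValueError):
    """Raised when an allele token cannot be interpreted."""


@total_ordering
@dataclass(frozen=True)
class AlleleValue:
    """One locus call: integer repeat, microvariant, null, or multi-allelic.

    Parameters
    ----------
    kind:
        One of ``"integer"``, ``"microvariant"``, ``"null"``, ``"multi"``.
    repeats:
        Full repeat count (absent for null and multi).
    partial:
        Partial repeat in base pairs, 1-4 (microvariant only).
    values:
        Sorted tuple of component alleles (multi only, length >= 2); never
        nests another multi.
    """

    kind: str
    repeats: Optional[int] = None
    partial: Optional[int] = None
    values: Tuple["AlleleValue", ...] = field(default=())

    def __post_init__(self) -> None:
        if self.kind not in ("integer", "microvariant", "null", "multi"):
            raise ValueError(f"unknown allele kind {self.kind!r}")
        if self.kind in ("integer", "microvariant"):
            if self.repeats is None or self.repeats < 0:
                raise ValueError("repeats must be a non-negative integer")
        if self.kind == "microvariant" and self.partial not in (1, 2, 3, 4):
            raise ValueError("microvariant partial must be in 1..4")
        if self.kind == "multi":
            if len(self.values) < 2:
                raise ValueError("multi allele needs >= 2 component values")
            if any(v.kind == "multi" for v in self.values):
                raise ValueError("multi alleles never nest")
            object.__setattr__(self, "values", tuple(sorted(self.values)))

    # -- ordering ---------------------------------------------------------
    def _key(self) -> tuple:
        # Nulls sort first; multis sort by their components.
        if self.kind == "null":
            return (0,)
        if self.kind == "multi":
            return (2,) + tuple(v._key() for v in self.values)
        return (1, self.repeats, self.partial or 0)

    def __lt__(self, other: "AlleleValue") -> bool:
        if not isinstance(other, AlleleValue):
            return NotImplemented
        return self._key() < other._key()

    # -- predicates -------------------------------------------------------
    @property
    def is_integer(self) -> bool:
        return self.kind == "integer"

    @property
    def is_microvariant(self) -> bool:
        return self.kind == "microvariant"

    @property
    def is_null(self) -> bool:
        return self.kind == "null"

    @property
    def is_multi(self) -> bool:
        return self.kind == "multi"

    def size(self) -> float:
        """Numeric size used for sorting/display (partial as tenths)."""
        if self.kind == "null":
            raise ValueError("null allele has no size")
        if self.kind == "multi":
            raise ValueError("multi allele has no single size")
        return self.repeats + (self.partial or 0) / 10.0

    # -- serialization ----------------------------------------------------
    def serialize(self) -> str:
        if self.kind == "null":
            return NULL_OUT
        if self.kind == "integer":
            return str(self.repeats)
        if self.kind == "microvariant":
            return f"{self.repeats}.{self.partial}"
        return ",".join(v.serialize() for v in self.values)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()

    @staticmethod
    def integer(repeats: int) -> "AlleleValue":
        return AlleleValue("integer", repeats=repeats)

    @staticmethod
    def microvariant(repeats: int, partial: int) -> "AlleleValue":
        return AlleleValue("microvariant", repeats=repeats, partial=partial)

    @staticmethod
    def null() -> "AlleleValue":
        return AlleleValue("null")

    @staticmethod
    def multi(*values: "AlleleValue") -> "AlleleValue":
        return AlleleValue("multi", values=tuple(values))


def _parse_simple(token: str, locus: Optional[str]) -> AlleleValue:
    m = _SIMPLE_RE.match(token)
    if m is None:
        where = f" at locus {locus}" if locus else ""
        raise AlleleParseError(f"malformed allele token {token!r}{where}")
    repeats = int(m.group(1))
    if m.group(2) is None:
        return AlleleValue.integer(repeats)
    partial = int(m.group(2))
    if partial not in (1, 2, 3, 4):
        where = f" at locus {locus}" if locus else ""
        raise AlleleParseError(
            f"malformed allele token {token!r}{where}: partial repeat must be 1-4 bp"
        )
    return AlleleValue.microvariant(repeats, partial)


def parse_allele(
    text: str,
    locus: Optional[str] = None,
    null_tokens: frozenset = NULL_TOKENS,
) -> AlleleValue:
    """Parse one allele cell into its canonical :class:`AlleleValue`.

    Comma-separated tokens become a multi-allelic pattern with components
    sorted ascending; any of *null_tokens* (case-insensitive) becomes a null.

    >>> parse_allele("18.2").serialize()
    '18.2'
    >>> parse_allele("20,19").serialize()
    '19,20'
    """
    token = text.strip()
    if not token:
        where = f" at locus {locus}" if locus else ""
        raise AlleleParseError(f"empty allele token{where}")
    if token.lower() in null_tokens:
        return AlleleValue.null()
    if "," in token:
        parts = [p.strip() for p in token.split(",") if p.strip()]
        if len(parts) < 2:
            raise AlleleParseError(f"malformed multi-allele token {text!r}")
        return AlleleValue.multi(*(_parse_simple(p, locus) for p in parts))
    return _parse_simple(token, locus)
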