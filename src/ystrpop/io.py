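"""Reading and writing delimited Y-STR haplotype tables.

The on-disk format is a delimited text table (TSV by default; comma and
semicolon are auto-detected) with a sample-ID column, a population column,
and one column per locus. DYS385 is accepted either as a single ``DYS385``
(or ``DYS385a/b``) column holding the unordered pair ``"11,14"``, or as two
separate ``DYS385a``/``DYS385b`` columns; it is canonicalized ascending
either way. Parsing and writing round-trip exactly.
"""

from __future__ import annotations

import csv
import io as _io
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from .alleles import AlleleParseError, AlleleValue, parse_allele
from .core import Haplotype, PopulationDataset
from .panel import DYS385_PAIR, LocusPanel, YFILER_17

__all__ = ["parse_haplotype_table", "write_haplotype_table", "TableFormatError"]

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = ("sampleid", "sample_id", "sample", "id")
POPULATION_COLUMNS = ("population", "pop", "group", "ethnicity")
DYS385_JOINT_COLUMNS = ("dys385", "dys385a/b", "dys385ab")


class TableFormatError(ValueError):
    """Raised when a haplotype table's layout or content is invalid."""


def _sniff_delimiter(header_line: str) -> str:
    for delim in ("\t", ";", ","):
        if delim in header_line:
            return delim
    return "\t"


def _norm(name: str) -> str:
    return name.strip().lower().replace("-", "_")


def parse_haplotype_table(
    source: Union[str, Path, _io.TextIOBase],
    panel: LocusPanel = YFILER_17,
    delimiter: Optional[str] = None,
) -> List[PopulationDataset]:
    """Parse a delimited haplotype table into per-population datasets.

    Returns one :class:`PopulationDataset` per distinct population label,
    in input order. Cell errors are reported with their row and column.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    lines = text.splitlines()
    if not lines:
        raise TableFormatError("empty haplotype table (no header)")
    delim = delimiter or _sniff_delimiter(lines[0])
    reader = csv.reader(lines, delimiter=delim)
    header = next(reader)
    norm_header = [_norm(h) for h in header]

    def find_col(candidates, what) -> int:
        for i, h in enumerate(norm_header):
            if h in candidates:
                return i
        raise TableFormatError(f"no {what} column found in header {header!r}")

    sample_col = find_col(SAMPLE_COLUMNS, "sample-ID")
    pop_col = find_col(POPULATION_COLUMNS, "population")

    locus_cols: Dict[str, int] = {}
    joint_385_col: Optional[int] = None
    panel_norm = {_norm(l): l for l in panel.loci}
    for i, h in enumerate(norm_header):
        if h in panel_norm:
            locus_cols[panel_norm[h]] = i
        elif h in DYS385_JOINT_COLUMNS:
            joint_385_col = i

    a385, b385 = DYS385_PAIR
    need_pair = panel.has_dys385_pair
    if need_pair and joint_385_col is None:
        if a385 not in locus_cols or b385 not in locus_cols:
            raise TableFormatError(
                "DYS385 must appear as one joint column or two split columns"
            )
    missing = [
        l
        for l in panel.loci
        if l not in locus_cols and not (l in DYS385_PAIR and joint_385_col is not None)
    ]
    if missing:
        raise TableFormatError(f"missing locus columns: {missing}")

    order: List[str] = []
    by_pop: Dict[str, List[Haplotype]] = {}
    seen_ids = set()
    n_rows = 0
    for row_no, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        n_rows += 1
        sample_id = row[sample_col].strip()
        population = row[pop_col].strip()
        if sample_id in seen_ids:
            raise TableFormatError(f"duplicate sample ID {sample_id!r} (row {row_no})")
        seen_ids.add(sample_id)
        calls: Dict[str, AlleleValue] = {}
        try:
            for locus, col in locus_cols.items():
                calls[locus] = parse_allele(row[col], locus=locus)
            if need_pair and joint_385_col is not None:
                tokens = [t for t in row[joint_385_col].split(",") if t.strip()]
                if len(tokens) == 1:
                    # single value: both copies equal (or a lone null)
                    v = parse_allele(tokens[0], locus="DYS385")
                    calls[a385] = calls[b385] = v
                elif len(tokens) == 2:
                    va = parse_allele(tokens[0], locus="DYS385a")
                    vb = parse_allele(tokens[1], locus="DYS385b")
                    calls[a385], calls[b385] = sorted((va, vb))
                else:
                    raise AlleleParseError(
                        f"DYS385 pair cell {row[joint_385_col]!r} has "
                        f"{len(tokens)} values"
                    )
        except AlleleParseError as exc:
            raise TableFormatError(f"row {row_no}: {exc}") from exc
        hap = Haplotype(sample_id, population, calls)
        if population not in by_pop:
            by_pop[population] = []
            order.append(population)
        by_pop[population].append(hap)

    if n_rows == 0:
        log.warning("haplotype table has a header but no data rows")
        return []
    return [PopulationDataset(pop, by_pop[pop]) for pop in order]


def write_haplotype_table(
    datasets: Sequence[PopulationDataset],
    panel: LocusPanel = YFILER_17,
    path: Optional[Union[str, Path]] = None,
    delimiter: str = "\t",
    joint_dys385: bool = False,
) -> str:
    """Serialize datasets to delimited text; inverse of
    :func:`parse_haplotype_table` (semantic round-trip).

    With ``joint_dys385=True`` the DYS385 pair is emitted as one ``"a,b"``
    column instead of two split columns.
    """
    a385, b385 = DYS385_PAIR
    loci = list(panel.loci)
    if joint_dys385 and panel.has_dys385_pair:
        # keep panel order: the joint column sits where DYS385a sat
        cols_out = [l for l in loci if l not in DYS385_PAIR]
        cols_out.insert(loci.index(a385), "DYS385a/b")
        header = ["SampleID", "Population"] + cols_out
    else:
        joint_dys385 = False
        header = ["SampleID", "Population"] + loci

    buf = _io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(header)
    for ds in datasets:
        for hap in ds:
            row = [hap.sample_id, ds.name]
            if joint_dys385:
                for l in header[2:]:
                    if l == "DYS385a/b":
                        row.append(
                            f"{hap.calls[a385].serialize()},{hap.calls[b385].serialize()}"
                        )
                    else:
                        row.append(hap.calls[l].serialize())
            else:
                row.extend(hap.calls[l].serialize() for l in loci)
            writer.writerow(row)
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
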