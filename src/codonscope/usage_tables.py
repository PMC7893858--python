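"""Codon usage tables: counting, parsing, normalization, heat-map export.

The stored primitive is always the raw per-codon *count*; per-thousand,
within-family relative (0-1 and 0-100) and RSCU scales are recomputed from
counts so that no rounding from a source file propagates.  On the 0-100
within-family scale a codon scores 100 when it is the only codon its
organism ever uses for that amino acid; the two single-codon families
(Met/ATG and Trp/TGG) therefore always score 100 in a usable table.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field

import pandas as pd

from .sequence_io import ALL_CODONS, STOP, Cds, GeneticCode, standard_code

MISSING = float("nan")


class TableError(ValueError):
    """Raised for malformed or unusable codon usage tables."""


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts for one organism plus provenance."""

    organism: str
    counts: dict[str, int]
    source: str = ""

    def __post_init__(self) -> None:
        if set(self.counts) != set(ALL_CODONS):
            missing = sorted(set(ALL_CODONS) - set(self.counts))
            raise TableError(f"table missing codons: {', '.join(missing)}")
        if any(v < 0 for v in self.counts.values()):
            raise TableError("negative codon count")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def usable(self) -> bool:
        return self.total > 0

    @property
    def per_thousand(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {c: 0.0 for c in ALL_CODONS}
        return {c: 1000.0 * n / t for c, n in self.counts.items()}


@dataclass(frozen=True)
class NormalizedFrequencies:
    """Derived frequency scales of a usage table under a genetic code."""

    table_id: str
    family_relative: dict[str, float]
    per_thousand: dict[str, float]
    rscu: dict[str, float]
    undefined_families: tuple[str, ...] = ()
    code: GeneticCode = field(default_factory=standard_code)

    @property
    def percent_scale(self) -> dict[str, float]:
        return {c: 100.0 * v for c, v in self.family_relative.items()}

    def family_max(self, codon: str) -> float:
        fam = self.code.family(self.code.codon_to_aa[codon])
        return max(self.family_relative[c] for c in fam)


def count_codons(
    cds_set, organism: str = "custom", source: str = "counted from CDS set"
) -> CodonUsageTable:
    """Build a usage table by counting frame-0 codons across a CDS set.

    Stop codons are counted like any other codon; an empty input yields an
    all-zero table flagged unusable.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for cds in cds_set:
        for codon in cds.codons:
            counts[codon] += 1
    return CodonUsageTable(organism=organism, counts=counts, source=source)


_KAZUSA_TUPLE = re.compile(r"([ACGTUacgtu]{3})\s+([\d.]+)\s*\(\s*(\d+)\s*\)")


def parse_usage_table(path, dialect: str, organism: str | None = None) -> CodonUsageTable:
    """Parse a codon usage table file.

    dialects
        ``kazusa_text``: whitespace-separated tuples ``CODON per-1000 (count)``,
        several per line (the layout Kazusa and HIVE-CUT export as text).
        ``csv_counts``: two-column ``codon,count`` rows, optional header.

    Counts come from the count column only; per-thousand values in the file
    are ignored and recomputed, which avoids inheriting their rounding.
    """
    name = organism or str(path)
    counts: dict[str, int] = {}

    def _add(codon: str, count: int, where: str) -> None:
        codon = codon.upper().replace("U", "T")
        if codon not in ALL_CODONS:
            raise TableError(f"{where}: unknown codon {codon!r}")
        if codon in counts:
            raise TableError(f"{where}: duplicate codon {codon!r}")
        counts[codon] = count

    if dialect == "kazusa_text":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                for m in _KAZUSA_TUPLE.finditer(line):
                    _add(m.group(1), int(m.group(3)), f"{path}:{lineno}")
    elif dialect == "csv_counts":
        with open(path, newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh), start=1):
                if not row or not row[0].strip():
                    continue
                tok = row[0].strip()
                is_header = lineno == 1 and (
                    tok.lower() == "codon"
                    or (len(row) > 1 and not row[1].strip().lstrip("-").isdigit())
                )
                if is_header:
                    continue
                if len(row) < 2:
                    raise TableError(f"{path}:{lineno}: expected codon,count")
                _add(tok, int(row[1]), f"{path}:{lineno}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if set(counts) != set(ALL_CODONS):
        missing = sorted(set(ALL_CODONS) - set(counts))
        raise TableError(f"{path}: missing codons: {', '.join(missing)}")
    return CodonUsageTable(organism=name, counts=counts, source=f"{dialect}:{path}")


def normalize(table: CodonUsageTable, code: GeneticCode | None = None) -> NormalizedFrequencies:
    """Derive within-family relative frequencies and RSCU from counts.

    ``family_relative[c] = count[c] / sum(counts over c's synonymous family)``
    and ``rscu[c] = count[c] / mean(counts over the family)``, so RSCU and
    the relative scale differ only by the family size factor.  A family whose
    codons were never observed gets 0 everywhere and is flagged undefined.
    """
    if not table.usable:
        raise TableError(f"table {table.organism!r} has zero total count")
    gc = code or standard_code()
    family_relative: dict[str, float] = {}
    rscu: dict[str, float] = {}
    undefined: list[str] = []
    for aa, fam in gc.families.items():
        fam_total = sum(table.counts[c] for c in fam)
        if fam_total == 0:
            undefined.append(aa)
            for c in fam:
                family_relative[c] = 0.0
                rscu[c] = 0.0
            continue
        mean = fam_total / len(fam)
        for c in fam:
            family_relative[c] = table.counts[c] / fam_total
            rscu[c] = table.counts[c] / mean
    return NormalizedFrequencies(
        table_id=table.organism,
        family_relative=family_relative,
        per_thousand=table.per_thousand,
        rscu=rscu,
        undefined_families=tuple(undefined),
        code=gc,
    )


def codon_row_order(code: GeneticCode | None = None, include_stops: bool = True) -> list[str]:
    """Stable heat-map row order: amino acids alphabetically by one-letter
    code (stops last as ``*``), codons alphabetically within each family."""
    gc = code or standard_code()
    aas = sorted(a for a in gc.families if a != STOP)
    if include_stops:
        aas.append(STOP)
    order: list[str] = []
    for aa in aas:
        order.extend(sorted(gc.family(aa)))
    return order


def heatmap_matrix(
    freq_sets, labels: list[str] | None = None, code: GeneticCode | None = None
) -> pd.DataFrame:
    """64-row matrix of 0-100 within-family percentages, one column per set.

    Rows follow :func:`codon_row_order`; codons of undefined families carry
    NaN, rendered as ``"X"`` by :func:`write_heatmap_tsv`.
    """
    freq_sets = list(freq_sets)
    if not freq_sets:
        raise ValueError("need at least one frequency set")
    gc = code or standard_code()
    order = codon_row_order(gc)
    cols = labels or [f.table_id for f in freq_sets]
    columns = []
    for freqs in freq_sets:
        pct = freqs.percent_scale
        undef = set(freqs.undefined_families)
        columns.append([
            MISSING if gc.codon_to_aa[c] in undef else pct[c] for c in order
        ])
    index = pd.MultiIndex.from_tuples(
        [(gc.codon_to_aa[c], c) for c in order], names=["aa", "codon"]
    )
    # column-wise construction tolerates duplicate labels
    return pd.DataFrame(
        {i: col for i, col in enumerate(columns)}, index=index
    ).set_axis(cols, axis=1)


def write_heatmap_tsv(matrix: pd.DataFrame, path) -> None:
    """Export the heat-map matrix as TSV; missing cells rendered as ``X``."""
    out = matrix.copy()
    out = out.map(lambda v: "X" if pd.isna(v) else f"{v:.1f}")
    out.to_csv(path, sep="\t")
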