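"""Loader for the published case-study inputs, when the user supplies them.

The case study this package reproduces rests on inputs distributed as a
journal supplementary spreadsheet (native and vendor-optimized CDSs for
KRas4B, Beclin 1 and PDE3A, plus HIVE-CUT codon usage tables for *E. coli*
and *H. sapiens*).  Those sequences are third-party data and are not
redistributed here; export them to plain files and point this loader at the
directory:

    <dir>/cds/*.fasta          one FASTA per sequence set (DNA)
    <dir>/tables/*.csv         codon,count tables (csv_counts dialect)
    <dir>/tables/*.txt         Kazusa-style text tables (kazusa_text dialect)

Everything in the package runs on generated fixtures without this data; the
loader only unlocks the published-number comparisons.
"""

from __future__ import annotations

from pathlib import Path

from .sequence_io import Cds
from .usage_tables import CodonUsageTable, parse_usage_table


class MissingDataError(FileNotFoundError):
    pass


def load_supplementary_dir(path) -> tuple[dict[str, list[Cds]], dict[str, CodonUsageTable]]:
    """Load user-supplied case-study data from ``path``.

    Returns (cds_sets keyed by FASTA stem, tables keyed by file stem).
    Raises :class:`MissingDataError` when the directory is absent.
    """
    from .sequence_io import read_fasta

    root = Path(path)
    if not root.is_dir():
        raise MissingDataError(
            f"supplementary data directory {root} not found; the published "
            "sequence sets are not redistributed with this package — see "
            "codonscope.datasets for the expected layout"
        )
    cds_sets = {
        p.stem: read_fasta(p, "dna")
        for p in sorted(root.glob("cds/*.fasta")) + sorted(root.glob("cds/*.fa"))
    }
    tables = {}
    for p in sorted(root.glob("tables/*.csv")):
        tables[p.stem] = parse_usage_table(p, "csv_counts", organism=p.stem)
    for p in sorted(root.glob("tables/*.txt")):
        tables[p.stem] = parse_usage_table(p, "kazusa_text", organism=p.stem)
    return cds_sets, tables
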