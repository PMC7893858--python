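"""Reading, validating and translating coding sequences.

Coding DNA sequences (CDSs) are handled as plain codon-structured strings
over ``{A,C,G,T}``; RNA input (``U``) and lower case are normalized silently
at parse time because vendor files mix conventions.  Coordinates reported in
errors and warnings are 1-based codon indices, matching amino-acid numbering.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger("codonscope")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(_h)

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
STOP = "*"

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


class SequenceError(ValueError):
    """Raised for malformed, out-of-alphabet or out-of-frame sequences."""


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map over the 64 DNA codons.

    The standard code ships as the default (:func:`standard_code`); any
    alternative table can be plugged in as long as it covers all 64 codons.
    Stop codons map to ``"*"``.
    """

    code_id: str
    codon_to_aa: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 DNA codons")
        aas = set(self.codon_to_aa.values()) - {STOP}
        if not aas:
            raise ValueError("genetic code has no sense codons")

    def family(self, aa: str) -> tuple[str, ...]:
        """Synonymous-codon family for an amino acid (or ``'*'`` for stops)."""
        return tuple(c for c in ALL_CODONS if self.codon_to_aa[c] == aa)

    @property
    def families(self) -> dict[str, tuple[str, ...]]:
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(cs) for aa, cs in fams.items()}

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.family(STOP)

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[codon] == STOP


def standard_code() -> GeneticCode:
    """The standard genetic code, built from Biopython's table 1."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for c in table.stop_codons:
        mapping[c] = STOP
    return GeneticCode(code_id="standard", codon_to_aa=mapping)


@dataclass(frozen=True)
class Cds:
    """A coding DNA sequence: id plus an in-frame A/C/G/T string."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codons(self) -> tuple[str, ...]:
        s = self.sequence
        return tuple(s[i : i + 3] for i in range(0, len(s), 3))

    def sense_codons(self, code: GeneticCode) -> tuple[str, ...]:
        """Codons excluding a single terminal stop, if present."""
        cs = self.codons
        if cs and code.is_stop(cs[-1]):
            cs = cs[:-1]
        return cs


@dataclass(frozen=True)
class ProteinSeq:
    """A protein sequence over the 20-letter amino-acid alphabet."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_nt(raw: str) -> str:
    return raw.upper().replace("U", "T")


def _check_alphabet(seq: str, alphabet: frozenset[str], record: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in alphabet:
            raise SequenceError(
                f"record {record!r}: invalid character {ch!r} at position {i + 1}"
            )


def validate_cds(seq: str, id: str = "cds", *, code: GeneticCode | None = None) -> Cds:
    """Validate a nucleotide string as an in-frame CDS.

    Length must be divisible by 3 and the alphabet restricted to A/C/G/T
    (after U->T / case normalization).  Internal stop codons are *not* an
    error here — they are flagged with a warning so that naturally occurring
    read-through or partial constructs can still be profiled.
    """
    norm = _normalize_nt(seq)
    _check_alphabet(norm, DNA_ALPHABET, id)
    if len(norm) % 3 != 0:
        raise SequenceError(
            f"record {id!r}: length {len(norm)} is not divisible by 3"
        )
    cds = Cds(id=id, sequence=norm)
    gc = code or standard_code()
    codons = cds.codons
    for i, codon in enumerate(codons[:-1]):
        if gc.is_stop(codon):
            logger.warning("record %r: internal stop codon at codon %d", id, i + 1)
    return cds


def read_fasta(path, alphabet: str = "dna") -> list[Cds] | list[ProteinSeq]:
    """Read a (multi-)FASTA file into validated Cds or ProteinSeq records.

    Order is preserved; DNA records are normalized (uppercase, U->T) and must
    be in frame.  ``alphabet`` is ``"dna"`` or ``"protein"``.
    """
    if alphabet not in {"dna", "protein"}:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    out: list = []
    for rec in records:
        seq = str(rec.seq)
        if alphabet == "dna":
            out.append(validate_cds(seq, id=rec.id))
        else:
            seq = seq.upper()
            _check_alphabet(seq, PROTEIN_ALPHABET, rec.id)
            out.append(ProteinSeq(id=rec.id, sequence=seq))
    return out


def write_fasta(records: Iterable[Cds | ProteinSeq], path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            s = rec.sequence
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def translate(
    cds: Cds, code: GeneticCode | None = None, *, permissive: bool = False
) -> ProteinSeq:
    """Translate a CDS; a single terminal stop is dropped.

    Internal (or leading) stop codons raise :class:`SequenceError` unless
    ``permissive`` is set, in which case they are emitted as ``"*"``.
    """
    gc = code or standard_code()
    codons = cds.codons
    if codons and gc.is_stop(codons[-1]):
        codons = codons[:-1]
    aas = []
    for i, codon in enumerate(codons):
        aa = gc.codon_to_aa[codon]
        if aa == STOP and not permissive:
            raise SequenceError(
                f"record {cds.id!r}: internal stop codon at codon {i + 1}"
            )
        aas.append(aa)
    return ProteinSeq(id=cds.id, sequence="".join(aas))
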