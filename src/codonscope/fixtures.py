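"""Deterministic toy tables, proteins and CDSs with analytically known values.

Everything here is generated in code — no data files — so every expected
value used in the test surface is forced by construction: the toy table's
counts are fixed below, extreme CDSs are all-family-maximum or all-minimum
encodings (CAI exactly 1, %MinMax pinned at +/-100), and random proteins
are seeded uniform draws.

Toy table counts (within-family shares follow directly):

    A: GCA 40, GCC 30, GCG 20, GCT 10      N: AAC 50, AAT 50 (tied)
    C: TGC 60, TGT 40                      P: CCA 25, CCC 15, CCG 45, CCT 15
    D: GAC 70, GAT 30                      Q: CAA 30, CAG 70
    E: GAA 55, GAG 45                      R: AGA 5, AGG 5, CGA 10, CGC 40,
    F: TTC 65, TTT 35                         CGG 15, CGT 25
    G: GGA 10, GGC 50, GGG 15, GGT 25      S: AGC 30, AGT 15, TCA 10, TCC 20,
    H: CAC 58, CAT 42                         TCG 5, TCT 20
    I: ATA 10, ATC 60, ATT 30              T: ACA 15, ACC 50, ACG 20, ACT 15
    K: AAA 75, AAG 25                      V: GTA 10, GTC 25, GTG 45, GTT 20
    L: CTA 5, CTC 15, CTG 40, CTT 10,      W: TGG 8
       TTA 10, TTG 20                      Y: TAC 60, TAT 40
    M: ATG 10                              *: TAA 30, TAG 10, TGA 20

Lysine 75/25, the asparagine tie and Met 10 anchor the worked examples used
throughout the documentation and tests.
"""

from __future__ import annotations

import numpy as np

from .sequence_io import (
    ALL_CODONS,
    PROTEIN_ALPHABET,
    STOP,
    Cds,
    GeneticCode,
    ProteinSeq,
    standard_code,
)
from .usage_tables import CodonUsageTable, NormalizedFrequencies, normalize

_TOY_COUNTS = {
    "GCA": 40, "GCC": 30, "GCG": 20, "GCT": 10,
    "TGC": 60, "TGT": 40,
    "GAC": 70, "GAT": 30,
    "GAA": 55, "GAG": 45,
    "TTC": 65, "TTT": 35,
    "GGA": 10, "GGC": 50, "GGG": 15, "GGT": 25,
    "CAC": 58, "CAT": 42,
    "ATA": 10, "ATC": 60, "ATT": 30,
    "AAA": 75, "AAG": 25,
    "CTA": 5, "CTC": 15, "CTG": 40, "CTT": 10, "TTA": 10, "TTG": 20,
    "ATG": 10,
    "AAC": 50, "AAT": 50,
    "CCA": 25, "CCC": 15, "CCG": 45, "CCT": 15,
    "CAA": 30, "CAG": 70,
    "AGA": 5, "AGG": 5, "CGA": 10, "CGC": 40, "CGG": 15, "CGT": 25,
    "AGC": 30, "AGT": 15, "TCA": 10, "TCC": 20, "TCG": 5, "TCT": 20,
    "ACA": 15, "ACC": 50, "ACG": 20, "ACT": 15,
    "GTA": 10, "GTC": 25, "GTG": 45, "GTT": 20,
    "TGG": 8,
    "TAC": 60, "TAT": 40,
    "TAA": 30, "TAG": 10, "TGA": 20,
}
assert set(_TOY_COUNTS) == set(ALL_CODONS)


def toy_table() -> CodonUsageTable:
    """The fixed toy usage table documented in the module docstring."""
    return CodonUsageTable(
        organism="toy", counts=dict(_TOY_COUNTS), source="codonscope fixture"
    )


def toy_frequencies() -> NormalizedFrequencies:
    return normalize(toy_table())


def extreme_cds(
    protein: ProteinSeq,
    table: CodonUsageTable,
    which: str,
    code: GeneticCode | None = None,
) -> Cds:
    """Encode a protein using only family-maximum or family-minimum codons
    (alphabetical tie-break), pinning CAI and %MinMax at their limits."""
    if which not in ("max", "min"):
        raise ValueError(f"which must be 'max' or 'min', got {which!r}")
    gc = code or standard_code()
    freqs = normalize(table, gc)
    sign = -1 if which == "max" else 1
    out = []
    for aa in protein.sequence:
        fam = gc.family(aa)
        out.append(sorted(fam, key=lambda c: (sign * freqs.family_relative[c], c))[0])
    return Cds(id=f"{protein.id}/{which}", sequence="".join(out))


def random_protein(length: int, seed: int = 1) -> ProteinSeq:
    """Seeded uniform draw over the 20 amino acids."""
    if length < 1:
        raise ValueError("length must be at least 1")
    rng = np.random.default_rng(seed)
    aas = sorted(PROTEIN_ALPHABET)
    seq = "".join(aas[int(i)] for i in rng.integers(len(aas), size=length))
    return ProteinSeq(id=f"random-protein-L{length}-s{seed}", sequence=seq)
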