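"""Reference reverse-translation strategies.

These serve two roles: comparable in-package "optimizers" (maximum-frequency
recoding, frequency-weighted sampling, codon harmonization) and generators
of replicate sets for the reproducibility analysis, where the *uniform*
strategy is the no-bias null.

Harmonization is implemented as within-family frequency-rank matching: each
native codon's rank among its synonyms in the source-organism table (1 =
most frequent, ties broken alphabetically) selects the codon of the same
rank in the expression-host table.  Rank matching is invariant to the
tables' absolute scales and degenerates to the identity when source and
target tables coincide.  Matching the %MinMax profile instead is a known
alternative definition and is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence_io import STOP, Cds, GeneticCode, ProteinSeq, standard_code, translate
from .usage_tables import CodonUsageTable, normalize

STRATEGY_NAMES = ("uniform", "weighted", "max_frequency", "harmonized")


class RevtransError(ValueError):
    pass


@dataclass(frozen=True)
class Strategy:
    """A named reverse-translation rule plus the tables and seed it needs.

    ``uniform`` needs no table; ``weighted`` and ``max_frequency`` need the
    host table; ``harmonized`` additionally needs the source-organism table
    the native CDS is read against.
    """

    name: str
    table: CodonUsageTable | None = None
    source_table: CodonUsageTable | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise RevtransError(f"unknown strategy {self.name!r}")
        if self.name in ("weighted", "max_frequency", "harmonized") and self.table is None:
            raise RevtransError(f"strategy {self.name!r} requires a usage table")
        if self.name == "harmonized" and self.source_table is None:
            raise RevtransError("harmonized strategy requires a source_table")


def _ranked_family(freqs, fam: tuple[str, ...]) -> list[str]:
    # descending frequency, alphabetical tie-break
    return sorted(fam, key=lambda c: (-freqs.family_relative[c], c))


def reverse_translate(
    protein: ProteinSeq,
    strategy: Strategy,
    native_cds: Cds | None = None,
    code: GeneticCode | None = None,
    rng: np.random.Generator | None = None,
    id: str | None = None,
) -> Cds:
    """Encode a protein as a CDS under the given strategy.

    The result always translates back to the input protein; stop codons are
    never emitted.  Stochastic strategies draw from ``rng`` when supplied,
    else from a generator seeded with ``strategy.seed``.
    """
    gc = code or standard_code()
    if strategy.name in ("uniform", "weighted") and rng is None:
        rng = np.random.default_rng(strategy.seed)

    norm_target = normalize(strategy.table, gc) if strategy.table is not None else None

    native_codons: tuple[str, ...] | None = None
    norm_source = None
    if strategy.name == "harmonized":
        if native_cds is None:
            raise RevtransError("harmonized strategy requires native_cds")
        native_prot = translate(native_cds, gc)
        if native_prot.sequence != protein.sequence:
            raise RevtransError(
                f"native CDS {native_cds.id!r} does not encode protein {protein.id!r}"
            )
        native_codons = native_cds.sense_codons(gc)
        norm_source = normalize(strategy.source_table, gc)

    out: list[str] = []
    for i, aa in enumerate(protein.sequence):
        fam = gc.family(aa)
        if not fam:
            raise RevtransError(f"no codons for amino acid {aa!r}")
        if len(fam) == 1:
            out.append(fam[0])
            continue
        if strategy.name == "uniform":
            out.append(fam[int(rng.integers(len(fam)))])
        elif strategy.name == "max_frequency":
            out.append(_ranked_family(norm_target, fam)[0])
        elif strategy.name == "weighted":
            w = np.array([norm_target.family_relative[c] for c in fam])
            if w.sum() == 0:
                raise RevtransError(
                    f"family of {aa!r} has no counts in table "
                    f"{strategy.table.organism!r}"
                )
            out.append(fam[int(rng.choice(len(fam), p=w / w.sum()))])
        else:  # harmonized
            rank = _ranked_family(norm_source, fam).index(native_codons[i])
            out.append(_ranked_family(norm_target, fam)[rank])
    label = id or f"{protein.id}/{strategy.name}"
    return Cds(id=label, sequence="".join(out))


def make_fixture_set(
    protein_length: int,
    n_replicates: int,
    strategy: Strategy,
    seed: int = 1,
    code: GeneticCode | None = None,
) -> tuple[ProteinSeq, list[Cds]]:
    """n reverse translations of one seeded random protein.

    Deterministic given (length, n, strategy, seed): the protein draw and
    every stochastic encoding share a generator seeded with ``seed``.
    Returns the protein together with its encodings.
    """
    from .fixtures import random_protein

    if protein_length < 1 or n_replicates < 1:
        raise RevtransError("length and n_replicates must be at least 1")
    gc = code or standard_code()
    protein = random_protein(protein_length, seed)
    rng = np.random.default_rng(seed)
    reps = [
        reverse_translate(protein, strategy, code=gc, rng=rng,
                          id=f"{protein.id}/{strategy.name}{i + 1}")
        for i in range(n_replicates)
    ]
    return protein, reps
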