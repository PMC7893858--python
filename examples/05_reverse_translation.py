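"""Reference reverse-translation strategies, including codon harmonization.

Four encodings of one protein: uniform (no bias), weighted (sample by host
frequency), max_frequency (CAI-maximizing), and harmonized (map each native
codon's within-family frequency rank in the source organism to the same
rank in the host table).
"""

from codonscope import (
    Strategy, cai, reverse_translate, toy_frequencies, toy_table, translate,
    validate_cds,
)

table = toy_table()
freqs = toy_frequencies()
native = validate_cds("AAGGATCTATCGGTTACAAAG", "native")
protein = translate(native)
print("protein:", protein.sequence)

for name in ("uniform", "weighted", "max_frequency"):
    strat = Strategy(name=name, table=None if name == "uniform" else table, seed=2)
    cds = reverse_translate(protein, strat)
    print(f"{name:14s} {cds.sequence}  CAI={cai(cds, freqs):.3f}")

harm = Strategy(name="harmonized", table=table, source_table=table)
cds = reverse_translate(protein, harm, native_cds=native)
print(f"{'harmonized':14s} {cds.sequence}  (source==target reproduces the native CDS:",
      cds.sequence == native.sequence, ")")
# max_frequency always reaches CAI = 1.0; harmonization instead preserves
# the native CDS's rare/frequent codon pattern in the host's frequency ranks.
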