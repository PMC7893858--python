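"""Build and normalize codon usage tables; export the 0-100 heat-map scale.

A usage table stores per-codon counts for an organism.  Normalizing it
gives, for every codon, its share of its synonymous family (0-1, or 0-100
on the heat-map scale) and the classic RSCU value (count over family mean).
"""

from codonscope import count_codons, heatmap_matrix, normalize, toy_table, validate_cds

# build a table by counting codons from a small CDS collection
cds_set = [validate_cds("ATGAAAAAGTTTTAA", "demo1"),
           validate_cds("ATGAAAAAATTC", "demo2")]
counted = count_codons(cds_set, organism="demo")
print("Lys counts from the CDS set:",
      {c: counted.counts[c] for c in ("AAA", "AAG")})

# normalize the built-in toy table (Lys fixed at 75/25)
freqs = normalize(toy_table())
print("AAA within-family share:", freqs.family_relative["AAA"])   # 0.75
print("AAA RSCU:", freqs.rscu["AAA"])                             # 1.5
print("ATG on the 0-100 scale:", freqs.percent_scale["ATG"])      # 100.0

# the heat-map matrix groups the 64 codons by amino acid, one column per table
m = heatmap_matrix([freqs, normalize(counted)], labels=["toy", "demo"])
print(m.loc["K"])
# Met/Trp always read 100: they have a single codon, so their family share
# is 100% under any usable table.
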