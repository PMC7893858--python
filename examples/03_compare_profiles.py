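"""Rank-sum comparison of codon profiles between two encodings.

Codon-frequency distributions are non-normal, so profiles are compared with
the two-sided Mann-Whitney-Wilcoxon rank-sum test and labelled with the
figure-legend convention: '**' p < 1e-5, '*' p < 1e-2, else 'n.s.'.
"""

from codonscope import (
    Strategy, codon_profile, extreme_cds, random_protein, rank_sum_test,
    reverse_translate, significance_label, toy_frequencies, toy_table,
)

table = toy_table()
freqs = toy_frequencies()
protein = random_protein(180, seed=4)

native_like = reverse_translate(protein, Strategy(name="weighted", table=table, seed=4))
optimized = extreme_cds(protein, table, "max")

a = codon_profile(native_like, freqs)
for label, other in [("weighted vs itself", native_like), ("weighted vs max", optimized)]:
    b = codon_profile(other, freqs)
    r = rank_sum_test(a.values, b.values)
    print(f"{label:20s} U={r.u_statistic:.0f} z={r.z:+.2f} "
          f"p={r.p_two_sided:.2e} ({r.method}) -> "
          f"{significance_label(r.p_two_sided)}")
# Identical profiles give p = 1 ('n.s.'); the fully frequency-maximized
# encoding shifts the whole profile upward, a significant shift ('*',
# p < 1e-2) at this length.
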