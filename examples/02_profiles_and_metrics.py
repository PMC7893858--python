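"""Per-CDS codon-frequency profiles and the scalar comparison metrics.

The codon profile lists each position's within-family frequency — the data
behind the violin plots — and the metrics row collects median/mean profile
frequency, CAI, %GC, %GC3 and the %Min-window share of the %MinMax profile.
"""

from codonscope import (
    cds_metrics, codon_profile, minmax_profile, profile_summary,
    toy_frequencies, toy_table, validate_cds,
)

freqs = toy_frequencies()
cds = validate_cds("AAAAAGATGGCAGGTCAAATCTTGCCGGACTAA", "demo")

profile = codon_profile(cds, freqs)
print("profile (first 3 positions):", profile.values[:3])  # (0.75, 0.25, 1.0)

s = profile_summary(profile)
print(f"n={s.n} median={s.median:.3f} mean={s.mean:.3f} "
      f"q1={s.q1:.3f} q3={s.q3:.3f}")

mm = minmax_profile(cds, toy_table(), window=5)
print("%MinMax values:", [round(v, 1) for v in mm.values])

row = cds_metrics(cds, freqs, mm)
print(f"CAI={row.cai:.3f} %GC={row.pct_gc:.1f} %GC3={row.pct_gc3:.1f} "
      f"%MinWindow={row.pct_min_window:.1f}")
# CAI < 1 flags positions using sub-maximal synonymous codons; negative
# %MinMax windows mark rare-codon clusters, and %MinWindow is the fraction
# of the CDS sitting in such clusters.
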