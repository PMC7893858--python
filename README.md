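# codonscope

Tools for quantifying, visualizing and comparing codon-optimized coding
sequences (CDSs), aimed at protein-production groups deciding between
vendor- or server-optimized genes for heterologous expression.

When a gene is recoded for an expression host, synonymous codons are swapped
according to the host's codon usage bias. Different optimization algorithms
make very different choices, and some are not even reproducible across
resubmissions of the same input. `codonscope` provides the analysis layer
for auditing such sequences:

- **Codon usage tables** — build from a CDS collection or parse
  Kazusa-style text / `codon,count` CSV files; normalize counts to
  within-family relative frequencies (the 0–100 heat-map scale, where a
  codon used for 100% of its amino acid scores 100), per-thousand values
  and classic RSCU.
- **Codon profiles** — per-position within-family frequencies of a CDS
  (violin-plot data) with median/quartile summaries.
- **Scalar metrics** — CAI (geometric mean of w(c) = f(c)/max f over the
  synonymous family), %GC, %GC3 (wobble-position GC) and the %Min-window
  fraction of the %MinMax profile.
- **%MinMax** — sliding-window statistic in [−100, +100] that locates
  clusters of rare (negative) or frequent (positive) codons along a CDS.
- **Profile comparison** — two-sided Mann-Whitney–Wilcoxon rank-sum test
  (exact for small tie-free samples, tie-corrected normal otherwise) with
  the `n.s.` / `*` / `**` labeling convention.
- **Reproducibility audit** — pairwise % codon identity among replicate
  optimizer outputs, compared against the band spanned by uniform random
  reverse translations (the "no codon bias" null).
- **Reference reverse-translation strategies** — uniform, frequency-
  weighted, CAI-maximizing, and rank-matching codon harmonization.

## Worked example

```python
from codonscope import (
    cds_metrics, codon_profile, minmax_profile, toy_frequencies,
    toy_table, validate_cds,
)

freqs = toy_frequencies()               # toy table: Lys AAA/AAG = 75/25, ...
cds = validate_cds("AAAAAGATGGCAGGTCAAATCTTGCCGGACTAA", "demo")

print(codon_profile(cds, freqs).values[:3])
# (0.75, 0.25, 1.0)  — AAA is 75% of Lys usage, AAG 25%, ATG always 1.0

mm = minmax_profile(cds, toy_table(), window=5)
row = cds_metrics(cds, freqs, mm)
print(f"CAI={row.cai:.3f} %GC={row.pct_gc:.1f} "
      f"%GC3={row.pct_gc3:.1f} %MinWindow={row.pct_min_window:.1f}")
# CAI=0.691 %GC=42.4 %GC3=60.0 %MinWindow=16.7
```

CAI = 0.691 says the demo CDS sits well below a fully frequency-maximized
encoding (CAI 1.0); %MinWindow = 16.7 means one in six %MinMax windows is a
rare-codon cluster. The scripts in `examples/` walk through each
capability (tables, profiles, statistical comparison, reproducibility,
reverse translation) and print the numbers they compute.

A thin CLI mirrors the library:

```bash
codonscope fixtures --length 30 --n 3 --strategy uniform --out fx
codonscope profile fx/replicates.fasta --table fx/toy_table.csv --out run
codonscope compare ref.fasta others.fasta --table fx/toy_table.csv --out cmp
codonscope reproducibility --replicates fx/replicates.fasta --out rep
```

Outputs are plot-ready TSV/JSON with the effective configuration embedded
as `# key=value` header lines.

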