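# Methods

This note records the models, conventions and numerical choices behind
`codonscope`, and what the fixture-based tests do and do not establish
about real sequence data.

## Sequences and the genetic code

CDSs are codon-structured strings over {A,C,G,T}; RNA (`U`) and lower case
are normalized silently at parse time because vendor exports mix
conventions. Length must be a multiple of three. Internal stop codons are
a warning, not an error: partial and read-through constructs should still
be profilable. Translation drops a single terminal stop. The standard
genetic code is the default and any 64-codon table can be plugged in;
ambiguity codes (N, R, Y, …) are rejected. All reported coordinates are
1-based codon indices, matching amino-acid numbering.

## Usage tables and normalization

Tables store raw per-codon counts; every derived scale — per-thousand,
within-family relative frequency f(c) (0–1, or ×100 for the heat map), and
RSCU — is recomputed from counts so rounding in a source file never
propagates. Within a synonymous family,

    f(c) = n(c) / Σ_family n,     RSCU(c) = n(c) / mean_family n,

so RSCU(c) = f(c) × family size. Single-codon families (Met/ATG, Trp/TGG)
always have f = 1, hence 100 on the percent scale, for any usable table.
A family with zero total count gets f = 0 for all members and is flagged
undefined; no pseudo-count is applied at the table level. Stop codons form
a three-codon family for normalization but are excluded from every
downstream metric. Heat-map rows order amino acids alphabetically by
one-letter code (stops last), codons alphabetically within a family; the
order is a documented convention, nothing more.

Two file dialects are parsed: Kazusa-style text (`CODON per-1000 (count)`
tuples, several per line) and two-column `codon,count` CSV. Only the count
column is trusted.

## Codon profiles and scalar metrics

The codon profile of a CDS lists f(codon_i) for each sense codon in order,
terminal stop excluded; single-codon families contribute 1.0. Profile
summaries (median, mean, quartiles) use linear interpolation between order
statistics (the "type 7" quantile rule) so violin summaries are
reproducible bit-for-bit; the rule matters only at small n.

CAI is the geometric mean of w(c) = f(c) / max f over c's family, over
contributing codons. By default ATG/TGG and stops do not contribute (the
classic definition); `include_single_codon_families=True` adds them with
w = 1, which only raises CAI toward 1 and covers server implementations
that include them. A codon with zero table count would make the geometric
mean collapse to 0, so w is floored at a configurable epsilon
(default 0.005 — small enough to dominate the mean downward without
annihilating it; both the flag and the value are recorded in outputs).

%GC is computed on the full nucleotide string including a terminal stop
(a plain sequence property); %GC3 is the fraction of sense codons whose
third base is G or C (a codon property, stops excluded). The two decisions
are deliberately asymmetric and embedded in the exported metadata.

## %MinMax

For a window of W sense codons with per-position family statistics
(maximum, minimum, average frequency) and X_actual the mean frequency of
the codons used:

    %Max = +100 (X_actual − X_avg) / (X_max − X_avg)   if X_actual > X_avg
    %Min = −100 (X_avg − X_actual) / (X_avg − X_min)   if X_actual < X_avg
    0 otherwise, including degenerate windows where a denominator vanishes
    (e.g. a window of only Met/Trp).

Defaults: W = 18 codons and per-thousand frequencies, the basis the
original sliding-window implementations use; within-family relative
frequencies are available as an option. Both choices are surfaced as flags
and recorded in output metadata because the %Min-window summary — the
percent of windows strictly below zero — depends on them. Values are
assigned to the window's start codon; a CDS shorter than W is an error
unless explicitly collapsed to one full-length window. Scores are clamped
to [−100, 100] to guard against float round-off at the endpoints.

## Rank-sum comparison

Profiles are non-normal, so two encodings are compared with the two-sided
Mann-Whitney–Wilcoxon test. With min(n1, n2) ≤ 8 and a tie-free pooled
sample the p-value is computed by exact enumeration of all label
assignments; otherwise by the normal approximation with tie-corrected
variance and no continuity correction. The method used is recorded in the
result. Significance labels follow the convention `**` p < 1e−5, `*`
p < 1e−2, else `n.s.`. The test suite cross-checks both routes against
scipy's independent implementation, and checks that exact p and the
continuity-corrected normal tail agree within 0.02 at sizes 6–8.

## Reproducibility audit

Replicate optimizer outputs of one protein are equal-length synonymous
encodings, so "% codon identity" is positional codon agreement — gapped
alignment is rejected by design. The null is uniform random reverse
translation: each family sampled uniformly, stops never emitted. For each
protein, n replicates (default n = 100, the case-study condition) give a
mean off-diagonal pairwise identity; the band is the range of per-protein
means (the raw per-pair distribution is also exported, since "the limits"
could alternatively be read as the per-pair range). The analytic
expectation of the per-protein mean is Σ_sites 1/(family size)/n_sites,
and for uniform sampling overlapping pairs are uncorrelated, which gives
the standard-error formula used in the convergence tests. An algorithm
whose replicate mean falls inside the band is flagged
`within_random_band`: its choices are indistinguishable from unbiased
random encoding.

## Reverse-translation strategies

`max_frequency` picks each family's most frequent codon (alphabetical
tie-break; deterministic, CAI = 1 by construction). `weighted` samples
∝ f(c); `uniform` samples each family uniformly. `harmonized` maps each
native codon's within-family frequency rank in the source-organism table
to the codon of the same rank in the host table. Rank matching is one of
several possible operationalizations of codon harmonization; it was chosen
because it is scale-invariant across tables and has a sharp identity
limit (source table = target table reproduces the native CDS exactly).
Matching the %MinMax profile instead is a known alternative and is not
implemented. All stochastic strategies take an explicit seed.

## Synthetic fixtures and what the tests show

The fixture module generates everything in code: a toy usage table with
fixed documented counts (Lys 75/25, Asn 50/50 tie, Met 10, plus
non-uniform counts for every other family), seeded uniform random
proteins, and extreme encodings (all-family-maximum / all-minimum) whose
metric values are analytically forced (CAI = 1, %MinMax = ±100,
%Min-window = 0/100). Test problem sizes are deliberately modest —
proteins of 30–180 residues, replicate sets of 5–10, baselines of n =
40–200 — chosen so expectations and standard errors are computable and the
suite stays quick.

These fixtures emulate the *structure* of real inputs (synonymous
families, frequency bias, replicate encodings) but not real codon-usage
distributions, dicodon or GC constraints, or any vendor algorithm's
behavior. Passing tests therefore establish the correctness of the
computations and their invariants, not any claim about a particular
organism's table or a particular optimizer. The published case-study
numbers (native KRas4B median frequency 0.339, CAI 0.61, the cross-host
rank-sum p = 0.327, the 33–40% random band) are asserted in the acceptance
tests only when the original supplementary sequence sets are supplied by
the user under `data/supplementary/`; the package does not redistribute
them, and those tests report their absence explicitly instead of passing
vacuously. The %Min-window column of the published metrics matrix is
checked only for qualitative ordering, because the published analysis does
not state the window size or frequency basis it used.

## Known limitations

- CAI variant ambiguity: public CAI servers differ in their treatment of
  single-codon families and zero-count codons; both knobs are exposed, and
  comparisons against externally computed CAI values should state them.
- %MinMax window size and basis materially change the %Min-window summary;
  cross-study comparisons must fix both.
- The harmonized strategy is rank-based and will not reproduce
  implementations that match absolute frequencies.
- No mRNA-structure, codon-pair, repeat or restriction-site analysis:
  those are other tools' optimization variables, not computed here.
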