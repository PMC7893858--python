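"""Statistical comparison of codon profiles and optimizer reproducibility.

Codon-frequency profiles are compared with the two-sided Mann-Whitney-
Wilcoxon rank-sum test: exact enumeration of the U null distribution when
both samples are small and tie-free, otherwise the normal approximation
with tie-corrected variance (no continuity correction).

Replicate optimizer outputs of one protein are equal-length synonymous
encodings, so "pairwise alignment" reduces to positional codon comparison —
gapped alignment is deliberately rejected.  The reproducibility null is
uniform random reverse translation ("no codon bias"): for each protein,
n random encodings are generated and their mean off-diagonal pairwise
identity gives the floor any genuine optimizer should clear.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt

import numpy as np
from scipy.stats import norm, rankdata

from .sequence_io import Cds, GeneticCode, ProteinSeq, standard_code, translate
from .revtrans import Strategy, reverse_translate

EXACT_CUTOFF = 8


class CompareError(ValueError):
    pass


@dataclass(frozen=True)
class RankSumResult:
    u_statistic: float
    z: float
    p_two_sided: float
    method: str  # exact | normal_tie_corrected
    n1: int
    n2: int


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, percent, 100 on the diagonal

    @property
    def mean_offdiag(self) -> float:
        m = self.matrix
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return float(m[iu].mean())


@dataclass(frozen=True)
class BaselineBand:
    per_protein_mean: dict[str, float]
    low: float
    high: float
    n_replicates: int
    seed: int


@dataclass(frozen=True)
class ReproducibilityReport:
    matrices: dict[str, IdentityMatrix]
    means: dict[str, float]
    baseline: BaselineBand
    within_random_band: dict[str, bool]


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u1: float) -> float:
    """Exact two-sided p by enumerating all group-label assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    n = len(pooled)
    ranks = rankdata(pooled)
    u_obs = min(u1, n1 * (n - n1) - u1)
    count = 0
    total = 0
    base = n1 * (n1 + 1) / 2
    n2 = n - n1
    for idx in combinations(range(n), n1):
        r = ranks[list(idx)].sum()
        u = r - base
        total += 1
        if min(u, n1 * n2 - u) <= u_obs + 1e-9:
            count += 1
    return count / total


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    Exact enumeration when min(n1, n2) <= 8 and the pooled sample is
    tie-free; otherwise normal approximation with tie-corrected variance
    and no continuity correction.  U reported for the first sample.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise CompareError("empty sample")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    has_ties = len(np.unique(pooled)) < n1 + n2

    # tie-corrected variance of U
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    z = 0.0 if var == 0 else (u1 - mu) / sqrt(var)

    if min(n1, n2) <= EXACT_CUTOFF and not has_ties:
        p = _exact_two_sided_p(a, b, u1)
        method = "exact"
    else:
        p = 1.0 if var == 0 else 2.0 * norm.sf(abs(z))
        method = "normal_tie_corrected"
    return RankSumResult(
        u_statistic=float(u1), z=float(z), p_two_sided=min(float(p), 1.0),
        method=method, n1=n1, n2=n2,
    )


def significance_label(p: float) -> str:
    """Figure-legend label: '**' below 1e-5, '*' below 1e-2, else 'n.s.'."""
    if not 0 < p <= 1:
        raise CompareError(f"p-value {p} outside (0, 1]")
    if p < 1e-5:
        return "**"
    if p < 1e-2:
        return "*"
    return "n.s."


def _codon_identity(x: Cds, y: Cds) -> float:
    cx, cy = x.codons, y.codons
    return 100.0 * sum(a == b for a, b in zip(cx, cy)) / len(cx)


def pairwise_codon_identity(
    cds_set, code: GeneticCode | None = None, *, check_protein: bool = True
) -> IdentityMatrix:
    """Percent codon identity between all pairs of equal-length encodings.

    All sequences must have the same codon length and (by default) translate
    to the same protein — they are replicate encodings, compared position by
    position with no gaps.
    """
    gc = code or standard_code()
    cds_list = list(cds_set)
    if len(cds_list) < 2:
        raise CompareError("need at least 2 sequences")
    ref = cds_list[0]
    ref_prot = translate(ref, gc, permissive=True).sequence if check_protein else None
    for other in cds_list[1:]:
        if len(other) != len(ref):
            raise CompareError(
                f"length mismatch: {ref.id!r} ({len(ref)}) vs {other.id!r} ({len(other)})"
            )
        if check_protein:
            prot = translate(other, gc, permissive=True).sequence
            if prot != ref_prot:
                raise CompareError(
                    f"protein mismatch: {ref.id!r} vs {other.id!r}"
                )
    n = len(cds_list)
    m = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        v = _codon_identity(cds_list[i], cds_list[j])
        m[i, j] = m[j, i] = v
    return IdentityMatrix(labels=tuple(c.id for c in cds_list), matrix=m)


def expected_uniform_identity(protein: ProteinSeq, code: GeneticCode | None = None) -> float:
    """Analytic mean pairwise identity of uniform random encodings:
    the average over sites of 1/(synonymous family size), as a percent."""
    gc = code or standard_code()
    sizes = [len(gc.family(aa)) for aa in protein.sequence]
    return 100.0 * sum(1.0 / s for s in sizes) / len(sizes)


def random_reverse_translation_baseline(
    protein_set, n: int = 100, seed: int = 1, code: GeneticCode | None = None
) -> BaselineBand:
    """Mean pairwise identity of n uniform random encodings per protein.

    The band [low, high] spans the per-protein means — the no-bias floor for
    the percent-codon-identity analysis.
    """
    gc = code or standard_code()
    proteins = list(protein_set)
    if n < 2:
        raise CompareError("need at least 2 replicates")
    if not proteins:
        raise CompareError("empty protein set")
    rng = np.random.default_rng(seed)
    means: dict[str, float] = {}
    for prot in proteins:
        if len(prot) == 0:
            raise CompareError(f"empty protein {prot.id!r}")
        strat = Strategy(name="uniform", table=None)
        reps = [
            reverse_translate(prot, strat, code=gc,
                              rng=rng, id=f"{prot.id}/rand{i + 1}")
            for i in range(n)
        ]
        ident = pairwise_codon_identity(reps, gc, check_protein=False)
        means[prot.id] = ident.mean_offdiag
    vals = list(means.values())
    return BaselineBand(
        per_protein_mean=means, low=min(vals), high=max(vals),
        n_replicates=n, seed=seed,
    )


def reproducibility_report(
    replicate_sets: dict,
    protein_set,
    n_baseline: int = 100,
    seed: int = 1,
    code: GeneticCode | None = None,
) -> ReproducibilityReport:
    """Per-algorithm identity matrices against the random-encoding band.

    An algorithm whose mean pairwise identity falls inside the band is
    indistinguishable from unbiased random reverse translation.
    """
    gc = code or standard_code()
    baseline = random_reverse_translation_baseline(protein_set, n_baseline, seed, gc)
    matrices = {}
    means = {}
    verdicts = {}
    for label, cds_set in replicate_sets.items():
        ident = pairwise_codon_identity(cds_set, gc)
        matrices[label] = ident
        means[label] = ident.mean_offdiag
        verdicts[label] = baseline.low <= ident.mean_offdiag <= baseline.high
    return ReproducibilityReport(
        matrices=matrices, means=means, baseline=baseline,
        within_random_band=verdicts,
    )
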