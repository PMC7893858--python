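"""Per-CDS scalar metrics and per-position codon-frequency profiles.

A *codon profile* is the ordered list of within-family relative frequencies
of each sense codon of a CDS under a usage table — the raw data behind the
violin plots used to compare optimizer outputs.  Scalar metrics assemble the
columns of the comparison matrix: median/mean profile frequency, CAI, %GC,
%GC3 and the %Min-window fraction of the %MinMax profile.

CAI here is the geometric mean over the CDS of w(c) = f(c)/max(f over c's
synonymous family), with f the within-family relative frequency.  By the
classic definition, single-codon families (ATG, TGG) and stop codons carry
no information about bias and are excluded by default; a codon absent from
the reference table gets w floored at a small epsilon so one unused codon
cannot annihilate the geometric mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence_io import STOP, Cds, GeneticCode
from .usage_tables import NormalizedFrequencies

DEFAULT_CAI_EPSILON = 0.005


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class CodonProfile:
    cds_id: str
    values: tuple[float, ...]
    table_id: str

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class ProfileSummary:
    """Violin-plot summary: n, median, mean and the two quartiles.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the "type 7" convention) so the numbers are reproducible
    bit-for-bit.
    """

    n: int
    median: float
    mean: float
    q1: float
    q3: float


@dataclass(frozen=True)
class CdsMetrics:
    cds_id: str
    n_codons: int
    median_frequency: float
    mean_frequency: float
    cai: float
    pct_gc: float
    pct_gc3: float
    pct_min_window: float
    table_id: str


def codon_profile(cds: Cds, freqs: NormalizedFrequencies) -> CodonProfile:
    """Per-position family-relative frequencies; terminal stop excluded.

    Single-codon families contribute 1.0.  A codon from a family the table
    never observed is an error naming the 1-based codon position.
    """
    code = freqs.code
    values = []
    undef = set(freqs.undefined_families)
    for i, codon in enumerate(cds.sense_codons(code)):
        aa = code.codon_to_aa[codon]
        if aa == STOP:
            continue  # internal stop in a permissive CDS: no frequency defined
        if aa in undef:
            raise MetricError(
                f"record {cds.id!r}: codon {codon!r} at codon {i + 1} belongs to "
                f"a family with no counts in table {freqs.table_id!r}"
            )
        values.append(freqs.family_relative[codon])
    return CodonProfile(cds_id=cds.id, values=tuple(values), table_id=freqs.table_id)


def profile_summary(profile: CodonProfile) -> ProfileSummary:
    if len(profile) == 0:
        raise MetricError(f"empty profile for {profile.cds_id!r}")
    v = np.asarray(profile.values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return ProfileSummary(n=len(v), median=float(med), mean=float(v.mean()),
                          q1=float(q1), q3=float(q3))


def cai(
    cds: Cds,
    freqs: NormalizedFrequencies,
    *,
    include_single_codon_families: bool = False,
    epsilon: float = DEFAULT_CAI_EPSILON,
) -> float:
    """Codon Adaptation Index in (0, 1].

    1.0 means every contributing position uses its family's most frequent
    codon.  ``include_single_codon_families`` adds ATG/TGG with w = 1
    (some server implementations do); stops never contribute.
    """
    code = freqs.code
    log_sum = 0.0
    n = 0
    for i, codon in enumerate(cds.sense_codons(code)):
        aa = code.codon_to_aa[codon]
        if aa == STOP:
            continue
        fam = code.family(aa)
        if len(fam) == 1:
            if include_single_codon_families:
                n += 1  # w = 1, log contribution 0
            continue
        fmax = freqs.family_max(codon)
        if fmax == 0.0:
            raise MetricError(
                f"record {cds.id!r}: codon {codon!r} at codon {i + 1} has an "
                f"undefined family in table {freqs.table_id!r}"
            )
        w = freqs.family_relative[codon] / fmax
        if w == 0.0:
            w = epsilon
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise MetricError(f"record {cds.id!r}: no codons contribute to CAI")
    return math.exp(log_sum / n)


def pct_gc(seq: str) -> float:
    """Percent G+C of a nucleotide string (computed on the full sequence,
    terminal stop included if present)."""
    if not seq:
        raise MetricError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def pct_gc3(cds: Cds, code: GeneticCode | None = None) -> float:
    """Percent of sense codons whose third (wobble) base is G or C."""
    from .sequence_io import standard_code

    gc = code or standard_code()
    thirds = [c[2] for c in cds.sense_codons(gc)]
    if not thirds:
        raise MetricError(f"record {cds.id!r}: no sense codons")
    return 100.0 * sum(b in "GC" for b in thirds) / len(thirds)


def cds_metrics(
    cds: Cds,
    freqs: NormalizedFrequencies,
    minmax_profile=None,
    *,
    cai_kwargs: dict | None = None,
) -> CdsMetrics:
    """Assemble one row of the comparison matrix for a CDS.

    ``minmax_profile`` is the %MinMax profile of the *same* CDS; its
    %Min-window summary fills the last column (NaN when not supplied).
    """
    from .minmax import pct_min_window

    if minmax_profile is not None and minmax_profile.cds_id != cds.id:
        raise MetricError(
            f"minmax profile is for {minmax_profile.cds_id!r}, not {cds.id!r}"
        )
    profile = codon_profile(cds, freqs)
    summ = profile_summary(profile)
    pmw = pct_min_window(minmax_profile) if minmax_profile is not None else float("nan")
    return CdsMetrics(
        cds_id=cds.id,
        n_codons=summ.n,
        median_frequency=summ.median,
        mean_frequency=summ.mean,
        cai=cai(cds, freqs, **(cai_kwargs or {})),
        pct_gc=pct_gc(cds.sequence),
        pct_gc3=pct_gc3(cds, freqs.code),
        pct_min_window=pmw,
        table_id=freqs.table_id,
    )
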