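"""%MinMax sliding-window profile of rare- and frequent-codon clusters.

For a window of W consecutive sense codons, let

    X_actual = mean frequency of the codons actually used,
    X_max    = mean of each position's family-maximum frequency,
    X_min    = mean of each position's family-minimum frequency,
    X_avg    = mean of each position's family-average frequency.

The window score is

    +100 * (X_actual - X_avg) / (X_max - X_avg)   if X_actual > X_avg,
    -100 * (X_avg - X_actual) / (X_avg - X_min)   if X_actual < X_avg,
      0                                            otherwise,

so +100 marks a run of each amino acid's most frequent codon, -100 a run of
its rarest, and 0 an even distribution (including degenerate windows of
single-codon amino acids, where the denominators vanish).  Scores are
assigned to the window's start codon (1-based), giving n_codons - W + 1
values per CDS.

Frequencies can be taken on the table's per-thousand scale (default, the
basis the original sliding-window tool uses) or on the within-family
relative scale; the choice only matters for how families are weighted
against each other inside a window and is recorded on the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

from .sequence_io import STOP, Cds, GeneticCode
from .usage_tables import CodonUsageTable, NormalizedFrequencies, normalize

DEFAULT_WINDOW = 18


class MinMaxError(ValueError):
    pass


@dataclass(frozen=True)
class MinMaxProfile:
    cds_id: str
    window: int
    values: tuple[float, ...]
    scale: str  # per_thousand | family_relative
    table_id: str = ""

    def __len__(self) -> int:
        return len(self.values)


def _frequency_map(
    table: CodonUsageTable, code: GeneticCode, scale: str
) -> dict[str, float]:
    if scale == "per_thousand":
        return table.per_thousand
    if scale == "family_relative":
        return normalize(table, code).family_relative
    raise ValueError(f"unknown scale {scale!r}")


def minmax_profile(
    cds: Cds,
    table: CodonUsageTable,
    window: int = DEFAULT_WINDOW,
    scale: str = "per_thousand",
    code: GeneticCode | None = None,
    *,
    allow_short: bool = False,
) -> MinMaxProfile:
    """Sliding-window %MinMax values in [-100, +100] along a CDS.

    A CDS shorter than the window is an error unless ``allow_short``
    collapses it to a single full-length window.
    """
    from .sequence_io import standard_code

    gc = code or standard_code()
    freq = _frequency_map(table, gc, scale)
    codons = [c for c in cds.sense_codons(gc) if gc.codon_to_aa[c] != STOP]
    n = len(codons)
    if window < 2:
        raise MinMaxError("window must be at least 2 codons")
    if n < window:
        if not allow_short:
            raise MinMaxError(
                f"record {cds.id!r}: {n} sense codons is shorter than the "
                f"{window}-codon window (pass allow_short to collapse)"
            )
        window = n
    actual = []
    fmax = []
    fmin = []
    favg = []
    for codon in codons:
        fam = gc.family(gc.codon_to_aa[codon])
        fam_vals = [freq[c] for c in fam]
        actual.append(freq[codon])
        fmax.append(max(fam_vals))
        fmin.append(min(fam_vals))
        favg.append(sum(fam_vals) / len(fam_vals))
    values = []
    for start in range(n - window + 1):
        sl = slice(start, start + window)
        x_act = sum(actual[sl]) / window
        x_max = sum(fmax[sl]) / window
        x_min = sum(fmin[sl]) / window
        x_avg = sum(favg[sl]) / window
        if x_act > x_avg and x_max > x_avg:
            v = 100.0 * (x_act - x_avg) / (x_max - x_avg)
        elif x_act < x_avg and x_avg > x_min:
            v = -100.0 * (x_avg - x_act) / (x_avg - x_min)
        else:
            v = 0.0
        values.append(max(-100.0, min(100.0, v)))  # guard float round-off
    return MinMaxProfile(
        cds_id=cds.id,
        window=window,
        values=tuple(values),
        scale=scale,
        table_id=table.organism,
    )


def pct_min_window(profile: MinMaxProfile) -> float:
    """Percent of the profile's windows scoring below zero — the fraction of
    the CDS sitting in rare-codon territory."""
    if len(profile) == 0:
        raise MinMaxError(f"empty profile for {profile.cds_id!r}")
    return 100.0 * sum(v < 0 for v in profile.values) / len(profile.values)
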