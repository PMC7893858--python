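"""Plot-ready tabular exports (TSV/JSON) with the effective run config embedded.

Every writer prefixes TSV output with ``# key=value`` comment lines (and
adds a ``config`` object to JSON output) so a rerun with the same config is
byte-identical for deterministic commands.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .compare import IdentityMatrix, ReproducibilityReport
from .metrics import CdsMetrics, CodonProfile
from .minmax import MinMaxProfile

METRIC_COLUMNS = [
    "id", "n_codons", "median_frequency", "mean_frequency", "cai",
    "pct_gc", "pct_gc3", "pct_min_window", "table_id",
]


def metrics_frame(rows: Iterable[CdsMetrics]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return df.rename(columns={"cds_id": "id"})[METRIC_COLUMNS]


def violin_long_frame(profiles: Iterable[CodonProfile]) -> pd.DataFrame:
    """Long-format (cds_id, position, frequency) table, 1-based positions."""
    rows = [
        (p.cds_id, i + 1, v)
        for p in profiles
        for i, v in enumerate(p.values)
    ]
    return pd.DataFrame(rows, columns=["cds_id", "position", "frequency"])


def minmax_long_frame(profiles: Iterable[MinMaxProfile]) -> pd.DataFrame:
    rows = [
        (p.cds_id, i + 1, v)
        for p in profiles
        for i, v in enumerate(p.values)
    ]
    return pd.DataFrame(rows, columns=["cds_id", "window_start_codon", "value"])


def minmax_heatmap_frame(profiles: Iterable[MinMaxProfile]) -> pd.DataFrame:
    """CDS x window matrix (rows = CDS labels); ragged rows padded with NaN."""
    profiles = list(profiles)
    width = max(len(p) for p in profiles)
    data = {
        p.cds_id: list(p.values) + [np.nan] * (width - len(p)) for p in profiles
    }
    return pd.DataFrame(data).T


def identity_frame(m: IdentityMatrix) -> pd.DataFrame:
    return pd.DataFrame(m.matrix, index=list(m.labels), columns=list(m.labels))


def config_header(config: Mapping) -> str:
    return "".join(f"# {k}={v}\n" for k, v in sorted(config.items()))


def write_tsv(df: pd.DataFrame, path, config: Mapping | None = None, **to_csv_kwargs) -> None:
    with open(path, "w") as fh:
        if config:
            fh.write(config_header(config))
        df.to_csv(fh, sep="\t", index=to_csv_kwargs.pop("index", False), **to_csv_kwargs)


def report_to_dict(report: ReproducibilityReport) -> dict:
    return {
        "algorithms": {
            label: {
                "labels": list(m.labels),
                "matrix": m.matrix.tolist(),
                "mean_offdiag": report.means[label],
                "within_random_band": report.within_random_band[label],
            }
            for label, m in report.matrices.items()
        },
        "baseline": dataclasses.asdict(report.baseline),
    }


def write_json(obj, path, config: Mapping | None = None) -> None:
    payload = dict(obj)
    if config:
        payload["config"] = dict(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
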