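"""Footprint occupancy score (FOS) filtering.

Footprints are short intervals inside accessible peaks where transposase
cut density drops, indicating probable protein binding. Each carries a
footprint occupancy score; smaller FOS means a better-supported footprint.
Only footprints with FOS strictly below ``median + (median - minimum)`` of
the full score distribution are retained for motif scanning.

Footprint *detection* (e.g. Wellington on cut-site profiles) is upstream of
this package; detected footprints and their FOS values are inputs. The
upstream detection settings can be recorded alongside imported tables via
:data:`WELLINGTON_SETTINGS`-style metadata for provenance.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

#: conventional Wellington CLI settings recorded for provenance when
#: importing footprints produced by pyDNase's wellington_footprints.py
WELLINGTON_SETTINGS = "-fp 6,41,1 -sh 7,36,1 -fdr 0.01 -fdriter 100 -fdrlimit -30 -A"

REQUIRED_COLUMNS = ("footprint", "peak", "start", "end")


def fos_threshold(fos_values: Sequence[float]) -> float:
    """FOS retention threshold: median + (median - minimum).

    The threshold always lies at or above the median, so at least half of
    the footprints are retained except in the degenerate all-equal case,
    where threshold equals the common value and the strict comparison
    retains nothing.
    """
    values = np.asarray(fos_values, dtype=float)
    if values.size == 0:
        raise ValueError("fos_threshold requires a nonempty list")
    if not np.isfinite(values).all():
        raise ValueError("FOS values must be finite")
    med = float(np.median(values))
    return med + (med - float(values.min()))


def filter_footprints(
    footprints: pd.DataFrame, fos_column: str = "FOS"
) -> pd.DataFrame:
    """Retain footprints with FOS strictly below the global threshold.

    The threshold is computed once on the whole input table (not per peak).
    Re-filtering the retained table recomputes a lower threshold and can
    remove more rows; the operation is deliberately not idempotent.
    """
    if fos_column not in footprints.columns:
        raise ValueError(f"missing FOS column {fos_column!r}")
    if len(footprints) == 0:
        return footprints.copy()
    thr = fos_threshold(footprints[fos_column].to_numpy())
    return footprints[footprints[fos_column] < thr].copy()


def read_footprints(path) -> pd.DataFrame:
    """Read a footprint table (TSV with footprint, peak, start, end, FOS)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"footprint table missing columns: {missing}")
    return df


def write_footprints(footprints: pd.DataFrame, path) -> None:
    footprints.to_csv(path, sep="\t", index=False)
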