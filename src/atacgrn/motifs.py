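"""TRANSFAC matrix parsing and PWM log-odds scanning of footprint sequences.

A position weight matrix (PWM) holds per-position base counts for a TF's
binding site. Scanning scores every offset of a sequence (both strands)
with the log2-odds of the position-specific base probabilities (with
pseudocount) against a background model; an offset is a hit when its score
reaches a configurable fraction of the achievable score range:

    score >= min_score + rel_threshold * (max_score - min_score)

`N` bases score 0 (indistinguishable from background). TRANSFAC records are
parsed with Biopython's motif reader behind a stricter numeric pre-check.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ENCODE = {b: i for i, b in enumerate(BASES)} | {"N": 4}

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class PWM:
    """Position count matrix with background model and pseudocount."""

    tf: str
    counts: np.ndarray  # (width, 4) in A,C,G,T order
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND
    pseudocount: float = 0.25

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"PWM {self.tf!r}: counts must be (width, 4) with width >= 1")
        if (counts < 0).any():
            raise ValueError(f"PWM {self.tf!r}: negative counts")
        if not np.isclose(sum(self.background), 1.0):
            raise ValueError(f"PWM {self.tf!r}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) log2-odds of base probability vs background."""
        c = self.counts + self.pseudocount
        probs = c / c.sum(axis=1, keepdims=True)
        return np.log2(probs / np.asarray(self.background))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def score_range(self) -> tuple[float, float]:
        lo = self.log_odds
        return float(lo.min(axis=1).sum()), float(lo.max(axis=1).sum())


@dataclass(frozen=True)
class ScanHit:
    tf: str
    offset: int
    strand: str  # "+" or "-"
    score: float


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# TRANSFAC I/O
# ---------------------------------------------------------------------------


def _precheck_transfac(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        head = stripped.split()[0]
        if head.isdigit():
            cells = stripped.split()
            if len(cells) < 5:
                raise ValueError(
                    f"TRANSFAC line {lineno}: matrix row has fewer than 4 count cells"
                )
            for cell in cells[1:5]:
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"TRANSFAC line {lineno}: non-numeric count {cell!r}"
                    ) from None


def parse_transfac(
    text: str,
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND,
    pseudocount: float = 0.25,
) -> list[PWM]:
    """Parse TRANSFAC-format matrix text into PWMs (counts kept exactly)."""
    _precheck_transfac(text)
    if "//" not in text:
        raise ValueError("TRANSFAC record missing // terminator")
    records = bio_motifs.parse(io.StringIO(text), "TRANSFAC", strict=False)
    out = []
    for rec in records:
        name = rec.get("ID") or rec.get("AC") or rec.name or f"motif{len(out) + 1}"
        counts = np.stack([np.asarray(rec.counts[b], dtype=float) for b in BASES], axis=1)
        out.append(PWM(name, counts, background=background, pseudocount=pseudocount))
    return out


def read_transfac(path, **kwargs) -> list[PWM]:
    with open(path) as fh:
        return parse_transfac(fh.read(), **kwargs)


def write_transfac(pwms: Iterable[PWM]) -> str:
    lines = []
    for pwm in pwms:
        lines.append(f"ID {pwm.tf}")
        lines.append("BF .")
        lines.append("P0      A      C      G      T")
        for i, row in enumerate(pwm.counts, start=1):
            cons = BASES[int(np.argmax(row))]
            cells = "      ".join(f"{v:g}" for v in row)
            lines.append(f"{i:02d}      {cells}      {cons}")
        lines.append("XX")
        lines.append("//")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENCODE[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"sequence contains invalid base {exc.args[0]!r}") from None


def _strand_scores(lookup: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Scores at every offset; lookup is (width, 5) with column 4 = N = 0."""
    w = lookup.shape[0]
    if codes.size < w:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lookup[np.arange(w)[None, :], windows].sum(axis=1)


def scan_sequence(
    pwm: PWM, seq: str, rel_threshold: float = 0.8
) -> list[ScanHit]:
    """Scan both strands of ``seq`` for PWM hits above the relative threshold.

    Offsets are 0-based positions of the hit's left edge on the forward
    sequence for both strands. A sequence shorter than the PWM yields no
    hits. Raising ``rel_threshold`` can only remove hits.
    """
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    codes = _encode(seq)
    w = pwm.width
    if codes.size < w:
        return []
    lookup = np.zeros((w, 5))
    lookup[:, :4] = pwm.log_odds
    lo, hi = pwm.score_range()
    cutoff = lo + rel_threshold * (hi - lo)

    hits: list[ScanHit] = []
    fwd = _strand_scores(lookup, codes)
    for off in np.flatnonzero(fwd >= cutoff):
        hits.append(ScanHit(pwm.tf, int(off), "+", float(fwd[off])))
    rc = _encode(reverse_complement(seq))
    rev = _strand_scores(lookup, rc)
    n = codes.size
    for j in np.flatnonzero(rev >= cutoff):
        hits.append(ScanHit(pwm.tf, int(n - w - j), "-", float(rev[j])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_footprints(
    pwms: Sequence[PWM],
    sequences: Mapping[str, str],
    footprint_peak: Mapping[str, str],
    rel_threshold: float = 0.8,
) -> pd.DataFrame:
    """Scan footprint sequences with a PWM library.

    ``sequences`` maps footprint identifier to its nucleotide sequence and
    ``footprint_peak`` maps footprint to its parent peak. Returns a hits
    table with one row per (TF, footprint, offset, strand).
    """
    rows = []
    for pwm in pwms:
        for fp_id in sorted(sequences):
            for hit in scan_sequence(pwm, sequences[fp_id], rel_threshold):
                rows.append(
                    (hit.tf, footprint_peak[fp_id], fp_id, hit.offset, hit.strand, hit.score)
                )
    return pd.DataFrame(
        rows, columns=["tf", "peak", "footprint", "offset", "strand", "score"]
    )


def tf_peak_sets(hits: pd.DataFrame) -> dict[str, set[str]]:
    """Collapse a hits table to TF -> set of motif-bearing peaks.

    Each peak appears once per TF regardless of hit multiplicity; TFs with
    no hits are absent from the map.
    """
    out: dict[str, set[str]] = {}
    for tf, sub in hits.groupby("tf", sort=True):
        peaks = set(sub["peak"])
        if peaks:
            out[str(tf)] = peaks
    return out
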