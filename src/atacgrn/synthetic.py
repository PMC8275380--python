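"""Synthetic study generator with planted ground truth.

Everything the pipeline consumes can be generated here on a single
synthetic chromosome ``chrS``: replicate-level peak calls with boundary
jitter and dropout, donor-paired negative-binomial count matrices,
footprints with a right-skewed gamma FOS distribution, and footprint
sequences with PWM consensus instances planted toward one end of a ranked
peak list. The returned :class:`SyntheticTruth` records what was planted
so downstream stages can be scored against known answers.

The defaults emulate the study design the pipeline targets: 3 technical
replicates per sample, 6 donors, paired group design, 42 bp reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval
from .motifs import BASES, PWM

CHROM = "chrS"
READ_LENGTH = 42


@dataclass
class SyntheticTruth:
    """Planted ground truth for one synthetic dataset."""

    seed: int
    true_consensus: list[GenomicInterval] = field(default_factory=list)
    true_differential: dict[str, tuple[int, float]] = field(default_factory=dict)
    planted_tfs: dict[str, tuple[str, float]] = field(default_factory=dict)
    planted_sites: list[tuple[str, str, str, int]] = field(default_factory=list)
    hub_tf: str | None = None


# ---------------------------------------------------------------------------
# Replicate peak calls
# ---------------------------------------------------------------------------


def generate_replicate_peaks(
    n_regions: int,
    n_replicates: int,
    n_samples: int,
    jitter_sd: float = 5.0,
    dropout_rate: float = 0.2,
    seed: int = 0,
    region_length: tuple[int, int] = (200, 500),
) -> tuple[list[list[list[GenomicInterval]]], SyntheticTruth]:
    """Per-sample, per-replicate peak calls around true accessible regions.

    True regions are placed on ``chrS`` with gaps larger than
    ``2 * (4 * jitter_sd + 42)`` so jittered copies can never bridge two
    regions. Each replicate of each sample contains each region with
    probability ``1 - dropout_rate``, boundaries perturbed by rounded
    Gaussian jitter. Returns ``samples[sample][replicate]`` lists plus the
    truth. Deterministic given ``seed``.
    """
    if n_regions < 1 or n_replicates < 1 or n_samples < 1:
        raise ValueError("n_regions, n_replicates and n_samples must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be nonnegative")
    if not 0 <= dropout_rate <= 1:
        raise ValueError("dropout_rate must lie in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    min_gap = int(2 * (4 * jitter_sd + READ_LENGTH)) + 1
    regions: list[GenomicInterval] = []
    pos = 1000
    for _ in range(n_regions):
        length = int(rng.integers(region_length[0], region_length[1] + 1))
        regions.append(GenomicInterval(CHROM, pos, pos + length))
        pos += length + min_gap + int(rng.integers(0, 500))

    samples: list[list[list[GenomicInterval]]] = []
    for _ in range(n_samples):
        reps: list[list[GenomicInterval]] = []
        for _ in range(n_replicates):
            peaks = []
            for region in regions:
                if rng.random() < dropout_rate:
                    continue
                ds = int(np.round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
                de = int(np.round(rng.normal(0.0, jitter_sd))) if jitter_sd > 0 else 0
                start, end = region.start + ds, region.end + de
                if end <= start:  # pathological jitter on a tiny region
                    start, end = region.start, region.end
                peaks.append(GenomicInterval(CHROM, start, end))
            reps.append(peaks)
        samples.append(reps)
    truth = SyntheticTruth(seed=seed, true_consensus=list(regions))
    return samples, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def generate_counts(
    features: Sequence[str],
    n_donors: int = 6,
    groups: tuple[str, str] = ("A", "B"),
    diff_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    base_mean: float = 100.0,
    donor_sigma: float = 0.3,
    diff_features: Sequence[str] | None = None,
    directions: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Donor-paired negative-binomial count matrix with a planted group effect.

    Feature baselines are lognormal around ``base_mean``; each donor carries
    a multiplicative lognormal effect shared by its two samples (paired
    nuisance variation); ``diff_fraction`` of features get a group effect of
    ``effect_log2fc`` log2 units in a random direction (or the explicit
    ``diff_features``/``directions``). Counts are NB with the given
    dispersion (variance mu + dispersion * mu^2). Columns are named
    ``{group}_d{donor}``. Truth records (direction, |log2FC|) per
    differential feature; with a zero effect size nothing is marked.
    """
    if n_donors < 2:
        raise ValueError("paired design requires at least 2 donors")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if not 0 <= diff_fraction <= 1:
        raise ValueError("diff_fraction must lie in [0, 1]")

    features = list(features)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    nf = len(features)
    base = base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=nf) / math.exp(0.5)
    donor_fx = rng.lognormal(mean=0.0, sigma=donor_sigma, size=n_donors)

    if diff_features is None:
        n_diff = int(round(diff_fraction * nf)) if effect_log2fc != 0 else 0
        diff_idx = rng.choice(nf, size=n_diff, replace=False) if n_diff else np.array([], int)
        diff_features = [features[i] for i in sorted(diff_idx)]
    if effect_log2fc == 0:
        diff_features = []
    pos = {f: i for i, f in enumerate(features)}
    if directions is None:
        directions = {
            f: int(d) for f, d in zip(diff_features, rng.choice([-1, 1], size=len(diff_features)))
        }

    log2_shift = np.zeros(nf)
    truth = SyntheticTruth(seed=seed)
    for f in diff_features:
        d = directions[f]
        log2_shift[pos[f]] = d * effect_log2fc
        truth.true_differential[f] = (d, abs(effect_log2fc))

    g1, g2 = groups
    columns: dict[str, np.ndarray] = {}
    r = 1.0 / dispersion
    for d in range(n_donors):
        for gname, sign in ((g1, +0.5), (g2, -0.5)):
            mu = base * donor_fx[d] * np.exp2(sign * log2_shift)
            p = r / (r + mu)
            columns[f"{gname}_d{d + 1}"] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(columns, index=pd.Index(features, name="feature"))
    return counts, truth


def reads_from_counts(
    counts: pd.DataFrame,
    feature_intervals: Mapping[str, GenomicInterval],
    read_length: int = READ_LENGTH,
    seed: int = 0,
    background_reads: int = 0,
    chrom_length: int | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Place each counted read uniformly inside its feature.

    Reads are fully contained in their region, so counting them back with
    the half-overlap rule recovers the matrix exactly; optional background
    reads are scattered uniformly along the chromosome.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if chrom_length is None:
        chrom_length = max(iv.end for iv in feature_intervals.values()) + 10_000
    out: dict[str, list[GenomicInterval]] = {}
    for sample in counts.columns:
        reads: list[GenomicInterval] = []
        col = counts[sample]
        for feat in counts.index:
            iv = feature_intervals[feat]
            n = int(col[feat])
            if n == 0:
                continue
            hi = max(iv.start + 1, iv.end - read_length)
            starts = rng.integers(iv.start, hi, size=n)
            reads.extend(GenomicInterval(iv.chrom, int(s), int(s) + read_length) for s in starts)
        if background_reads:
            starts = rng.integers(0, chrom_length - read_length, size=background_reads)
            reads.extend(GenomicInterval(CHROM, int(s), int(s) + read_length) for s in starts)
        out[sample] = sorted(reads)
    return out


# ---------------------------------------------------------------------------
# Footprints, sequences and planted motifs
# ---------------------------------------------------------------------------


def random_pwm_library(
    n_tfs: int, width: int = 8, seed: int = 0, strength: float = 20.0
) -> list[PWM]:
    """PWMs with random consensus sequences and strongly peaked columns."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pwms = []
    for i in range(n_tfs):
        consensus = rng.integers(0, 4, size=width)
        counts = np.ones((width, 4))
        counts[np.arange(width), consensus] = strength
        pwms.append(PWM(f"TF{i + 1:02d}", counts))
    return pwms


def generate_footprints_and_sequences(
    peaks: Sequence[tuple[str, GenomicInterval]],
    pwm_library: Sequence[PWM],
    planted: Mapping[str, float] | None = None,
    top_fraction: float = 0.1,
    end: str = "top",
    fos_gamma: tuple[float, float] = (2.0, 0.5),
    fos_constant: float | None = None,
    footprints_per_peak: int = 2,
    footprint_width: int = 30,
    seed: int = 0,
    planted_assignments: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, str], SyntheticTruth]:
    """Footprints with FOS plus per-peak sequences carrying planted motifs.

    ``peaks`` must be ranked best-first; for each planted TF the stated
    fraction of the top (or bottom) ``top_fraction`` block of peaks gets the
    TF's consensus sequence embedded in one of its footprints.
    ``planted_assignments`` overrides the fraction logic with explicit
    per-TF peak lists (used by the pipeline to plant against several
    rankings at once). FOS values are gamma distributed (right-skewed);
    footprints carrying a planted motif draw from the lower half of the
    same distribution, modelling truly occupied, well-protected sites.
    ``fos_constant`` forces the degenerate all-equal FOS case.

    Returns (footprint table, peak sequences, truth); the truth lists every
    planted site as (tf, peak, footprint, offset within footprint) and sets
    ``hub_tf`` to the planted TF with the most planted peaks.
    """
    planted = dict(planted or {})
    pwm_by_tf = {p.tf: p for p in pwm_library}
    max_w = max((p.width for p in pwm_library), default=0)
    if max_w >= footprint_width:
        raise ValueError(
            f"footprint_width={footprint_width} must exceed widest PWM ({max_w})"
        )
    for tf, frac in planted.items():
        if tf not in pwm_by_tf:
            raise ValueError(f"planted TF {tf!r} not in PWM library")
        if not 0 <= frac <= 1:
            raise ValueError(f"planted fraction for {tf!r} must lie in [0, 1]")
    if end not in ("top", "bottom"):
        raise ValueError("end must be 'top' or 'bottom'")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    peaks = list(peaks)
    peak_ids = [pid for pid, _ in peaks]

    # choose which peaks carry which TF
    if planted_assignments is None:
        block_n = max(1, int(math.ceil(top_fraction * len(peaks))))
        block = peak_ids[:block_n] if end == "top" else peak_ids[-block_n:]
        planted_assignments = {}
        for tf in sorted(planted):
            k = int(round(planted[tf] * block_n))
            chosen = rng.choice(block_n, size=k, replace=False) if k else np.array([], int)
            planted_assignments[tf] = [block[i] for i in sorted(chosen)]

    shape, scale = fos_gamma
    if fos_constant is None and (shape <= 0 or scale <= 0):
        raise ValueError("fos_gamma shape and scale must be positive")

    seqs: dict[str, str] = {}
    rows: list[tuple[str, str, int, int, float]] = []
    fp_lookup: dict[str, list[str]] = {}
    for pid, iv in peaks:
        length = iv.length
        seq = "".join(rng.choice(list(BASES), size=length))
        seqs[pid] = seq
        k = min(footprints_per_peak, max(1, length // (2 * footprint_width)))
        slot = length // k
        fp_ids = []
        for j in range(k):
            lo = j * slot
            hi = min((j + 1) * slot, length) - footprint_width
            off = int(rng.integers(lo, max(hi, lo) + 1))
            fp_id = f"{pid}_fp{j + 1}"
            if fos_constant is not None:
                fos = float(fos_constant)
            else:
                fos = float(rng.gamma(shape, scale))
            rows.append((fp_id, pid, iv.start + off, iv.start + off + footprint_width, fos))
            fp_ids.append(fp_id)
        fp_lookup[pid] = fp_ids

    fp_df = pd.DataFrame(rows, columns=["footprint", "peak", "start", "end", "FOS"])
    fp_index = {r[0]: i for i, r in enumerate(rows)}
    peak_start = {pid: iv.start for pid, iv in peaks}

    truth = SyntheticTruth(seed=seed)
    for tf in sorted(planted_assignments):
        pwm = pwm_by_tf[tf]
        site = pwm.consensus
        for pid in planted_assignments[tf]:
            fp_id = fp_lookup[pid][int(rng.integers(0, len(fp_lookup[pid])))]
            i = fp_index[fp_id]
            fp_row = fp_df.iloc[i]
            fp_off_in_peak = int(fp_row["start"]) - peak_start[pid]
            max_off = footprint_width - pwm.width
            off = int(rng.integers(0, max_off + 1))
            s = seqs[pid]
            p0 = fp_off_in_peak + off
            seqs[pid] = s[:p0] + site + s[p0 + pwm.width :]
            truth.planted_sites.append((tf, pid, fp_id, off))
            if fos_constant is None:
                # occupied sites are well protected: FOS from the lower half
                u = rng.uniform(0.0, 0.5)
                fp_df.iat[i, fp_df.columns.get_loc("FOS")] = float(
                    stats.gamma.ppf(u, shape, scale=scale)
                )
    for tf in sorted(planted):
        truth.planted_tfs[tf] = (end, planted[tf])
    counts_per_tf = {
        tf: len(set(p for t, p, _, _ in truth.planted_sites if t == tf))
        for tf in planted_assignments
    }
    if counts_per_tf:
        truth.hub_tf = max(sorted(counts_per_tf), key=lambda t: counts_per_tf[t])
    return fp_df, seqs, truth


def footprint_sequences(
    footprints: pd.DataFrame,
    peak_sequences: Mapping[str, str],
    peak_intervals: Mapping[str, GenomicInterval],
) -> dict[str, str]:
    """Extract each footprint's sequence from its parent peak sequence."""
    out = {}
    for row in footprints.itertuples(index=False):
        iv = peak_intervals[row.peak]
        out[row.footprint] = peak_sequences[row.peak][row.start - iv.start : row.end - iv.start]
    return out


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
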