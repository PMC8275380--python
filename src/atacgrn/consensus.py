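"""Consensus peak construction, read counting, gene annotation and variant overlap.

The consensus set is built in two stages. Stage one acts within one sample:
peaks reproduced in at least two technical replicates (75% reciprocal
overlap) are split at all boundary points into disjoint atoms, atoms
supported by at least two replicates are kept, and bookended atoms are
merged. Stage two acts across samples: atoms supported by at least four
samples survive, and surviving regions closer than the read length (42 bp)
are merged into single consensus peaks.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, merge_intervals, sort_intervals

Category = str  # one of: promoter-TSS, TTS, exon, intron, intergenic


def reciprocal_overlap(
    a: GenomicInterval, b: GenomicInterval
) -> tuple[float, float]:
    """Fraction of ``a`` and of ``b`` covered by their intersection.

    Returns ``(0.0, 0.0)`` for intervals on different sequences.
    """
    inter = a.overlap_length(b)
    if inter == 0:
        return (0.0, 0.0)
    return (inter / a.length, inter / b.length)


def _atoms_with_support(
    sources: Sequence[Sequence[GenomicInterval]],
) -> list[tuple[GenomicInterval, int]]:
    """Partition the union of all intervals at every boundary point.

    Returns disjoint atoms (sub-intervals between consecutive boundaries
    covered by at least one interval) with the number of distinct sources
    containing each atom. A source supports an atom iff one of its
    intervals covers the atom entirely; since atoms never straddle a
    boundary, covering any point of the atom is equivalent.
    """
    by_chrom: dict[str, list[tuple[int, int, int]]] = defaultdict(list)
    for src_idx, ivs in enumerate(sources):
        for iv in ivs:
            by_chrom[iv.chrom].append((iv.start, iv.end, src_idx))

    atoms: list[tuple[GenomicInterval, int]] = []
    for chrom in sorted(by_chrom):
        triples = by_chrom[chrom]
        bounds = sorted({x for s, e, _ in triples for x in (s, e)})
        starts = [s for s, _, _ in triples]
        order = sorted(range(len(triples)), key=lambda i: starts[i])
        triples = [triples[i] for i in order]
        sorted_starts = [t[0] for t in triples]
        for lo, hi in zip(bounds, bounds[1:]):
            # intervals with start <= lo and end >= hi cover [lo, hi)
            k = bisect.bisect_right(sorted_starts, lo)
            supporters = {t[2] for t in triples[:k] if t[1] >= hi}
            if supporters:
                atoms.append((GenomicInterval(chrom, lo, hi), len(supporters)))
    return atoms


def replicate_consensus(
    replicate_peaks: Sequence[Sequence[GenomicInterval]],
    min_replicates: int = 2,
    min_reciprocal: float = 0.75,
) -> list[GenomicInterval]:
    """Stage-one consensus across technical replicates of one sample.

    A peak is *selected* if at least ``min_replicates - 1`` other
    replicates each contain a partner peak with reciprocal overlap of at
    least ``min_reciprocal`` in both directions. Selected peaks are
    partitioned into disjoint atoms; atoms present in at least
    ``min_replicates`` replicates are kept and bookended atoms merged.
    """
    if len(replicate_peaks) == 0 or all(len(r) == 0 for r in replicate_peaks):
        raise ValueError("replicate_consensus requires at least one nonempty replicate set")
    if min_replicates > len(replicate_peaks):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds number of replicates "
            f"({len(replicate_peaks)})"
        )

    selected: list[list[GenomicInterval]] = []
    for i, peaks in enumerate(replicate_peaks):
        keep = []
        for p in peaks:
            n_partners = 0
            for j, other in enumerate(replicate_peaks):
                if j == i:
                    continue
                for q in other:
                    fa, fb = reciprocal_overlap(p, q)
                    if fa >= min_reciprocal and fb >= min_reciprocal:
                        n_partners += 1
                        break
            if n_partners >= min_replicates - 1:
                keep.append(p)
        selected.append(keep)

    kept = [
        iv for iv, support in _atoms_with_support(selected) if support >= min_replicates
    ]
    return merge_intervals(kept, max_gap=0)


def cross_sample_consensus(
    samples: Sequence[Sequence[GenomicInterval]],
    min_samples: int = 4,
    merge_distance: int = 42,
) -> list[GenomicInterval]:
    """Stage-two consensus across samples.

    All sample region sets are pooled and partitioned into atoms; atoms
    covered by at least ``min_samples`` samples survive, and surviving
    regions whose gap is at most ``merge_distance`` bases are merged.
    Output is sorted, disjoint, with all pairwise gaps > ``merge_distance``.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be at least 1")
    if min_samples > len(samples):
        raise ValueError(
            f"min_samples={min_samples} exceeds number of samples ({len(samples)})"
        )
    kept = [
        iv for iv, support in _atoms_with_support(samples) if support >= min_samples
    ]
    return merge_intervals(kept, max_gap=merge_distance)


def count_reads(
    reads: Mapping[str, Sequence[GenomicInterval]] | Sequence[Sequence[GenomicInterval]],
    features: Sequence[GenomicInterval],
    min_read_overlap: float = 0.5,
) -> pd.DataFrame:
    """Count reads into disjoint consensus features (features x samples).

    A read is assigned to a feature iff their overlap is at least
    ``min_read_overlap`` times the read length; every read counts at most
    once. If two features reach the bound (only possible at exactly half
    overlap each), the read goes to the feature with the larger overlap,
    ties broken by the smaller feature start.
    """
    features = sort_intervals(features)
    for a, b in zip(features, features[1:]):
        if a.chrom == b.chrom and b.start < a.end:
            raise ValueError(f"features must be disjoint; {a.name} overlaps {b.name}")

    if isinstance(reads, Mapping):
        sample_names = list(reads.keys())
        read_sets = [reads[s] for s in sample_names]
    else:
        sample_names = [f"sample{i + 1}" for i in range(len(reads))]
        read_sets = list(reads)

    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for f in features:
        by_chrom[f.chrom].append(f)
    starts_by_chrom = {c: [f.start for f in fs] for c, fs in by_chrom.items()}

    feature_names = [f.name for f in features]
    feature_pos = {f: i for i, f in enumerate(features)}
    counts = pd.DataFrame(
        0, index=pd.Index(feature_names, name="feature"), columns=sample_names, dtype=int
    )

    for col, rs in zip(sample_names, read_sets):
        col_counts = counts[col].to_numpy()
        for read in rs:
            fs = by_chrom.get(read.chrom)
            if not fs:
                continue
            starts = starts_by_chrom[read.chrom]
            lo = bisect.bisect_right(starts, read.start) - 1
            best = None  # (overlap, -start, feature)
            for f in fs[max(lo, 0) : bisect.bisect_right(starts, read.end)]:
                ov = read.overlap_length(f)
                if ov * 2 >= read.length * 2 * min_read_overlap and ov > 0:
                    key = (ov, -f.start)
                    if best is None or key > best[0]:
                        best = (key, f)
            if best is not None:
                col_counts[feature_pos[best[1]]] += 1
        counts[col] = col_counts
    return counts


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    """Minimal gene model: span, strand, optional exons (0-based half-open)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class GeneModel:
    genes: list[Gene] = field(default_factory=list)

    @classmethod
    def from_bed6(cls, path) -> "GeneModel":
        """Gene spans from a 6-column BED (name in column 4, strand in 6)."""
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 6:
                    raise ValueError(f"expected 6-column BED, got: {line!r}")
                genes.append(Gene(f[3], f[0], int(f[1]), int(f[2]), f[5]))
        return cls(genes)

    @classmethod
    def from_gff(cls, path) -> "GeneModel":
        """Gene + exon features from a GFF3/GTF file (via gffutils when
        available, else a tolerant line parser for the gene/exon subset)."""
        genes: dict[str, dict] = {}
        exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9:
                    continue
                chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
                ident = _parse_gene_id(attrs)
                if ftype == "gene":
                    genes[ident] = dict(
                        chrom=chrom, start=int(start) - 1, end=int(end), strand=strand
                    )
                elif ftype == "exon":
                    exons[ident].append((int(start) - 1, int(end)))
        return cls(
            [
                Gene(name, g["chrom"], g["start"], g["end"], g["strand"],
                     tuple(sorted(exons.get(name, []))))
                for name, g in genes.items()
            ]
        )


def _parse_gene_id(attrs: str) -> str:
    # GTF: gene_id "X"; GFF3: ID=X or Parent=X / gene_id=X
    for key in ("gene_id", "ID", "Parent", "Name"):
        for sep, quote in ((" ", '"'), ("=", "")):
            token = f"{key}{sep}"
            for part in attrs.replace(";", "; ").split("; "):
                part = part.strip().rstrip(";")
                if part.startswith(token):
                    return part[len(token):].strip('"')
    return attrs.strip()


@dataclass(frozen=True)
class AnnotatedPeak:
    interval: GenomicInterval
    gene: str | None
    category: Category
    distance_to_tss: int | None


def annotate_peak(
    peak: GenomicInterval,
    model: GeneModel,
    promoter_window: int = 1000,
    tts_window: int = 1000,
    distance_cap: int = 10_000,
) -> AnnotatedPeak:
    """Assign a peak to a gene and a genomic category by its midpoint.

    Categories are checked in precedence order promoter-TSS > TTS > exon >
    intron > intergenic against the gene with the nearest TSS on the same
    sequence. Peaks farther than ``distance_cap`` from every TSS are
    intergenic with no gene assigned.
    """
    if not model.genes:
        raise ValueError("empty gene annotation")
    mid = peak.midpoint
    same = [g for g in model.genes if g.chrom == peak.chrom]
    if not same:
        return AnnotatedPeak(peak, None, "intergenic", None)
    nearest = min(same, key=lambda g: (abs(mid - g.tss), g.name))
    signed = mid - nearest.tss
    if nearest.strand == "-":
        signed = -signed
    if abs(mid - nearest.tss) > distance_cap:
        return AnnotatedPeak(peak, None, "intergenic", None)
    if abs(mid - nearest.tss) <= promoter_window:
        cat = "promoter-TSS"
    elif abs(mid - nearest.tts) <= tts_window:
        cat = "TTS"
    elif any(s <= mid < e for s, e in nearest.exons):
        cat = "exon"
    elif nearest.start <= mid < nearest.end:
        cat = "intron"
    else:
        cat = "intergenic"
    return AnnotatedPeak(peak, nearest.name, cat, signed)


def annotate_peaks(
    peaks: Iterable[GenomicInterval], model: GeneModel, **kwargs
) -> pd.DataFrame:
    rows = []
    for p in peaks:
        a = annotate_peak(p, model, **kwargs)
        rows.append((p.name, a.gene, a.category, a.distance_to_tss))
    return pd.DataFrame(
        rows, columns=["peak", "gene", "category", "distance_to_tss"]
    ).set_index("peak")


def intersect_variants(
    variants: Iterable[tuple[str, int]], peaks: Sequence[GenomicInterval]
) -> dict[tuple[str, int], GenomicInterval]:
    """Map 0-based variant positions to the (disjoint) peak containing them.

    Variants falling in no peak are omitted from the result.
    """
    peaks = sort_intervals(peaks)
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append(p)
    out: dict[tuple[str, int], GenomicInterval] = {}
    for chrom, pos in variants:
        ps = by_chrom.get(chrom)
        if not ps:
            continue
        starts = [p.start for p in ps]
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and ps[i].contains_point(chrom, pos):
            out[(chrom, pos)] = ps[i]
    return out
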