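import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
    max_examples=50,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ranked_scores(rng):
    """A 2000-feature ranked list with symmetric scores, sorted descending."""
    scores = np.sort(rng.normal(size=2000))[::-1]
    return pd.Series(scores, index=[f"peak{i:04d}" for i in range(2000)], name="score")


def brute_force_consensus(sources, min_support, max_gap=0, max_coord=3000):
    """Per-base support-counting oracle for both consensus stages.

    Counts, for every base on every chromosome, how many sources cover it,
    keeps bases with support >= min_support, assembles maximal runs and
    merges runs whose gap is <= max_gap.
    """
    from atacgrn.intervals import GenomicInterval, merge_intervals

    chroms = {iv.chrom for src in sources for iv in src}
    kept = []
    for chrom in sorted(chroms):
        cover = np.zeros(max_coord, dtype=int)
        for src in sources:
            mask = np.zeros(max_coord, dtype=bool)
            for iv in src:
                if iv.chrom == chrom:
                    mask[iv.start : iv.end] = True
            cover += mask
        good = cover >= min_support
        start = None
        for pos in range(max_coord + 1):
            on = pos < max_coord and good[pos]
            if on and start is None:
                start = pos
            elif not on and start is not None:
                kept.append(GenomicInterval(chrom, start, pos))
                start = None
    return merge_intervals(kept, max_gap=max_gap)


def random_interval_sets(rng, n_sets, max_intervals=30, max_coord=1000):
    """Small random interval sets for oracle-equivalence checks."""
    from atacgrn.intervals import GenomicInterval

    sets = []
    for _ in range(n_sets):
        n = int(rng.integers(0, max_intervals + 1))
        ivs = []
        for _ in range(n):
            start = int(rng.integers(0, max_coord - 2))
            length = int(rng.integers(1, min(120, max_coord - start)))
            ivs.append(GenomicInterval("chrT", start, start + length))
        sets.append(sorted(ivs))
    return sets
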