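"""Build a consensus peak set from noisy replicate-level peak calls.

Generates 30 true accessible regions, observes them through 3 jittered
technical replicates in each of 8 samples, and runs the two consensus
stages: within-sample (>=2 replicates at 75% reciprocal overlap) and
across samples (>=4 samples, 42 bp merge distance).
"""

from atacgrn import (
    cross_sample_consensus,
    generate_replicate_peaks,
    replicate_consensus,
)

samples, truth = generate_replicate_peaks(
    n_regions=30, n_replicates=3, n_samples=8, jitter_sd=5, dropout_rate=0.2, seed=42
)

sample_regions = [replicate_consensus(reps) for reps in samples]
consensus = cross_sample_consensus(sample_regions, min_samples=4, merge_distance=42)

recovered = sum(
    any(t.jaccard(c) >= 0.9 for c in consensus) for t in truth.true_consensus
)
print(f"true regions:        {len(truth.true_consensus)}")
print(f"consensus peaks:     {len(consensus)}")
print(f"recovered (J>=0.9):  {recovered}")
print(f"first three: {[p.name for p in consensus[:3]]}")

# Despite 20% replicate dropout and 5 bp boundary jitter, the two-stage
# consensus recovers essentially every planted region with near-exact
# boundaries; spurious regions would need support in 4 of 8 samples.
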