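# Methods

This note documents the models, conventions and design choices behind
`atacgrn`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic benchmark does and does not
show about real data.

## Coordinates and formats

All intervals are BED-convention: 0-based, half-open `[start, end)`.
Feature identifiers are `chrom:start-end`. Differential tables are TSVs
with columns `feature, log2FC, PValue, FDR`; footprints are TSVs with
`footprint, peak, start, end, FOS`; PWMs are TRANSFAC-format text; gene
sets are GMT. Stage outputs are plain files so real-data users can enter
the pipeline at any point (e.g. with edgeR differential tables or
Wellington footprints; the conventional Wellington settings are recorded
in `footprints.WELLINGTON_SETTINGS` for provenance).

## Consensus construction

Stage one (within sample): a peak is reproducible if at least
`min_replicates − 1` other replicates each contain a partner with
reciprocal overlap ≥ `min_reciprocal` in *both* directions (bedtools
`-f/-r` semantics). Reproducible peaks are partitioned into disjoint atoms
at every boundary point; atoms covered by ≥ `min_replicates` replicates
are kept and bookended atoms merged. Stage two (across samples): support
is counted at atomic resolution — a sample supports an atom iff one of its
regions covers it — atoms with support ≥ `min_samples` survive, and
surviving regions with gap ≤ `merge_distance` are merged. "Gap" means
`start_j − end_i`, so a 43-base gap at `merge_distance = 42` stays split.
Both operations are idempotent on their own output and are verified
against an exhaustive per-base support-counting oracle in the tests.

Defaults: `min_replicates = 2`, `min_reciprocal = 0.75`,
`min_samples = 4`, `merge_distance = 42` bp (one read length),
`min_read_overlap = 0.5` (a read joins a feature only when at least half
of it overlaps; ties at exactly half/half go to the larger overlap, then
the smaller feature start — reachable only for bookended features).

Peak-to-gene annotation is deliberately simple: the peak midpoint is
classified against the gene with the nearest TSS in precedence order
promoter-TSS (TSS ± 1 kb) > TTS (± 1 kb) > exon > intron (gene body) >
intergenic, with a 10 kb cap beyond which no gene is assigned. A peak
within the cap but outside all windows is intergenic with the nearest gene
recorded. This mimics common annotator defaults and is plumbing, not a
reimplementation of any specific tool.

## Differential analysis

`call_differential` flags features with FDR < 0.05 and fold change ≥ 1.25
or ≤ 0.75 (both bounds inclusive; "more than 25% change" in either
direction). `rank_features` scores features by
−log₁₀(significance) × sign(log₂FC) with the significance floored at
1e−300 to keep scores finite; FDR is the default significance field and
p-value is available, since both conventions are in common use. Ties are
broken by feature identifier for determinism.

Real differential tables should come from a dedicated count-model fit
(e.g. an edgeR GLM with donor and condition covariates, CQN-normalized for
ATAC); reproducing such fits is out of scope. For the self-contained
synthetic chain the package ships `paired_nb_test`: the per-donor log2
ratio of library-size-normalized counts (offset 0.5) is tested against
zero with a one-sample t-test across donors. Donor-level multiplicative
effects cancel exactly within pairs, and the empirical per-feature
variance of the paired ratios absorbs negative-binomial overdispersion
without an explicit dispersion model — at n = 6 donors this is simpler
than, and in our simulations as well calibrated as, a moment-matched
score test (null type-I error within binomial tolerance of the nominal
5%; recall ≥ 80% for 2-log2-unit effects at dispersion 0.1).

`direction_agreement` restricts to features significant in both tables
(peaks translated to genes via the annotation, best-FDR peak per gene),
tabulates up/down calls, and computes an upper-tail Monte Carlo p for the
concordant count under random reshuffles of one margin (plus-one
corrected; default 10,000 reshuffles). With a single jointly significant
feature the test is undefined and an error is raised.

## Footprint filtering

The retention threshold is median(FOS) + (median − minimum), computed once
on the whole input table; footprints strictly below it are kept. Lower
FOS = better-supported footprint, following the score's published
orientation; imported data must match this convention. The threshold
never falls below the median, so at least half the footprints survive
except in the degenerate all-equal case where nothing does. Re-filtering
a filtered table computes a new, lower threshold and can remove more —
the operation is intentionally not idempotent and is applied exactly once
per analysis.

## Motif scanning

Scores are log₂-odds of pseudocounted position probabilities
(pseudocount 0.25 per cell) against a uniform background, summed over the
window, on both strands. `N` contributes 0 bits. A window is a hit when
its score reaches `min + rel_threshold × (max − min)` of the PWM's
achievable score range; `rel_threshold = 0.8` by default. The match
threshold materially shapes hit sets and no single convention is
standard, so it is explicit configuration rather than a constant.
Scanning is restricted to retained-footprint sequences, preserving the
footprint-then-motif order of the workflow. TRANSFAC parsing is backed by
Biopython's motif reader with a numeric pre-check that reports the
offending line; the scanner is cross-checked against Biopython's PSSM in
the tests.

## Enrichment

The statistic is the weighted KS running sum: hits increment by
|s|^weight / Σ_members |s|^weight, misses decrement by 1/(N − M); the ES
is the extremum. `weight = 1` (classic weighted GSEA) by default; if all
member scores are zero the hit increments fall back to uniform. The null
draws `n_perm` random member sets of the same size (equivalent to
permuting the ranked labels with scores held fixed — the chosen null is
recorded here deliberately, as permuting ranks and permuting memberships
coincide only under fixed scores). With observed ES of sign σ,

  p = (1 + #{null ES of sign σ at least as extreme}) / (1 + #{null ES of sign σ}),
  NES = ES / mean |null ES of sign σ|.

The sign-conditional denominator follows the GSEA convention and makes
null p-values uniform on [0, 1] (verified by KS test in the acceptance
suite); a fixed `n_perm + 1` denominator would cap p near ½ under a
sign-symmetric null. `n_perm = 1000` by default (minimum 100); every set
gets an independent child generator derived from the seed in sorted
set-name order, so results are independent of dictionary order.
BH correction is delegated to statsmodels and verified against a
hand-rolled step-up oracle.

## Network and PageRank

Sources: TFs enriched at FDR < 0.05 whose own gene passes the expression
detection filter (> 1 CPM in ≥ 3 samples — the minimal filtering rule is
taken to be the same detection rule used for the RNA analysis). Targets:
gene-level nodes; an edge exists when a peak assigned to the gene carries
a retained-footprint motif hit of the source TF and the peak is a DAR or
the gene a DEG; multiple supporting peaks collapse into one edge with an
evidence list.

PageRank is computed on the edge-inverted graph by sparse power iteration
with uniform teleport, dangling mass redistributed uniformly, damping
0.85 and L1 tolerance 1e−10 (both configurable; damping and the
percentile interpolation are conventions, not derived quantities). The
iteration is verified against a dense solve of
(I − d·Sᵀ)x = (1 − d)/N on random graphs (≤ 1e−8) and against networkx.
Key TFs are nodes strictly above the 99th percentile (linear
interpolation) of their own network's values; the comparison table
reports each selected node's value in both networks, encoding absence
from a network as a literal 0 — highly ranked in one network and 0 in the
other is the signature of a contrast-specific regulator. A TF's
above-median average expression ("highly expressed" class) is available
as an annotation but is not a hard filter.

## Synthetic data: what it emulates, and what it does not

The generator works on one synthetic chromosome `chrS` and mirrors the
targeted study design: 3 technical replicates per sample, 6 donors, two
paired contrasts (four conditions), 42 bp reads. True regions are spaced
with gaps > 2 × (4·jitter_sd + 42) so jittered observations can never
bridge regions and the planted truth stays unambiguous. Counts are
negative binomial (default dispersion 0.1, lognormal feature baselines
around mean 100) with lognormal donor effects (σ = 0.3) shared within a
donor's pair — nuisance variation the paired test must cancel. Default
effect size is 2 log2 units on 20% of features; RNA changes are planted
concordantly with ATAC changes for 80% of differential peaks' genes.

FOS values are gamma(2, 0.5) — right-skewed positive scores that exercise
the median/min threshold nontrivially (the distribution itself is a
modelling choice; no particular form is claimed for real data).
Footprints carrying a planted motif draw their FOS from the lower half of
the same gamma (inverse CDF of U(0, 0.5)): truly occupied sites are well
protected, so planted signal survives the occupancy filter by
construction. PWMs are random 8-mers with strongly peaked columns; the
planted hub TF's consensus is embedded in every top-decile peak of one
contrast only, two decoy-free "shared" TFs in both contrasts, and one TF
in the second contrast only; remaining PWMs are pure decoys.

The default pipeline scale (300 regions, 20 TFs, 1000 permutations) keeps
a full run under ~10 s while leaving every stage statistically
non-trivial; the acceptance script uses comparable sizes.

Passing on this benchmark demonstrates the *logic* of the chain —
thresholds, rankings, enrichment calibration, network assembly and the
cross-network comparison — under known truth. It does not demonstrate
robustness to properties the generator omits: GC and length biases (no
CQN here), correlated/overlapping peaks, non-uniform background sequence
composition, motif similarity between real TF families, footprint
detection noise, or library-composition effects on CPM normalization.
Real-data conclusions inherit the quality of the upstream peak caller,
differential model and footprint detector whose outputs this package
consumes.

## Numerical conventions

- Significance floors at 1e−300 before log10; rank ties broken by feature id.
- Median of an even-length list is the mean of the central pair.
- ES clipped to [−1, 1] against floating-point drift; first-extremum tie-break.
- Monte Carlo p-values are plus-one corrected and bounded below by 1/(n+1).
- PageRank values sum to 1 within 1e−9 and are strictly positive for d < 1.
- All generators and tests derive child seeds from a single integer seed
  via SeedSequence; identical seeds give byte-identical pipeline output
  (manifests contain no timestamps).

## Known limitations

- The paired test is a log-ratio t-test, not a GLM; with < 4 donors its
  power is poor and the synthetic defaults assume 6.
- The annotator is midpoint-based and single-gene; enhancers regulating
  distal genes are out of reach by design.
- Enrichment assumes member sets well below the size of the ranked list;
  sets empty or total after intersection are rejected, not skipped.
- The key-TF percentile is computed over all node values including
  low-ranked target genes, so the selection size scales with network
  size; with very small networks the 99th percentile selects a single
  node.
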