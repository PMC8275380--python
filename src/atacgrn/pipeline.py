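"""End-to-end orchestration: synthetic study -> consensus -> differential ->
footprints -> motifs -> enrichment -> networks -> key-TF comparison.

The synthetic run emulates a paired study of two contrasts sharing one set
of accessible regions (think cytokine-positive vs -negative cells, and
memory vs naive cells, profiled in the same donors): consensus peaks are
built from jittered replicate peak calls, ATAC reads are placed and counted
back, donor-paired tests call DARs per contrast, motif instances for a hub
TF (contrast A only) and shared TFs are planted in the top-ranked peaks,
and the two reconstructed networks are compared by inverted-edge PageRank.

Every stage writes plain files into the run directory so users with real
peak calls, differential tables or footprints can re-enter mid-pipeline;
``manifest.json`` records parameters, seeds and output checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import consensus as cns
from . import differential as diff
from . import enrichment as enr
from . import footprints as fps
from . import motifs as mot
from . import network as net
from . import synthetic as syn
from .intervals import GenomicInterval, write_bed

logger = logging.getLogger("atacgrn")


@dataclass
class RunConfig:
    """All pipeline parameters with their standard defaults.

    Thresholds mirror the analysis conventions of the method: >=2 of 3
    technical replicates at 75% reciprocal overlap, >=4 samples, 42 bp
    merge distance and read length, half-read overlap counting, FDR < 0.05
    with 1.25/0.75 fold-change bounds, >1 CPM in >=3 samples, FOS
    median+(median-min) filtering, FDR < 0.05 motif enrichment, damping
    0.85 and the 99th percentile for key-TF selection.
    """

    seed: int = 1
    # synthetic study scale
    n_regions: int = 300
    n_replicates: int = 3
    n_donors: int = 6
    jitter_sd: float = 5.0
    dropout_rate: float = 0.2
    diff_fraction: float = 0.2
    effect_log2fc: float = 2.0
    dispersion: float = 0.1
    donor_sigma: float = 0.3
    rna_concordance: float = 0.8
    n_tfs: int = 20
    pwm_width: int = 8
    top_fraction: float = 0.1
    hub_fraction: float = 1.0
    shared_fraction: float = 0.5
    footprints_per_peak: int = 2
    footprint_width: int = 30
    fos_shape: float = 2.0
    fos_scale: float = 0.5
    background_reads: int = 200
    # stage thresholds
    min_replicates: int = 2
    min_reciprocal: float = 0.75
    min_samples: int = 4
    merge_distance: int = 42
    min_read_overlap: float = 0.5
    read_length: int = 42
    min_cpm: float = 1.0
    min_cpm_samples: int = 3
    fdr_cutoff: float = 0.05
    fc_up: float = 1.25
    fc_down: float = 0.75
    rel_threshold: float = 0.8
    n_perm: int = 1000
    weight: float = 1.0
    damping: float = 0.85
    pagerank_tol: float = 1e-10
    percentile: float = 99.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ContrastResult:
    name: str
    atac_table: pd.DataFrame
    rna_table: pd.DataFrame
    ranked_peaks: pd.Series
    dar_peaks: set
    deg_genes: set
    enrichment: pd.DataFrame
    sources: set
    network: net.RegulatoryNetwork


@dataclass
class RunResult:
    config: RunConfig
    outdir: Path
    consensus_peaks: list[GenomicInterval]
    truth: syn.SyntheticTruth
    contrasts: dict[str, ContrastResult]
    key_tf_table: pd.DataFrame
    peak_gene: dict[str, str]


def _child_seed(seed: int, label: str) -> np.random.SeedSequence:
    digest = hashlib.sha256(label.encode()).digest()[:4]
    return np.random.SeedSequence([seed, int.from_bytes(digest, "big")])


def _seed_int(seed: int, label: str) -> int:
    return int(_child_seed(seed, label).generate_state(1)[0] % (2**31))


CONTRASTS = {
    "gmcsf": ("pos", "neg"),
    "memory": ("mem", "naive"),
}


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunResult:
    """Run the full synthetic pipeline and write all stage outputs.

    Stages: replicate peak generation -> per-sample consensus ->
    cross-sample consensus -> read placement and counting -> donor-paired
    differential (ATAC and RNA, per contrast) -> signed-significance
    ranking -> footprint generation and FOS filtering -> motif scanning ->
    rank-permutation TF enrichment -> source/target selection -> network
    assembly -> inverted PageRank -> cross-network key-TF comparison.
    """
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    def _write_df(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index)
        written[name] = _sha256(path)

    def _fail(stage: str, exc: Exception) -> RuntimeError:
        return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")

    # --- stage 1: synthetic peak calls and consensus ----------------------
    logger.info("stage consensus: generating replicate peaks and consensus set")
    conditions = [c for pair in CONTRASTS.values() for c in pair]
    n_samples = len(conditions) * cfg.n_donors
    try:
        sample_sets, truth = syn.generate_replicate_peaks(
            cfg.n_regions,
            cfg.n_replicates,
            n_samples,
            jitter_sd=cfg.jitter_sd,
            dropout_rate=cfg.dropout_rate,
            seed=_seed_int(cfg.seed, "peaks"),
        )
        sample_names = [
            f"{cond}_d{d + 1}" for cond in conditions for d in range(cfg.n_donors)
        ]
        sample_regions = [
            cns.replicate_consensus(reps, cfg.min_replicates, cfg.min_reciprocal)
            for reps in sample_sets
        ]
        peaks = cns.cross_sample_consensus(
            sample_regions, cfg.min_samples, cfg.merge_distance
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise _fail("consensus", exc) from exc
    write_bed(peaks, outdir / "consensus_peaks.bed")
    written["consensus_peaks.bed"] = _sha256(outdir / "consensus_peaks.bed")
    peak_ids = [p.name for p in peaks]
    peak_by_id = {p.name: p for p in peaks}

    # --- stage 2: ATAC counts via read placement --------------------------
    logger.info("stage counting: placing and counting reads for %d samples", n_samples)
    # map each consensus peak to the truth region it recovers (for planting)
    atac_counts: dict[str, pd.DataFrame] = {}
    diff_peaks: dict[str, list[str]] = {}
    rng_split = np.random.default_rng(_child_seed(cfg.seed, "split"))
    shuffled = list(peak_ids)
    rng_split.shuffle(shuffled)
    n_diff = int(round(cfg.diff_fraction * len(peak_ids)))
    diff_peaks["gmcsf"] = sorted(shuffled[:n_diff])
    diff_peaks["memory"] = sorted(shuffled[n_diff : 2 * n_diff])

    contrasts: dict[str, ContrastResult] = {}
    atac_truth: dict[str, syn.SyntheticTruth] = {}
    for contrast, (g1, g2) in CONTRASTS.items():
        counts_true, t = syn.generate_counts(
            peak_ids,
            n_donors=cfg.n_donors,
            groups=(g1, g2),
            diff_fraction=cfg.diff_fraction,
            effect_log2fc=cfg.effect_log2fc,
            dispersion=cfg.dispersion,
            donor_sigma=cfg.donor_sigma,
            seed=_seed_int(cfg.seed, f"atac:{contrast}"),
            diff_features=diff_peaks[contrast],
        )
        atac_truth[contrast] = t
        reads = syn.reads_from_counts(
            counts_true,
            peak_by_id,
            read_length=cfg.read_length,
            seed=_seed_int(cfg.seed, f"reads:{contrast}"),
            background_reads=cfg.background_reads,
        )
        counted = cns.count_reads(reads, peaks, cfg.min_read_overlap)
        atac_counts[contrast] = counted
        _write_df(counted, f"atac_counts_{contrast}.tsv")

    # --- stage 3: differential + ranking ----------------------------------
    logger.info("stage differential: paired tests and signed-significance ranking")
    gene_of_peak = {pid: f"gene{idx + 1:04d}" for idx, pid in enumerate(peak_ids)}
    tf_names = [f"TF{i + 1:02d}" for i in range(cfg.n_tfs)]

    rna_tables: dict[str, pd.DataFrame] = {}
    expressed_union: set[str] = set()
    for contrast, (g1, g2) in CONTRASTS.items():
        counted = atac_counts[contrast]
        groups = {c: c.rsplit("_", 1)[0] for c in counted.columns}
        donors = {c: c.rsplit("_", 1)[1] for c in counted.columns}
        atac_table = diff.paired_nb_test(counted, groups, donors)
        atac_table = diff.call_differential(
            atac_table, cfg.fdr_cutoff, cfg.fc_up, cfg.fc_down
        )
        ranked = diff.rank_features(atac_table)
        dar = set(atac_table.index[atac_table["significant"]])

        # RNA: genes concordant with a fraction of the planted DARs + TF genes
        rng_rna = np.random.default_rng(_child_seed(cfg.seed, f"rna-pick:{contrast}"))
        planted_dirs = {
            gene_of_peak[p]: d
            for p, (d, _) in atac_truth[contrast].true_differential.items()
        }
        genes = sorted(planted_dirs)
        k = int(round(cfg.rna_concordance * len(genes)))
        chosen = sorted(rng_rna.choice(len(genes), size=k, replace=False))
        deg_plan = {genes[i]: planted_dirs[genes[i]] for i in chosen}
        all_genes = [gene_of_peak[p] for p in peak_ids] + tf_names
        rna_counts, _ = syn.generate_counts(
            all_genes,
            n_donors=cfg.n_donors,
            groups=(g1, g2),
            effect_log2fc=cfg.effect_log2fc,
            dispersion=cfg.dispersion,
            donor_sigma=cfg.donor_sigma,
            seed=_seed_int(cfg.seed, f"rna:{contrast}"),
            diff_features=sorted(deg_plan),
            directions=deg_plan,
        )
        rna_table = diff.paired_nb_test(
            rna_counts,
            {c: c.rsplit("_", 1)[0] for c in rna_counts.columns},
            {c: c.rsplit("_", 1)[1] for c in rna_counts.columns},
        )
        rna_table = diff.call_differential(
            rna_table, cfg.fdr_cutoff, cfg.fc_up, cfg.fc_down
        )
        expressed = set(
            diff.filter_expressed(rna_counts, cfg.min_cpm, cfg.min_cpm_samples)
        )
        expressed_union |= expressed
        deg = set(rna_table.index[rna_table["significant"]])
        rna_tables[contrast] = rna_table

        _write_df(atac_table, f"differential_atac_{contrast}.tsv")
        _write_df(rna_table, f"differential_rna_{contrast}.tsv")
        _write_df(ranked.to_frame(), f"ranked_peaks_{contrast}.tsv")
        contrasts[contrast] = ContrastResult(
            name=contrast,
            atac_table=atac_table,
            rna_table=rna_table,
            ranked_peaks=ranked,
            dar_peaks=dar,
            deg_genes=deg,
            enrichment=pd.DataFrame(),
            sources=set(),
            network=net.RegulatoryNetwork(graph=nx.DiGraph()),
        )

    # --- stage 4: footprints, sequences, motif planting -------------------
    logger.info("stage footprints: planting motifs and filtering by FOS")
    pwms = syn.random_pwm_library(
        cfg.n_tfs, width=cfg.pwm_width, seed=_seed_int(cfg.seed, "pwms")
    )
    hub, shared_a, shared_b, b_only = (
        tf_names[0],
        tf_names[1],
        tf_names[2],
        tf_names[3],
    )
    block_n = max(1, int(np.ceil(cfg.top_fraction * len(peak_ids))))

    def _top_block(contrast: str) -> list[str]:
        return list(contrasts[contrast].ranked_peaks.index[:block_n])

    rng_plant = np.random.default_rng(_child_seed(cfg.seed, "plant"))

    def _pick(block: list[str], frac: float) -> list[str]:
        k = int(round(frac * len(block)))
        idx = sorted(rng_plant.choice(len(block), size=k, replace=False))
        return [block[i] for i in idx]

    block_a, block_b = _top_block("gmcsf"), _top_block("memory")
    assignments = {
        hub: _pick(block_a, cfg.hub_fraction),
        shared_a: _pick(block_a, cfg.shared_fraction),
        shared_b: _pick(block_b, cfg.shared_fraction),
        b_only: _pick(block_b, cfg.hub_fraction),
    }
    # the shared TFs bind in both contrasts' top peaks
    assignments[shared_a] = sorted(
        set(assignments[shared_a]) | set(_pick(block_b, cfg.shared_fraction))
    )
    assignments[shared_b] = sorted(
        set(assignments[shared_b]) | set(_pick(block_a, cfg.shared_fraction))
    )

    ranked_pairs = [
        (pid, peak_by_id[pid]) for pid in contrasts["gmcsf"].ranked_peaks.index
    ]
    fp_table, peak_seqs, fp_truth = syn.generate_footprints_and_sequences(
        ranked_pairs,
        pwms,
        fos_gamma=(cfg.fos_shape, cfg.fos_scale),
        footprints_per_peak=cfg.footprints_per_peak,
        footprint_width=cfg.footprint_width,
        seed=_seed_int(cfg.seed, "footprints"),
        planted_assignments=assignments,
    )
    truth.planted_sites = fp_truth.planted_sites
    truth.hub_tf = hub
    truth.planted_tfs = {
        tf: ("top", cfg.hub_fraction if tf in (hub, b_only) else cfg.shared_fraction)
        for tf in assignments
    }
    for contrast in CONTRASTS:
        truth.true_differential.update(atac_truth[contrast].true_differential)
    truth.true_consensus = list(peaks)

    fps.write_footprints(fp_table, outdir / "footprints.tsv")
    written["footprints.tsv"] = _sha256(outdir / "footprints.tsv")
    syn.write_fasta(peak_seqs, outdir / "peak_sequences.fa")
    written["peak_sequences.fa"] = _sha256(outdir / "peak_sequences.fa")
    (outdir / "pwms.transfac").write_text(mot.write_transfac(pwms))
    written["pwms.transfac"] = _sha256(outdir / "pwms.transfac")

    retained = fps.filter_footprints(fp_table)
    _write_df(retained, "footprints_retained.tsv", index=False)

    # --- stage 5: motif scanning ------------------------------------------
    logger.info("stage motifs: scanning %d retained footprints", len(retained))
    fp_seqs = syn.footprint_sequences(retained, peak_seqs, peak_by_id)
    fp_peak = dict(zip(retained["footprint"], retained["peak"]))
    hits = mot.scan_footprints(pwms, fp_seqs, fp_peak, cfg.rel_threshold)
    _write_df(hits, "motif_hits.tsv", index=False)
    sets = mot.tf_peak_sets(hits)

    # --- stage 6: enrichment, networks ------------------------------------
    logger.info("stage network: enrichment, source/target selection, PageRank")
    networks: dict[str, net.RegulatoryNetwork] = {}
    for contrast in CONTRASTS:
        cres = contrasts[contrast]
        usable = {
            tf: s
            for tf, s in sets.items()
            if 0 < len(s & set(cres.ranked_peaks.index)) < len(cres.ranked_peaks)
        }
        if not usable:
            raise _fail("enrichment", ValueError("no TF set overlaps the ranked peaks"))
        enrich = enr.tf_enrichment(
            cres.ranked_peaks,
            usable,
            n_perm=cfg.n_perm,
            seed=_seed_int(cfg.seed, f"enrich:{contrast}"),
            weight=cfg.weight,
            fdr_cutoff=cfg.fdr_cutoff,
        )
        cres.enrichment = enrich
        _write_df(enrich, f"tf_enrichment_{contrast}.tsv")
        sources = net.select_sources(enrich, expressed_union, cfg.fdr_cutoff)
        cres.sources = sources
        edges = net.select_targets(
            gene_of_peak, cres.dar_peaks, cres.deg_genes, hits, sources
        )
        network = net.build_network(edges)
        if network.graph.number_of_nodes() > 0:
            net.inverted_pagerank(network, cfg.damping, cfg.pagerank_tol)
        cres.network = network
        networks[contrast] = network
        _write_df(edges, f"network_edges_{contrast}.tsv", index=False)
        pr = pd.DataFrame(
            sorted((network.pagerank or {}).items()), columns=["node", "pagerank"]
        )
        _write_df(pr, f"pagerank_{contrast}.tsv", index=False)

    key = net.key_tfs(
        networks["gmcsf"], networks["memory"], cfg.percentile, labels=("gmcsf", "memory")
    )
    _write_df(key, "key_tfs.tsv")

    # --- manifest ----------------------------------------------------------
    cfg_path = outdir / "config.yaml"
    cfg.to_yaml(cfg_path)
    written["config.yaml"] = _sha256(cfg_path)
    manifest = {
        "package": "atacgrn",
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "stages": [
            "consensus", "counting", "differential", "footprints",
            "motifs", "enrichment", "network",
        ],
        "outputs": dict(sorted(written.items())),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return RunResult(
        config=cfg,
        outdir=outdir,
        consensus_peaks=peaks,
        truth=truth,
        contrasts=contrasts,
        key_tf_table=key,
        peak_gene=gene_of_peak,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
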