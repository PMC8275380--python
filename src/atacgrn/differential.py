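"""Differential accessibility/expression calls, signed-significance ranking,
a donor-paired count test for synthetic data, and RNA/ATAC direction agreement.

Differential statistics tables are plain pandas DataFrames with the columns
``feature`` (or the index), ``log2FC``, ``PValue`` and ``FDR``; real-data
users supply tables produced by their own differential pipeline (e.g. an
edgeR GLM), and the calls here only apply thresholds and ranking on top.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_fdr

#: floor applied to significance values before log10, to avoid infinities
SIGNIFICANCE_FLOOR = 1e-300

REQUIRED_COLUMNS = ("log2FC", "PValue", "FDR")


def _as_table(records: pd.DataFrame) -> pd.DataFrame:
    df = records.copy()
    if "feature" in df.columns:
        df = df.set_index("feature")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"differential table missing columns: {missing}")
    return df


def filter_expressed(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 3
) -> pd.Index:
    """Detection filter: keep features with more than ``min_cpm`` counts per
    million in at least ``min_samples`` samples.

    CPM is computed against each sample's total library size. The
    comparison is strict (> min_cpm), matching the usual "more than 1 CPM"
    phrasing.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size in samples: {bad}")
    cpm = counts / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return counts.index[keep]


def call_differential(
    records: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    fc_up: float = 1.25,
    fc_down: float = 0.75,
) -> pd.DataFrame:
    """Flag DARs/DEGs: FDR below cutoff and fold change outside [fc_down, fc_up].

    The fold-change window is inclusive at both bounds (a 1.25-fold change
    qualifies); significance additionally requires FDR strictly below the
    cutoff.
    """
    df = _as_table(records)
    if df["FDR"].isna().any():
        raise ValueError("missing FDR values")
    fc = np.exp2(df["log2FC"].to_numpy(dtype=float))
    sig = (df["FDR"].to_numpy(dtype=float) < fdr_cutoff) & (
        (fc >= fc_up) | (fc <= fc_down)
    )
    df = df.copy()
    df["significant"] = sig
    return df


def rank_features(
    records: pd.DataFrame, significance_field: str = "FDR"
) -> pd.Series:
    """Signed-significance ranking: score = -log10(significance) * sign(log2FC).

    Returns scores indexed by feature, sorted descending; ties are broken
    by feature identifier so the order is deterministic. ``significance_field``
    selects FDR (default) or PValue as the significance measure.
    """
    df = _as_table(records)
    field = {"fdr": "FDR", "pvalue": "PValue"}.get(
        significance_field.lower(), significance_field
    )
    if field not in df.columns:
        raise ValueError(f"unknown significance field {significance_field!r}")
    sig = np.clip(df[field].to_numpy(dtype=float), SIGNIFICANCE_FLOOR, None)
    score = -np.log10(sig) * np.sign(df["log2FC"].to_numpy(dtype=float))
    out = pd.Series(score, index=df.index, name="score")
    order = sorted(out.index, key=lambda f: (-out[f], str(f)))
    return out.loc[order]


def paired_nb_test(
    counts: pd.DataFrame,
    groups: Mapping[str, str] | Sequence[str],
    donors: Mapping[str, str] | Sequence[str],
) -> pd.DataFrame:
    """Donor-paired differential test on overdispersed count data.

    For each feature the per-donor log2 ratio of library-size-normalized
    counts (offset 0.5) between the two groups is computed, and a one-sample
    t-test across donors is applied. The empirical per-feature variance of
    the paired log ratios absorbs negative-binomial overdispersion as well
    as donor-level nuisance variation, which cancels within pairs.
    Benjamini-Hochberg FDR is attached.

    Every donor must contribute exactly one sample per group.
    """
    samples = list(counts.columns)
    if not isinstance(groups, Mapping):
        groups = dict(zip(samples, groups))
    if not isinstance(donors, Mapping):
        donors = dict(zip(samples, donors))
    levels = sorted(set(groups.values()))
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    g1, g2 = levels
    pairs: dict[str, dict[str, str]] = {}
    for s in samples:
        pairs.setdefault(donors[s], {})[groups[s]] = s
    for d, by_group in sorted(pairs.items()):
        if set(by_group) != {g1, g2}:
            raise ValueError(f"donor {d!r} lacks one sample per group (unpaired design)")
    if len(pairs) < 2:
        raise ValueError("paired test requires at least 2 donors")

    lib = counts.sum(axis=0).astype(float)
    donors_sorted = sorted(pairs)
    x = np.stack(
        [counts[pairs[d][g1]].to_numpy(dtype=float) for d in donors_sorted], axis=1
    )
    y = np.stack(
        [counts[pairs[d][g2]].to_numpy(dtype=float) for d in donors_sorted], axis=1
    )
    lx = np.array([lib[pairs[d][g1]] for d in donors_sorted])
    ly = np.array([lib[pairs[d][g2]] for d in donors_sorted])
    r = np.log2((x + 0.5) / lx) - np.log2((y + 0.5) / ly)

    n = r.shape[1]
    mean = r.mean(axis=1)
    sd = r.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(sd == 0, np.where(mean == 0, 1.0, SIGNIFICANCE_FLOOR), p)
    out = pd.DataFrame(
        {"log2FC": mean, "PValue": p, "FDR": bh_fdr(p)},
        index=counts.index.rename("feature"),
    )
    return out


def direction_agreement(
    rna: pd.DataFrame,
    atac: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    n_mc: int = 10_000,
    seed: int = 0,
    feature_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Test whether RNA and ATAC changes agree in direction more than chance.

    Features significant (FDR < cutoff) in *both* tables form a 2x2 table of
    up/down calls. ``feature_map`` optionally translates ATAC features
    (peaks) to RNA features (genes); when several peaks map to one gene the
    peak with the smallest FDR represents it. The p-value is the upper-tail
    Monte Carlo probability of at least the observed concordant count under
    ``n_mc`` random reshuffles of one table's directions (plus-one corrected).
    """
    rna_t = _as_table(rna)
    atac_t = _as_table(atac)
    if feature_map is not None:
        atac_t = atac_t.copy()
        atac_t["gene"] = [feature_map.get(f) for f in atac_t.index]
        atac_t = atac_t.dropna(subset=["gene"])
        atac_t = (
            atac_t.sort_values("FDR", kind="stable")
            .groupby("gene", sort=True)
            .first()
        )
    common = rna_t.index.intersection(atac_t.index)
    joint = common[
        (rna_t.loc[common, "FDR"] < fdr_cutoff)
        & (atac_t.loc[common, "FDR"] < fdr_cutoff)
    ]
    joint = pd.Index(sorted(joint))
    if len(joint) < 2:
        raise ValueError(
            f"only {len(joint)} feature(s) significant in both tables; "
            "direction agreement is undefined"
        )
    r_up = rna_t.loc[joint, "log2FC"].to_numpy() > 0
    a_up = atac_t.loc[joint, "log2FC"].to_numpy() > 0
    table = pd.DataFrame(
        [
            [int(np.sum(a_up & r_up)), int(np.sum(a_up & ~r_up))],
            [int(np.sum(~a_up & r_up)), int(np.sum(~a_up & ~r_up))],
        ],
        index=pd.Index(["atac_up", "atac_down"]),
        columns=pd.Index(["rna_up", "rna_down"]),
    )
    observed = int(np.sum(a_up == r_up))
    rng = np.random.default_rng(seed)
    n = len(joint)
    perms = np.argsort(rng.random((n_mc, n)), axis=1)
    sim = (a_up[perms] == r_up[None, :]).sum(axis=1)
    p = (1 + int(np.sum(sim >= observed))) / (n_mc + 1)
    return table, p
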