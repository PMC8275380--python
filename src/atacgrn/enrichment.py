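"""Rank-based permutation enrichment of feature sets in ranked lists.

The enrichment statistic is the weighted Kolmogorov-Smirnov running sum of
gene set enrichment analysis: walking down the ranked list, membership hits
increment the sum proportionally to |score|^weight and misses decrement it
uniformly; the enrichment score (ES) is the extremum of the walk. The null
is built by drawing random member sets of the same size from the ranked
list, the p-value compares |ES| with same-sign null extrema (plus-one
corrected), and the normalized ES (NES) divides by the mean magnitude of
same-sign null extrema. The same machinery applies to TF motif-bearing
peak sets in ranked peak lists and to gene sets (GMT) in ranked gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    pvalue: float
    set_size: int
    fdr: float = float("nan")


def _steps(scores: np.ndarray, mask: np.ndarray, weight: float) -> np.ndarray:
    n = scores.size
    m = int(mask.sum())
    w = np.abs(scores[mask]) ** weight
    total = w.sum()
    steps = np.full(n, -1.0 / (n - m))
    if total > 0:
        steps[mask] = w / total
    else:  # all member scores zero: fall back to uniform hit increments
        steps[mask] = 1.0 / m
    return steps


def enrichment_score(
    ranked: pd.Series, members, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES of a member set in a ranked list (scores sorted descending).

    Returns the signed extremum of the running sum together with the full
    running sum. ES lies in [-1, 1]; a positive ES means enrichment toward
    the top of the list.
    """
    scores = ranked.to_numpy(dtype=float)
    mask = ranked.index.isin(set(members)).astype(bool)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("member set is empty after intersection with the ranked list")
    if m == len(ranked):
        raise ValueError("member set covers the whole ranked list")
    running = np.cumsum(_steps(scores, mask, weight))
    es = float(np.clip(running[np.argmax(np.abs(running))], -1.0, 1.0))
    return es, running


def _null_es(
    scores: np.ndarray, set_size: int, n_perm: int, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random member sets of the given size (vectorized)."""
    n = scores.size
    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :set_size]
    absw = np.abs(scores) ** weight
    w_sel = absw[idx]
    totals = w_sel.sum(axis=1)
    steps = np.full((n_perm, n), -1.0 / (n - set_size))
    hit_steps = np.where(
        totals[:, None] > 0, w_sel / np.where(totals[:, None] > 0, totals[:, None], 1.0),
        1.0 / set_size,
    )
    np.put_along_axis(steps, idx, hit_steps, axis=1)
    running = np.cumsum(steps, axis=1)
    pos = np.argmax(np.abs(running), axis=1)
    return running[np.arange(n_perm), pos]


def permutation_test(
    ranked: pd.Series,
    members,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    weight: float = 1.0,
) -> EnrichmentResult:
    """Permutation p-value and NES for one member set.

    The null draws ``n_perm`` random sets of the same size from the ranked
    list. With observed ES of sign s, p = (1 + #{null ES of sign s at least
    as extreme}) / (1 + #{null ES of sign s}), the one-sided convention of
    GSEA, which is uniform under the null; NES = ES / mean |null ES of sign s|.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    es, _ = enrichment_score(ranked, members, weight=weight)
    scores = ranked.to_numpy(dtype=float)
    m = int(ranked.index.isin(set(members)).sum())
    null = _null_es(scores, m, n_perm, weight, rng)
    if np.all(null == 0):
        raise ValueError("degenerate null: all permutation enrichment scores are 0")
    if es >= 0:
        same = null[null >= 0]
        extreme = int(np.sum(same >= es)) if es > 0 else same.size
    else:
        same = null[null < 0]
        extreme = int(np.sum(same <= es))
    p = (1 + extreme) / (1 + same.size) if same.size else 1.0
    denom = float(np.mean(np.abs(same))) if same.size else float(np.mean(np.abs(null)))
    nes = es / denom if denom > 0 else 0.0
    return EnrichmentResult(set_id="", es=es, nes=nes, pvalue=p, set_size=m)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tf_enrichment(
    ranked: pd.Series,
    tf_sets: Mapping[str, set],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Enrichment of every TF's motif-bearing peak set in a ranked peak list.

    One row per TF with ES, NES, permutation p, BH FDR and a ``selected``
    flag (FDR < cutoff). Sets are intersected with the ranked features
    first; a set that is empty (or total) after intersection is an error.
    The same function serves gene-set enrichment by passing a ranked gene
    list and GMT-derived sets. Deterministic given ``seed``: each set gets
    an independent child generator in sorted set-name order.
    """
    if not tf_sets:
        raise ValueError("empty set map")
    names = sorted(tf_sets)
    children = np.random.SeedSequence(seed).spawn(len(names))
    rows = []
    for name, child in zip(names, children):
        rng = np.random.default_rng(child)
        res = permutation_test(ranked, tf_sets[name], n_perm=n_perm, seed=rng, weight=weight)
        rows.append((name, res.set_size, res.es, res.nes, res.pvalue))
    df = pd.DataFrame(rows, columns=["set_id", "set_size", "es", "nes", "pvalue"])
    df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
    df["selected"] = df["fdr"] < fdr_cutoff
    return df.set_index("set_id")


def binomial_concordance(k_agree: int, n: int) -> float:
    """Upper-tail probability of >= k_agree agreements in n fair coin flips.

    P(X >= k), X ~ Binomial(n, 1/2), computed by stable summation. Used to
    ask how likely an observed direction concordance between two datasets
    is by chance.
    """
    if not 0 <= k_agree <= n:
        raise ValueError(f"k_agree must be in [0, {n}], got {k_agree}")
    from scipy.stats import binom

    if k_agree == 0:
        return 1.0
    return float(binom.sf(k_agree - 1, n, 0.5))


# ---------------------------------------------------------------------------
# GMT set files
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            sets[fields[0]] = {f for f in fields[2:] if f}
    return sets


def write_gmt(sets: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t.\t{members}\n")
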