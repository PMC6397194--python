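"""Per-sample immune cell infiltration calls from metagene enrichment.

Each sample's genes are ranked by their cohort z-score and a weighted
Kolmogorov–Smirnov running-sum enrichment score (the single-sample GSEA
convention) is computed for every cell-type metagene set: hits add
|z|^α normalized by the total hit weight, misses subtract 1/(N − N_hits),
and the score is the signed maximum deviation from zero.  Significance
comes from a random-gene-set permutation null (sample-label permutation
is impossible in a single-sample statistic), p-values are converted to
Storey q-values, and a cell type is called infiltrating when q ≤ 0.10.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort_io import ExpressionMatrix, GeneSetCollection, compute_zscores
from .stats_core import pearson, storey_q

__all__ = [
    "enrichment_score",
    "permutation_p",
    "call_infiltration",
    "coinfiltration_matrix",
]


def _ranked_weights(z: pd.Series, alpha: float) -> tuple[pd.Index, np.ndarray]:
    """Genes ordered by descending z with their |z|^alpha weights."""
    if z.index.has_duplicates:
        raise ValueError("duplicate genes in ranking")
    ordered = z.sort_values(ascending=False, kind="mergesort")
    weights = np.abs(ordered.to_numpy()) ** alpha
    return ordered.index, weights


def _es_from_hits(weights: np.ndarray, hit_mask: np.ndarray) -> float:
    n = weights.size
    n_hits = int(hit_mask.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit weights zero (e.g. z = 0 everywhere in the set): spread evenly
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    peak = np.argmax(np.abs(running))
    return float(running[peak])


def enrichment_score(z: pd.Series, gene_set, alpha: float = 1.0) -> float:
    """Weighted KS running-sum enrichment score of a gene set.

    ``z`` maps gene → per-sample cohort z-score; genes are ranked by
    descending z and hits weighted by |z|^alpha (alpha = 0 gives the
    rank-only statistic).  Returns the signed maximum deviation, in
    [−1, 1].

    Raises
    ------
    ValueError
        If no gene of the set is present in the ranking.
    """
    members = {g for g in gene_set}
    present = members & set(z.index)
    if not present:
        raise ValueError("gene set has zero overlap with the expression ranking")
    order, weights = _ranked_weights(z, alpha)
    hit_mask = np.asarray(order.isin(present))
    return _es_from_hits(weights, hit_mask)


def _null_es(
    weights: np.ndarray, set_size: int, B: int, rng: np.random.Generator
) -> np.ndarray:
    """ES of B random gene sets of the given size over a fixed ranking."""
    n = weights.size
    if set_size >= n:
        raise ValueError("set size must be smaller than the number of ranked genes")
    hit = np.zeros((B, n), dtype=bool)
    for b in range(B):
        hit[b, rng.choice(n, size=set_size, replace=False)] = True
    hit_w = np.where(hit, weights[None, :], 0.0)
    totals = hit_w.sum(axis=1)
    zero = totals == 0
    if zero.any():
        hit_w[zero] = hit[zero].astype(float)
        totals[zero] = set_size
    steps = hit_w / totals[:, None] - (~hit) / (n - set_size)
    running = np.cumsum(steps, axis=1)
    peaks = np.argmax(np.abs(running), axis=1)
    return running[np.arange(B), peaks]


def permutation_p(
    es_observed: float,
    z: pd.Series,
    set_size: int,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
    alpha: float = 1.0,
) -> float:
    """One-sided permutation p-value from a random-gene-set null.

    p = (1 + #{null ES ≥ observed ES}) / (B + 1); reproducible under a
    fixed seed/generator.
    """
    if B < 100:
        raise ValueError("permutation null requires B >= 100")
    rng = np.random.default_rng(rng)
    _, weights = _ranked_weights(z, alpha)
    null = _null_es(weights, set_size, B, rng)
    return float((1 + np.sum(null >= es_observed)) / (B + 1))


def call_infiltration(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    q_cut: float = 0.10,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 1.0,
    q_batch: str = "per_sample",
) -> pd.DataFrame:
    """Call infiltration for every sample × cell type.

    Returns a long-format frame with columns ``sample_id``,
    ``cell_type``, ``es``, ``p``, ``q``, ``infiltrated``.  Permutation
    nulls are shared across cell types of equal set size within a
    sample; q-values are Storey-adjusted across cell types within each
    sample (``q_batch="per_sample"``, the default) or across all
    sample × cell-type tests (``"global"``).
    """
    if q_batch not in {"per_sample", "global"}:
        raise ValueError(f"unknown q_batch {q_batch!r}")
    if matrix.values.shape[1] < 2:
        raise ValueError("infiltration calling requires at least 2 samples")
    matrix = matrix if matrix.zscores is not None else compute_zscores(matrix)
    rng = np.random.default_rng(seed)
    gene_index = set(matrix.values.index)
    overlaps = {}
    for name in sets.names():
        present = set(sets[name]) & gene_index
        if not present:
            raise ValueError(f"gene set {name!r} has zero overlap with the expression matrix")
        overlaps[name] = present

    rows = []
    for sample in matrix.samples:
        z = matrix.zscores[sample]
        order, weights = _ranked_weights(z, alpha)
        null_cache: dict[int, np.ndarray] = {}
        for name in sets.names():
            present = overlaps[name]
            hit_mask = np.asarray(order.isin(present))
            es = _es_from_hits(weights, hit_mask)
            size = len(present)
            if size not in null_cache:
                null_cache[size] = _null_es(weights, size, B, rng)
            null = null_cache[size]
            p = float((1 + np.sum(null >= es)) / (B + 1))
            rows.append({"sample_id": sample, "cell_type": name, "es": es, "p": p})
    calls = pd.DataFrame(rows)
    if q_batch == "per_sample":
        calls["q"] = calls.groupby("sample_id", sort=False)["p"].transform(
            lambda p: storey_q(p.to_numpy())
        )
    else:
        calls["q"] = storey_q(calls["p"].to_numpy())
    calls["infiltrated"] = calls["q"] <= q_cut
    return calls


def coinfiltration_matrix(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation of binary infiltration indicators.

    Pearson correlation of the 0/1 indicators (the phi coefficient) for
    every cell-type pair, with t-based p-values.  Pairs involving a
    constant indicator column are reported as missing.
    """
    wide = calls.pivot(index="sample_id", columns="cell_type", values="infiltrated").astype(float)
    if wide.shape[1] < 2 or wide.shape[0] < 3:
        raise ValueError("co-infiltration needs >= 2 cell types and >= 3 samples")
    types = list(wide.columns)
    r = pd.DataFrame(np.eye(len(types)), index=types, columns=types)
    p = pd.DataFrame(np.full((len(types), len(types)), np.nan), index=types, columns=types)
    for i, a in enumerate(types):
        for j in range(i + 1, len(types)):
            b = types[j]
            try:
                res = pearson(wide[a], wide[b])
                r.loc[a, b] = r.loc[b, a] = res.statistic
                p.loc[a, b] = p.loc[b, a] = res.p
            except ValueError:
                r.loc[a, b] = r.loc[b, a] = np.nan
    return r, p
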