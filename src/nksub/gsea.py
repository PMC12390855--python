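"""Preranked gene-set enrichment analysis, implemented from scratch.

The enrichment score (ES) is the signed maximal deviation from zero of a
weighted Kolmogorov-Smirnov-like running sum: walking the ranked list, hit
genes add |score|^p / sum_hits |score|^p and misses subtract 1/(N - N_hits).
The null distribution comes from gene-label permutations — set membership is
reassigned uniformly at random among the ranked genes, preserving set size —
because the input is a precomputed ranked list, from which per-sample
phenotype shuffling cannot be reconstructed. NES divides ES by the mean
|null ES| of the same sign; the nominal p is the same-sign null tail
fraction; the FDR q compares the pooled null NES distribution with the
observed NES distribution, clipped to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexp import RankedList
from .matrix_io import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = ["EnrichmentScore", "enrichment_score", "gsea_preranked"]


@dataclass
class EnrichmentScore:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]


def enrichment_score(
    ranked: RankedList, gene_set, weight_p: float = 1.0
) -> EnrichmentScore:
    """Weighted running-sum enrichment score of a gene set in a ranked list.

    Requires a non-trivial overlap: at least one hit and at least one miss.
    If every hit score is zero (possible with weight_p >= 1), hits add
    1/N_hits each — the unweighted degenerate rule. ES is the running-sum
    value of maximal absolute deviation (earliest position on ties); the
    leading edge contains the hit genes at or before the extremum for
    positive ES, and strictly after it for negative ES.
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                      count=len(ranked))
    n = len(ranked)
    n_hits = int(hit.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the entire ranked universe")
    w = np.abs(ranked.scores) ** weight_p
    hit_w = w[hit]
    total = hit_w.sum()
    inc = np.empty(n)
    if total == 0:
        inc[hit] = 1.0 / n_hits
    else:
        inc[hit] = hit_w / total
    inc[~hit] = -1.0 / (n - n_hits)
    running = np.cumsum(inc)
    idx = int(np.argmax(np.abs(running)))
    es = float(running[idx])
    hit_pos = np.flatnonzero(hit)
    if es > 0:
        le = hit_pos[hit_pos <= idx]
    elif es < 0:
        le = hit_pos[hit_pos > idx]
    else:
        le = np.array([], dtype=int)
    return EnrichmentScore(es=es, running_sum=running,
                           leading_edge=[ranked.genes[i] for i in le])


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorized ES for many hit-position sets at once.

    ``positions``: (n_sets, m) arrays of 0-based ranked-list positions (need
    not be sorted); ``weights``: |score|^p over the whole ranked list. The
    running sum attains its extrema only immediately before or at hit
    positions, so only those 2m candidates per set are evaluated, in list
    order so ties resolve to the earliest position as in
    :func:`enrichment_score`.
    """
    positions = np.sort(positions, axis=1)
    m = positions.shape[1]
    w = weights[positions]
    totals = w.sum(axis=1, keepdims=True)
    frac = np.where(totals > 0, w / np.where(totals > 0, totals, 1.0), 1.0 / m)
    H = np.cumsum(frac, axis=1)
    i = np.arange(1, m + 1)
    miss = 1.0 / (n - m)
    at_hit = H - (positions + 1 - i) * miss
    before_hit = (H - frac) - (positions - (i - 1)) * miss
    cand = np.empty((positions.shape[0], 2 * m))
    cand[:, 0::2] = before_hit
    cand[:, 1::2] = at_hit
    best = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(cand.shape[0]), best]


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 15,
    max_size: int = 500,
    weight_p: float = 1.0,
) -> pd.DataFrame:
    """Score every gene set in ``collection`` against ``ranked``.

    Sets whose intersection with the ranked universe falls outside
    [min_size, max_size] are skipped with a log line. Returns one row per
    surviving set (sorted by NES, descending) with columns set, size, es,
    nes, p, q, leading_edge. Deterministic for a fixed seed.
    """
    n = len(ranked)
    if n < 2 * min_size:
        raise ValueError(
            f"ranked list has {n} genes; need at least {2 * min_size}"
        )
    if n_perm < 100:
        log.warning("n_perm=%d is low; FDR estimates will be unstable", n_perm)
    universe = set(ranked.genes)
    surviving = []
    for gs in collection:
        size = len(set(gs.genes) & universe)
        if size < min_size or size > max_size or size == n:
            log.info("skipping %s (size %d outside [%d, %d])",
                     gs.name, size, min_size, max_size)
            continue
        surviving.append((gs, size))
    if not surviving:
        raise ValueError("no gene set survives size filtering")

    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.scores) ** weight_p
    rows = []
    null_nes_pool = []
    for gs, size in surviving:
        obs = enrichment_score(ranked, gs.genes, weight_p=weight_p)
        perm_pos = np.empty((n_perm, size), dtype=int)
        for i in range(n_perm):
            perm_pos[i] = rng.choice(n, size=size, replace=False)
        null_es = _es_from_positions(perm_pos, weights, n)

        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.abs(null_es).mean()
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.abs(null_es).mean()
        if obs.es > 0:
            nes = obs.es / mean_pos if mean_pos > 0 else 0.0
            p = (pos_null >= obs.es).sum() / pos_null.size if pos_null.size else 0.0
        elif obs.es < 0:
            nes = obs.es / mean_neg if mean_neg > 0 else 0.0
            p = (neg_null <= obs.es).sum() / neg_null.size if neg_null.size else 0.0
        else:
            nes, p = 0.0, 1.0
        null_nes = np.where(
            null_es > 0,
            null_es / (mean_pos if mean_pos > 0 else 1.0),
            null_es / (mean_neg if mean_neg > 0 else 1.0),
        )
        null_nes_pool.append(null_nes)
        rows.append({"set": gs.name, "size": size, "es": obs.es, "nes": nes,
                     "p": p, "leading_edge": ",".join(obs.leading_edge)})

    pooled = np.concatenate(null_nes_pool)
    obs_nes = np.array([r["nes"] for r in rows])
    qs = []
    for nes_star in obs_nes:
        if nes_star > 0:
            num = (pooled >= nes_star).mean()
            den = (obs_nes >= nes_star).mean()
        elif nes_star < 0:
            num = (pooled <= nes_star).mean()
            den = (obs_nes <= nes_star).mean()
        else:
            qs.append(1.0)
            continue
        qs.append(float(np.clip(num / den if den > 0 else 1.0, 0.0, 1.0)))
    # Enforce monotonicity within each sign class: a weaker |NES| can never
    # have a smaller q than a stronger one.
    qs = np.asarray(qs)
    for sign_mask, key in ((obs_nes > 0, -obs_nes), (obs_nes < 0, obs_nes)):
        idx = np.flatnonzero(sign_mask)
        if idx.size:
            order = idx[np.argsort(key[idx], kind="stable")]
            qs[order] = np.maximum.accumulate(qs[order])
    for r, q in zip(rows, qs):
        r["q"] = float(q)
    df = pd.DataFrame(rows, columns=["set", "size", "es", "nes", "p", "q",
                                     "leading_edge"])
    return df.sort_values("nes", ascending=False, kind="stable",
                          ignore_index=True)
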