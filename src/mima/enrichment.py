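"""Cross-study signature comparison statistics.

Covers the gene-set machinery used to compare differential-expression
signatures between cohorts: one-sided Fisher exact overlap of gene sets,
hypergeometric over-representation analysis, preranked GSEA (weighted
Kolmogorov-Smirnov running sum with a gene-label permutation null), the
pathway score -log10(padj) * sign(NES), and the Pearson correlation / OLS
slope between two studies' pathway scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PathwayCollection
from .errors import ConfigurationError
from .stats import bh_adjust, hypergeom_upper_tail

__all__ = [
    "bh_adjust",
    "fisher_overlap",
    "rank_metric",
    "make_ranking",
    "preranked_gsea",
    "pathway_score",
    "score_correlation",
    "ora",
    "overlap_percentage",
    "OverlapResult",
    "GseaResult",
]

log = logging.getLogger("mima.enrichment")

_TINY_P = float(np.finfo(float).tiny)


@dataclass
class OverlapResult:
    """Fisher exact test of the overlap between two gene sets in a universe."""

    label_a: str
    label_b: str
    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # universe \ (A ∪ B)
    odds_ratio: float
    p_value: float
    padj: float | None = None


def fisher_overlap(
    set_a, set_b, universe, labels: tuple[str, str] = ("A", "B"), alternative: str = "greater"
) -> OverlapResult:
    """One-sided (enrichment) Fisher exact test of |A ∩ B| within ``universe``.

    The one-sided p equals the hypergeometric upper tail of the overlap; the
    odds ratio is the sample odds ratio of the 2x2 table.
    """
    universe = set(universe)
    if not universe:
        raise ConfigurationError("empty universe")
    A, B = set(set_a), set(set_b)
    if not A <= universe or not B <= universe:
        raise ConfigurationError("both sets must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return OverlapResult(
        label_a=labels[0],
        label_b=labels[1],
        a=a, b=b, c=c, d=d,
        odds_ratio=float(odds),
        p_value=float(np.clip(p, _TINY_P, 1.0)),
    )


RANK_MODES = ("signed_logp", "lfc_times_logp", "stat")


def rank_metric(log2fc, p, mode: str = "signed_logp", stat=None) -> np.ndarray:
    """Per-gene ranking score for preranked GSEA.

    ``signed_logp``  : -log10(p) * sign(log2FC)
    ``lfc_times_logp``: log2FC * -log10(p)
    ``stat``         : pass an externally supplied statistic through unchanged.

    Zero p-values are clamped to the smallest positive float with a warning.
    """
    if mode not in RANK_MODES:
        raise ConfigurationError(f"unknown rank metric mode {mode!r}")
    if mode == "stat":
        if stat is None:
            raise ConfigurationError("mode 'stat' requires the stat argument")
        return np.asarray(stat, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    p = np.asarray(p, dtype=float)
    if not np.isfinite(lfc).all():
        raise ConfigurationError("log2fc must be finite")
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    if (p == 0).any():
        log.warning("clamping %d zero p-value(s) for the rank metric", int((p == 0).sum()))
        p = np.clip(p, _TINY_P, 1.0)
    neglogp = -np.log10(p)
    return neglogp * np.sign(lfc) if mode == "signed_logp" else lfc * neglogp


def make_ranking(genes, scores) -> pd.Series:
    """Ranked gene list: scores descending, ties broken by gene id (deterministic)."""
    s = pd.Series(np.asarray(scores, dtype=float), index=pd.Index(genes, name="gene"))
    if s.index.has_duplicates:
        raise ConfigurationError("ranked gene list must have unique genes")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


@dataclass
class GseaResult:
    pathway: str
    es: float
    nes: float
    p_value: float
    padj: float
    size: int
    leading_edge: list[str] = field(default_factory=list)


def _running_es(abs_scores_w: np.ndarray, hit_mask: np.ndarray) -> tuple[float, int]:
    """Weighted KS enrichment score and the index of its extremum."""
    n = hit_mask.size
    nh = int(hit_mask.sum())
    w = np.where(hit_mask, abs_scores_w, 0.0)
    total = w.sum()
    if total == 0:  # all hit scores are exactly zero: fall back to unweighted
        w = hit_mask.astype(float)
        total = w.sum()
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~hit_mask) / (n - nh)
    running = p_hit - p_miss
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def _perm_es(abs_scores_w: np.ndarray, nh: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets (gene-label permutation null)."""
    n = abs_scores_w.size
    out = np.empty(n_perm, dtype=float)
    chunk = max(1, int(5_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # random nh positions per row via argpartition of uniform keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, nh - 1, axis=1)[:, :nh]
        mask = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask, idx, True, axis=1)
        w = np.where(mask, abs_scores_w[None, :], 0.0)
        totals = w.sum(axis=1)
        zero = totals == 0
        if zero.any():
            w[zero] = mask[zero].astype(float)
            totals[zero] = nh
        p_hit = np.cumsum(w, axis=1) / totals[:, None]
        p_miss = np.cumsum(~mask, axis=1) / (n - nh)
        running = p_hit - p_miss
        ext = np.argmax(np.abs(running), axis=1)
        out[done : done + m] = running[np.arange(m), ext]
        done += m
    return out


def preranked_gsea(
    ranking: pd.Series,
    sets: PathwayCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = 1,
) -> list[GseaResult]:
    """Preranked GSEA over a pathway collection.

    The enrichment score is the extremum of the weighted KS running sum
    (hit increments proportional to |score|^weight).  The null is a gene-label
    permutation: ES of random same-size sets drawn from the ranking.  The
    permutation p is one-sided on the observed ES's own sign; NES divides the
    ES by the mean |ES| of same-signed permutation values.  BH adjustment runs
    across all sets with a defined NES.  Sets smaller than ``min_size`` after
    intersection with the ranking, and sets covering the whole ranking, are
    dropped with a warning.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    ranking = make_ranking(ranking.index, ranking.values)
    order_genes = ranking.index
    abs_w = np.abs(ranking.values) ** weight
    n = len(ranking)
    gene_pos = {g: i for i, g in enumerate(order_genes)}

    rng = np.random.default_rng(seed)
    perm_cache: dict[int, np.ndarray] = {}
    raw: list[tuple[str, float, float, float, int, list[str]]] = []
    for name, members in sets:
        pos = sorted({gene_pos[g] for g in members if g in gene_pos})
        if len(pos) < len(set(members)):
            log.warning("set %s: %d gene(s) not in the ranking", name, len(set(members)) - len(pos))
        if len(pos) < min_size or len(pos) == 0:
            log.warning("dropping set %s: fewer than %d genes in the ranking", name, min_size)
            continue
        if len(pos) >= n:
            warnings.warn(f"dropping set {name}: covers the entire ranking (degenerate ES)")
            continue
        mask = np.zeros(n, dtype=bool)
        mask[pos] = True
        es, i_ext = _running_es(abs_w, mask)
        if es >= 0:
            leading = [g for g in order_genes[: i_ext + 1] if mask[gene_pos[g]]]
        else:
            leading = [g for g in order_genes[i_ext:] if mask[gene_pos[g]]]
        nh = len(pos)
        if nh not in perm_cache:
            perm_cache[nh] = _perm_es(abs_w, nh, n_perm, rng)
        perm = perm_cache[nh]
        if es >= 0:
            count = int((perm >= es).sum())
            same_sign = perm[perm > 0]
        else:
            count = int((perm <= es).sum())
            same_sign = perm[perm < 0]
        p = (1 + count) / (1 + n_perm)
        nes = float(es / np.abs(same_sign).mean()) if same_sign.size else np.nan
        raw.append((name, es, nes, p, nh, leading))

    defined = [r for r in raw if np.isfinite(r[2])]
    undefined = [r for r in raw if not np.isfinite(r[2])]
    if undefined:
        log.warning("%d set(s) with undefined NES excluded from the BH family", len(undefined))
    padj = bh_adjust([r[3] for r in defined]) if defined else np.array([])
    results = [
        GseaResult(pathway=name, es=es, nes=nes, p_value=p, padj=float(max(adj, p)), size=size,
                   leading_edge=leading)
        for (name, es, nes, p, size, leading), adj in zip(defined, padj)
    ]
    results += [
        GseaResult(pathway=name, es=es, nes=float("nan"), p_value=p, padj=float("nan"),
                   size=size, leading_edge=leading)
        for name, es, nes, p, size, leading in undefined
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def gsea_to_frame(results: list[GseaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.pathway, r.size, r.es, r.nes, r.p_value, r.padj, ";".join(r.leading_edge))
            for r in results
        ],
        columns=["pathway", "size", "es", "nes", "p_value", "padj", "leading_edge"],
    )


def pathway_score(padj, nes) -> np.ndarray | float:
    """-log10(padj) * sign(NES); the cross-study comparison score per pathway."""
    padj_arr = np.asarray(padj, dtype=float)
    nes_arr = np.asarray(nes, dtype=float)
    if (padj_arr <= 0).any() or (padj_arr > 1).any():
        raise ConfigurationError("padj must lie in (0, 1]")
    if not np.isfinite(nes_arr).all():
        raise ConfigurationError("NES must be finite")
    out = -np.log10(padj_arr) * np.sign(nes_arr)
    return float(out) if out.ndim == 0 else out


def score_correlation(scores_a: pd.Series, scores_b: pd.Series) -> tuple[float, float, int]:
    """Pearson r and OLS slope of B on A over the shared pathway ids.

    Returns (r, slope, n_matched).  Unmatched pathways are dropped and counted
    in the log.
    """
    common = scores_a.index.intersection(scores_b.index)
    dropped = (len(scores_a) - len(common)) + (len(scores_b) - len(common))
    if dropped:
        log.info("score_correlation: %d unmatched pathway score(s) dropped", dropped)
    if len(common) < 3:
        raise ConfigurationError("need >= 3 matched pathways for a correlation")
    x = scores_a.loc[common].to_numpy(dtype=float)
    y = scores_b.loc[common].to_numpy(dtype=float)
    r = float(stats.pearsonr(x, y).statistic)
    slope = float(np.polyfit(x, y, 1)[0])
    return r, slope, int(len(common))


def ora(query_set, annotation_sets: PathwayCollection, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_set`` in each annotation set.

    Per set: upper-tail p of the overlap within ``universe``, BH-adjusted
    across sets, sorted by (padj, p, name).
    """
    universe = set(universe)
    query = set(query_set) & universe
    if not query:
        raise ConfigurationError("empty query set (after restriction to the universe)")
    rows = []
    for name, members in annotation_sets:
        in_universe = set(members) & universe
        if not in_universe:
            continue
        overlap = len(query & in_universe)
        p = hypergeom_upper_tail(overlap, len(universe), len(in_universe), len(query))
        rows.append((name, len(in_universe), overlap, float(np.clip(p, _TINY_P, 1.0))))
    table = pd.DataFrame(rows, columns=["pathway", "set_size", "overlap", "p"])
    table["padj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return table.sort_values(["padj", "p", "pathway"], kind="mergesort").reset_index(drop=True)


def overlap_percentage(degs_a, degs_b) -> float:
    """|A ∩ B| / |A| as a percentage; A is the reference (query) set.

    Call once per direction (up-/down-regulated) with the directional subsets.
    """
    A, B = set(degs_a), set(degs_b)
    if not A:
        raise ConfigurationError("reference DEG set is empty")
    return 100.0 * len(A & B) / len(A)
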