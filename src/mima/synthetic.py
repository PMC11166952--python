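"""Synthetic cohorts with the statistical structure the association pipeline assumes.

The generator emulates a small spaceflight-style longitudinal cohort: a handful
of crew members sampled at a few timepoints, pseudo-bulk gene expression per
immune cell type, and compositional microbial abundance matrices per
(domain, rank).  Expression for a "planted" gene-microbe pair follows

    expr = baseline + crew_intercept + slope * z(log(microbe + pc)) + noise

with Gaussian crew random intercepts (SD ``crew_sd``) and Gaussian residuals
(SD ``noise_sd``); non-planted genes are baseline + intercept + noise.
Microbial counts are zero-inflated log-normal rounded to integers, matching
the zero-heavy, heavy-tailed profiles of shotgun taxonomic abundance tables
without modelling read depth.  Planted effects are injected on the log scale,
the scale on which both association stages are fit.

Everything is driven by a single integer seed; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    DEFAULT_CELL_TYPES,
    CompoundInteractome,
    ExpressionMatrix,
    MicrobeAbundanceMatrix,
    PathwayCollection,
)
from .errors import ConfigurationError, DegenerateDesignError
from .transforms import pseudocount
from .stats import bh_adjust

log = logging.getLogger("mima.synthetic")

_TINY_P = float(np.finfo(float).tiny)


def _default_microbes() -> dict[tuple[str, str], int]:
    return {("bacteria", "genus"): 50, ("virus", "genus"): 20}


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``effect_size`` is the planted slope in expression-SD units per
    predictor-SD; ``crew_sd`` and ``noise_sd`` are on the expression scale.
    ``zero_inflation`` is the fraction of structurally zero microbial counts.
    """

    n_crew: int = 4
    n_timepoints: int = 6
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    n_genes: int = 100
    n_microbes_per_rank: dict[tuple[str, str], int] = field(default_factory=_default_microbes)
    n_planted: int = 10
    effect_size: float = 1.0
    crew_sd: float = 0.5
    noise_sd: float = 0.5
    zero_inflation: float = 0.3
    baseline_range: tuple[float, float] = (2.0, 8.0)
    planted_cell_type: str | None = None  # defaults to the first cell type
    seed: int = 0

    def validate(self) -> None:
        if self.n_crew < 2:
            raise ConfigurationError("n_crew must be >= 2")
        if self.n_timepoints < 2:
            raise ConfigurationError("n_timepoints must be >= 2")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if not self.cell_types:
            raise ConfigurationError("cell_types must be non-empty")
        if not self.n_microbes_per_rank:
            raise ConfigurationError("n_microbes_per_rank must be non-empty")
        if any(n < 1 for n in self.n_microbes_per_rank.values()):
            raise ConfigurationError("n_microbes_per_rank counts must be positive")
        if self.n_planted < 0:
            raise ConfigurationError("n_planted must be >= 0")
        min_microbes = min(self.n_microbes_per_rank.values())
        if self.n_planted > self.n_genes * min_microbes:
            raise ConfigurationError("n_planted exceeds n_genes x smallest microbe matrix")
        if self.n_planted > self.n_genes:
            raise ConfigurationError("n_planted must be <= n_genes (one planted microbe per gene)")
        if not 0 <= self.zero_inflation < 1:
            raise ConfigurationError("zero_inflation must lie in [0, 1)")
        for name in ("effect_size", "crew_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.planted_cell_type is not None and self.planted_cell_type not in self.cell_types:
            raise ConfigurationError("planted_cell_type is not one of cell_types")


@dataclass
class PlantedPair:
    cell_type: str
    gene: str
    microbe: str
    domain: str
    rank: str
    sign: int  # +1 / -1


@dataclass
class SyntheticTruth:
    """Ground truth a pipeline run is expected to recover."""

    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_compounds: list[str] = field(default_factory=list)
    planted_pathways: list[str] = field(default_factory=list)

    def pair_keys(self) -> set[tuple]:
        return {(p.cell_type, p.gene, p.microbe, p.domain, p.rank) for p in self.planted_pairs}


def _sample_ids(n_crew: int, n_timepoints: int) -> list[str]:
    return [f"crew{k}_T{j}" for k in range(1, n_crew + 1) for j in range(1, n_timepoints + 1)]


def _simulate_microbes(
    rng: np.random.Generator, config: CohortConfig, samples: list[str]
) -> dict[tuple[str, str], MicrobeAbundanceMatrix]:
    out: dict[tuple[str, str], MicrobeAbundanceMatrix] = {}
    for (domain, rank), n_feat in sorted(config.n_microbes_per_rank.items()):
        ids = [f"{domain[:3]}_{rank}_{i:04d}" for i in range(1, n_feat + 1)]
        # Per-feature log-mean heterogeneity keeps the abundance distribution
        # heavy-tailed across features as well as within them.
        meanlog = rng.uniform(1.0, 5.0, size=n_feat)
        raw = rng.lognormal(mean=meanlog[:, None], sigma=1.5, size=(n_feat, len(samples)))
        zeros = rng.random((n_feat, len(samples))) < config.zero_inflation
        counts = np.rint(np.where(zeros, 0.0, raw))
        if not (counts > 0).any():
            counts[0, 0] = 1.0  # guard: pseudocount rule needs one positive entry
        out[(domain, rank)] = MicrobeAbundanceMatrix(
            pd.DataFrame(counts, index=ids, columns=samples), domain=domain, rank=rank
        )
    return out


def _choose_planted(
    rng: np.random.Generator,
    config: CohortConfig,
    genes: list[str],
    microbes: dict[tuple[str, str], MicrobeAbundanceMatrix],
) -> list[PlantedPair]:
    if config.n_planted == 0:
        return []
    cell_type = config.planted_cell_type or config.cell_types[0]
    pool = [
        (feat, domain, rank)
        for (domain, rank), m in sorted(microbes.items())
        for feat in m.features
    ]
    planted_genes = rng.choice(len(genes), size=config.n_planted, replace=False)
    planted_microbes = rng.choice(len(pool), size=config.n_planted, replace=True)
    pairs = []
    for g_idx, m_idx in zip(planted_genes, planted_microbes):
        feat, domain, rank = pool[m_idx]
        pairs.append(PlantedPair(cell_type, genes[g_idx], feat, domain, rank, sign=1))
    return pairs


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, ExpressionMatrix], dict[tuple[str, str], MicrobeAbundanceMatrix], SyntheticTruth]:
    """Simulate expression matrices per cell type, abundance matrices per (domain, rank), and truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    samples = _sample_ids(config.n_crew, config.n_timepoints)
    crew_of = np.repeat(np.arange(config.n_crew), config.n_timepoints)
    genes = [f"gene_{i:05d}" for i in range(1, config.n_genes + 1)]

    microbes = _simulate_microbes(rng, config, samples)
    planted = _choose_planted(rng, config, genes, microbes)
    planted_by_ct: dict[str, dict[str, PlantedPair]] = {}
    for p in planted:
        planted_by_ct.setdefault(p.cell_type, {})[p.gene] = p

    # Planted predictors on the analysis scale: z-scored log(count + pseudocount).
    predictor: dict[tuple[str, str, str], np.ndarray] = {}
    for (domain, rank), m in microbes.items():
        pc = pseudocount(m)
        logged = np.log(m.data.to_numpy() + pc)
        sd = logged.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        z = (logged - logged.mean(axis=1, keepdims=True)) / sd[:, None]
        for i, feat in enumerate(m.features):
            predictor[(domain, rank, feat)] = z[i]

    expression: dict[str, ExpressionMatrix] = {}
    n_s = len(samples)
    for cell_type in config.cell_types:
        baseline = rng.uniform(*config.baseline_range, size=config.n_genes)
        intercepts = rng.normal(0.0, config.crew_sd, size=(config.n_genes, config.n_crew))
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_s))
        values = baseline[:, None] + intercepts[:, crew_of] + noise
        for gene, pair in planted_by_ct.get(cell_type, {}).items():
            g = genes.index(gene)
            x = predictor[(pair.domain, pair.rank, pair.microbe)]
            values[g] += pair.sign * config.effect_size * x
        expression[cell_type] = ExpressionMatrix(
            pd.DataFrame(values, index=genes, columns=samples), cell_type=cell_type
        )

    return expression, microbes, SyntheticTruth(planted_pairs=planted)


def generate_deg_table(
    expr: ExpressionMatrix,
    design: dict[str, str],
    lfc_threshold: float = 0.25,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression: Welch t-test + BH, then threshold.

    ``design`` maps sample id -> "pre" | "post".  The fold change is
    log2(mean(post) / mean(pre)), so the input is expected on a non-negative
    expression scale.  A gene is flagged as a DEG iff |log2FC| exceeds
    ``lfc_threshold`` and the BH-adjusted p falls below ``padj_threshold``.
    """
    groups = pd.Series({s: design[s] for s in expr.sample_ids if s in design})
    pre = expr.data.loc[:, groups[groups == "pre"].index]
    post = expr.data.loc[:, groups[groups == "post"].index]
    if pre.shape[1] < 2 or post.shape[1] < 2:
        raise DegenerateDesignError("each design group needs >= 2 samples")

    a, b = pre.to_numpy(dtype=float), post.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(np.isnan(p), np.where(equal_means, 1.0, _TINY_P), p)
    p = np.clip(p, _TINY_P, 1.0)

    mean_pre, mean_post = a.mean(axis=1), b.mean(axis=1)
    bad = (mean_pre <= 0) | (mean_post <= 0)
    if bad.any():
        log.warning("clamping %d gene(s) with non-positive group mean for log2FC", int(bad.sum()))
    eps = 1e-9
    log2fc = np.log2(np.maximum(mean_post, eps) / np.maximum(mean_pre, eps))
    log2fc = np.where(equal_means, 0.0, log2fc)

    padj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": expr.genes,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "direction": np.where(log2fc >= 0, "up", "down"),
        }
    )
    table["is_deg"] = (np.abs(table["log2fc"]) > lfc_threshold) & (table["padj"] < padj_threshold)
    return table


def pre_post_design(expr: ExpressionMatrix, n_pre: int = 3) -> dict[str, str]:
    """Label the first ``n_pre`` timepoints of every crew member "pre", the rest "post"."""
    design = {}
    for sid in expr.sample_ids:
        tp = int(str(expr.samples.loc[sid, "timepoint"]).lstrip("T"))
        design[sid] = "pre" if tp <= n_pre else "post"
    return design


def generate_interactome(
    n_compounds: int,
    n_genes: int,
    density: float,
    deg_genes=(),
    n_planted: int = 0,
    planted_deg_fraction: float = 0.9,
    compound_class: str = "drug",
    seed: int = 0,
) -> tuple[CompoundInteractome, list[str]]:
    """Bipartite compound -> gene sets; planted compounds over-sample the DEG list.

    Background compounds draw genes uniformly with expected set size
    ``density * n_genes``; planted compounds draw ``planted_deg_fraction`` of
    their genes from ``deg_genes``.  Returns the interactome and the planted
    compound ids.
    """
    if not 0 < density < 1:
        raise ConfigurationError("density must lie in (0, 1)")
    if n_compounds < 1 or n_genes < 1:
        raise ConfigurationError("n_compounds and n_genes must be positive")
    if n_planted > n_compounds:
        raise ConfigurationError("n_planted exceeds n_compounds")
    rng = np.random.default_rng(seed)
    genes = np.array([f"gene_{i:05d}" for i in range(1, n_genes + 1)])
    deg_genes = [g for g in deg_genes if g in set(genes)]
    if n_planted and not deg_genes:
        raise ConfigurationError("planted compounds require a non-empty deg_genes list")
    non_deg = np.array(sorted(set(genes) - set(deg_genes)))

    gene_sets: dict[str, frozenset] = {}
    planted_ids: list[str] = []
    for i in range(1, n_compounds + 1):
        cid = f"{compound_class}_{i:04d}"
        size = max(1, rng.binomial(n_genes, density))
        if i <= n_planted:
            n_from_deg = min(len(deg_genes), max(1, int(round(size * planted_deg_fraction))))
            n_rest = min(len(non_deg), size - n_from_deg)
            members = np.concatenate(
                [
                    rng.choice(deg_genes, size=n_from_deg, replace=False),
                    rng.choice(non_deg, size=n_rest, replace=False) if n_rest else [],
                ]
            )
            planted_ids.append(cid)
        else:
            members = rng.choice(genes, size=min(size, n_genes), replace=False)
        gene_sets[cid] = frozenset(members.tolist())
    return CompoundInteractome(gene_sets, compound_class=compound_class), planted_ids


def generate_pathways(
    n_sets: int,
    set_size_range: tuple[int, int],
    genes,
    ranking=None,
    n_planted: int = 0,
    concordance: float = 0.9,
    top_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[PathwayCollection, list[str]]:
    """Random gene sets plus planted sets concentrated at the top of ``ranking``.

    ``concordance`` is the probability that each member of a planted set is
    drawn from the top ``top_fraction`` of the supplied ranking (ordered gene
    list, best first).  Returns the collection and the planted set names.
    """
    genes = list(genes)
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError("set_size_range must satisfy 1 <= lo <= hi")
    if hi > len(genes):
        raise ConfigurationError("set_size_range upper bound exceeds the gene universe")
    if n_planted > n_sets:
        raise ConfigurationError("n_planted exceeds n_sets")
    if n_planted and ranking is None:
        raise ConfigurationError("planted pathways require a ranking")
    rng = np.random.default_rng(seed)
    collection = PathwayCollection()
    planted_ids: list[str] = []
    if ranking is not None:
        ranking = list(ranking)
        top = ranking[: max(1, int(round(top_fraction * len(ranking))))]
    for i in range(1, n_sets + 1):
        name = f"pathway_{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i <= n_planted:
            members: list[str] = []
            seen: set[str] = set()
            while len(members) < size:
                pool = top if rng.random() < concordance else genes
                g = pool[int(rng.integers(len(pool)))]
                if g not in seen:
                    seen.add(g)
                    members.append(g)
            planted_ids.append(name)
        else:
            members = [genes[j] for j in rng.choice(len(genes), size=size, replace=False)]
        collection.sets[name] = members
        collection.descriptions[name] = "planted" if i <= n_planted else "random"
    return collection, planted_ids


def cohort_config_to_dict(config: CohortConfig) -> dict:
    """JSON/YAML-friendly view of a config (tuple keys flattened)."""
    d = asdict(config)
    d["cell_types"] = list(config.cell_types)
    d["baseline_range"] = list(config.baseline_range)
    d["n_microbes_per_rank"] = {f"{dom}/{rank}": n for (dom, rank), n in config.n_microbes_per_rank.items()}
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "n_microbes_per_rank" in d:
        d["n_microbes_per_rank"] = {
            (tuple(k.split("/")) if isinstance(k, str) else tuple(k)): v
            for k, v in d["n_microbes_per_rank"].items()
        }
    if "cell_types" in d:
        d["cell_types"] = tuple(d["cell_types"])
    if "baseline_range" in d:
        d["baseline_range"] = tuple(d["baseline_range"])
    return CohortConfig(**d)
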