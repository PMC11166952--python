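"""Stage 2: per-candidate mixed-model inference, Bonferroni scheme, and null comparison.

Each candidate pair from the LASSO screen is refit as a random-intercept
linear mixed model,

    gene ~ microbe + (1 | crew),

with the gene centered/scaled and the microbe on the same log-scale transform
as in stage 1.  The variance ratio is estimated by profiled REML (the 1-D
profiling lme4 uses for a single random intercept), the slope and its
standard error come from GLS at the REML optimum, and the fixed slope gets a
two-sided Wald t p-value with Satterthwaite denominator degrees of freedom —
with a handful of crew members a plain z (or even a fixed-df t) reference is
anti-conservative in the far tail, especially for predictors whose variation
is mostly between crews.  A boundary fit (zero crew variance) falls back to
ordinary least squares, which the model then equals; the fallback is flagged
in the output.

Significance is reported at three nested stringency levels: a non-zero LASSO
coefficient (by construction of the candidate list), nominal p < 0.05, and a
Bonferroni rule whose family size is (number of microbes in the pair's
domain x rank) x (number of DEGs in the pair's cell type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import ExpressionMatrix, MicrobeAbundanceMatrix
from .errors import ConfigurationError, DegeneratePredictorError
from .screen import CandidateAssociation, ScreenConfig, run_screen_all
from .transforms import TRANSFORMS, center_scale, transform_abundance

log = logging.getLogger("mima.infer")

_TINY_P = float(np.finfo(float).tiny)
_CREW_VAR_FLOOR = 1e-8


@dataclass
class LmmFit:
    slope: float
    slope_se: float
    p_value: float
    crew_variance: float
    method: str  # "lmm" | "ols"
    converged: bool


@dataclass
class AssociationResult:
    """One gene-microbe pair after stage-2 inference, with stringency flags."""

    cell_type: str
    gene: str
    microbe: str
    domain: str
    rank: str
    transform: str
    lasso_coefficient: float
    slope: float
    slope_se: float
    p_value: float
    crew_variance: float
    method: str
    converged: bool
    nominal: bool = False
    bonf_020: bool = False
    bonf_005: bool = False

    @property
    def slope_sign(self) -> int:
        return 1 if self.slope > 0 else (-1 if self.slope < 0 else 0)

    def pair_key(self) -> tuple:
        return (self.cell_type, self.gene, self.microbe, self.domain, self.rank, self.transform)


def _ols_fit(y: np.ndarray, x: np.ndarray) -> LmmFit:
    res = stats.linregress(x, y)
    return LmmFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        p_value=float(np.clip(res.pvalue, _TINY_P, 1.0)),
        crew_variance=0.0,
        method="ols",
        converged=True,
    )


def _group_blocks(crew: np.ndarray):
    groups, gi = np.unique(crew, return_inverse=True)
    sizes = np.bincount(gi)
    return gi, sizes


def _profiled_reml(y: np.ndarray, X: np.ndarray, gi: np.ndarray, sizes: np.ndarray):
    """Profiled REML criterion pieces for V = sigma_e^2 (I + lam * Z Z').

    For a single random intercept, W = (I + lam ZZ')^-1 acts blockwise:
    within a group of size m, W = I - lam/(1 + m lam) * J.  Both the residual
    variance and the fixed effects profile out, leaving a 1-D criterion in
    lam = sigma_crew^2 / sigma_e^2.
    """
    n, p = X.shape
    n_groups = sizes.size
    Xg = np.zeros((n_groups, p))
    yg = np.zeros(n_groups)
    np.add.at(Xg, gi, X)
    np.add.at(yg, gi, y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)

    def pieces(lam: float):
        c = lam / (1.0 + sizes * lam)  # per-group deflation weight
        XtWX = XtX - (Xg * c[:, None]).T @ Xg
        XtWy = Xty - (Xg * (c * yg)[:, None]).sum(axis=0)
        yWy = yty - float(c @ yg**2)
        C = np.linalg.inv(XtWX)
        beta = C @ XtWy
        rss = yWy - float(beta @ XtWy)  # r' W r via projection identity
        return C, beta, max(rss, 1e-300)

    def neg_criterion(lam: float) -> float:
        C, beta, rss = pieces(lam)
        sign, ld_XtWX = np.linalg.slogdet(np.linalg.inv(C))
        ld_V = float(np.log1p(sizes * lam).sum())
        return 0.5 * ((n - p) * np.log(rss) + ld_V + ld_XtWX)

    return pieces, neg_criterion


def _satterthwaite_df(x: np.ndarray, gi: np.ndarray, sizes: np.ndarray,
                      crew_var: float, resid_var: float) -> float:
    """Satterthwaite denominator df for the slope of a random-intercept model.

    df = 2 var(b)^2 / (g' A g) with g the gradient of var(b) w.r.t. the two
    variance components and A the inverse REML information.  Dense n x n
    algebra; the designs here are tiny.
    """
    n = x.size
    X = np.column_stack([np.ones(n), x])
    Z = np.zeros((n, sizes.size))
    Z[np.arange(n), gi] = 1.0
    ZZt = Z @ Z.T
    V = resid_var * np.eye(n) + crew_var * ZZt
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    var_b = C[1, 1]
    P = Vi - Vi @ X @ C @ X.T @ Vi
    dV = (ZZt, np.eye(n))
    grad = np.array([(C @ X.T @ Vi @ dVk @ Vi @ X @ C)[1, 1] for dVk in dV])
    info = np.array([[0.5 * np.trace(P @ dVk @ P @ dVm) for dVm in dV] for dVk in dV])
    try:
        cov_theta = np.linalg.inv(info)
        denom = float(grad @ cov_theta @ grad)
    except np.linalg.LinAlgError:
        denom = np.inf
    if denom <= 0 or not np.isfinite(denom):
        return float(n - 2)
    return float(np.clip(2.0 * var_b**2 / denom, 1.0, n - 2))


def fit_lmm(gene_values, microbe_values, crew_ids) -> LmmFit:
    """Random-intercept model of one gene on one microbe, grouped by crew.

    The variance ratio is estimated by profiled REML (1-D bounded
    optimization, the same profiling lme4 uses), the slope and its standard
    error come from GLS at the REML optimum, and the two-sided p-value is a
    Wald t with Satterthwaite denominator df.  Degenerate groupings (a single
    crew) or a boundary fit (zero crew variance) fall back to ordinary least
    squares, which the model then equals.
    """
    y = np.asarray(gene_values, dtype=float)
    x = np.asarray(microbe_values, dtype=float)
    crew = np.asarray(crew_ids)
    if y.shape != x.shape or y.shape[0] != crew.shape[0]:
        raise ConfigurationError("gene, microbe and crew vectors must have equal length")
    if np.ptp(x) == 0:
        raise DegeneratePredictorError("microbe predictor is constant")
    if len(np.unique(crew)) < 2:
        log.warning("single crew group: falling back to ordinary regression")
        return _ols_fit(y, x)

    n = y.size
    X = np.column_stack([np.ones(n), x])
    gi, sizes = _group_blocks(crew)
    pieces, neg_criterion = _profiled_reml(y, X, gi, sizes)

    # optimize on an unbounded scale: lam = exp(u), u in [-12, 12]
    res = optimize.minimize_scalar(
        lambda u: neg_criterion(float(np.exp(u))), bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    if neg_criterion(0.0) <= res.fun:  # boundary optimum: no crew variance
        return _ols_fit(y, x)
    C, beta, rss = pieces(lam)
    resid_var = rss / (n - 2)
    crew_var = lam * resid_var
    if crew_var < _CREW_VAR_FLOOR:
        return _ols_fit(y, x)
    slope = float(beta[1])
    se = float(np.sqrt(resid_var * C[1, 1]))
    df = _satterthwaite_df(x, gi, sizes, crew_var, resid_var)
    p = 2.0 * stats.t.sf(abs(slope / se), df=df)
    return LmmFit(
        slope=slope,
        slope_se=se,
        p_value=float(np.clip(p, _TINY_P, 1.0)),
        crew_variance=float(crew_var),
        method="lmm",
        converged=bool(res.success),
    )


def infer_candidates(
    expression: dict[str, ExpressionMatrix],
    microbes: dict[tuple[str, str], MicrobeAbundanceMatrix],
    candidates: list[CandidateAssociation],
) -> list[AssociationResult]:
    """Fit the mixed model for every candidate pair, on the candidate's transform."""
    transformed_cache: dict[tuple, pd.DataFrame] = {}
    gene_cache: dict[tuple[str, str], np.ndarray] = {}
    results: list[AssociationResult] = []
    for cand in candidates:
        expr = expression[cand.cell_type]
        tkey = (cand.domain, cand.rank, cand.transform)
        if tkey not in transformed_cache:
            ta = transform_abundance(microbes[(cand.domain, cand.rank)], cand.transform)
            transformed_cache[tkey] = ta.values.loc[:, expr.sample_ids]
        gkey = (cand.cell_type, cand.gene)
        if gkey not in gene_cache:
            gene_cache[gkey] = center_scale(expr.data.loc[cand.gene].to_numpy(dtype=float))
        x = transformed_cache[tkey].loc[cand.microbe].to_numpy(dtype=float)
        try:
            fit = fit_lmm(gene_cache[gkey], x, expr.crew_ids().to_numpy())
        except DegeneratePredictorError:
            log.warning("constant predictor for %s/%s; dropped", cand.gene, cand.microbe)
            continue
        results.append(
            AssociationResult(
                cell_type=cand.cell_type,
                gene=cand.gene,
                microbe=cand.microbe,
                domain=cand.domain,
                rank=cand.rank,
                transform=cand.transform,
                lasso_coefficient=cand.lasso_coefficient,
                slope=fit.slope,
                slope_se=fit.slope_se,
                p_value=fit.p_value,
                crew_variance=fit.crew_variance,
                method=fit.method,
                converged=fit.converged,
            )
        )
    return results


@dataclass
class BonferroniScheme:
    """Family sizes for the per-(cell type, domain, rank) Bonferroni rule."""

    alpha: float = 0.05
    n_microbes: dict[tuple[str, str], int] = field(default_factory=dict)
    n_degs: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if any(n < 1 for n in self.n_microbes.values()) or any(n < 1 for n in self.n_degs.values()):
            raise ConfigurationError("family counts must be positive")

    @classmethod
    def from_inputs(
        cls,
        microbes: dict[tuple[str, str], MicrobeAbundanceMatrix],
        degs: dict[str, list[str]],
        alpha: float = 0.05,
    ) -> "BonferroniScheme":
        return cls(
            alpha=alpha,
            n_microbes={key: m.data.shape[0] for key, m in microbes.items()},
            n_degs={ct: len(genes) for ct, genes in degs.items()},
        )


def bonferroni_threshold(
    scheme: BonferroniScheme, cell_type: str, domain: str, rank: str, alpha: float | None = None
) -> float:
    """alpha / (microbes in this domain x rank  *  DEGs in this cell type)."""
    scheme.validate()
    alpha = scheme.alpha if alpha is None else alpha
    try:
        n_m = scheme.n_microbes[(domain, rank)]
    except KeyError:
        raise ConfigurationError(f"no microbe count for ({domain}, {rank})") from None
    try:
        n_d = scheme.n_degs[cell_type]
    except KeyError:
        raise ConfigurationError(f"no DEG count for cell type {cell_type!r}") from None
    return alpha / (n_m * n_d)


def classify(results: list[AssociationResult], scheme: BonferroniScheme) -> list[AssociationResult]:
    """Set the nested stringency flags (bonf_005 => bonf_020 => nominal)."""
    out = []
    for r in results:
        t005 = bonferroni_threshold(scheme, r.cell_type, r.domain, r.rank, alpha=0.05)
        t020 = bonferroni_threshold(scheme, r.cell_type, r.domain, r.rank, alpha=0.20)
        nominal = r.p_value < 0.05
        # Nesting is enforced by construction so tiny families (where
        # 0.2/family > 0.05) cannot produce a Bonferroni hit without nominal.
        bonf_020 = nominal and r.p_value < t020
        bonf_005 = bonf_020 and r.p_value < t005
        out.append(replace(r, nominal=nominal, bonf_020=bonf_020, bonf_005=bonf_005))
    return out


def tally_positive_significant(results: list[AssociationResult], cell_types=None) -> dict[str, int]:
    """Count Bonferroni(0.05)-significant, positive-slope associations per cell type."""
    counts: dict[str, int] = {ct: 0 for ct in (cell_types or [])}
    for r in results:
        counts.setdefault(r.cell_type, 0)
        if r.bonf_005 and r.slope_sign > 0:
            counts[r.cell_type] += 1
    return counts


def rank_genes(results: list[AssociationResult], max_genes: int = 10) -> dict[str, pd.DataFrame]:
    """Per cell type, genes ranked by (# Bonferroni<0.2 hits, # nominal hits), top 10.

    Genes with no nominal association are dropped.  Ties break on the gene id
    so the report is deterministic.
    """
    per_ct: dict[str, dict[str, list[int]]] = {}
    for r in results:
        counts = per_ct.setdefault(r.cell_type, {}).setdefault(r.gene, [0, 0])
        if r.bonf_020:
            counts[0] += 1
        if r.nominal:
            counts[1] += 1
    report: dict[str, pd.DataFrame] = {}
    for ct, genes in per_ct.items():
        rows = [
            (g, c[0], c[1]) for g, c in genes.items() if c[1] > 0
        ]
        if not rows:
            continue
        rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
        report[ct] = pd.DataFrame(
            rows[:max_genes], columns=["gene", "n_bonf_020", "n_nominal"]
        )
    return report


# --------------------------------------------------------------------------
# Randomized-data null comparison
# --------------------------------------------------------------------------

STRINGENCY_LEVELS = ("lasso", "nominal", "bonferroni")


@dataclass
class LevelCounts:
    count_real: int
    count_randomized: int
    count_overlap: int


@dataclass
class NullComparison:
    """Association counts on real vs randomized data, and their overlap, per stringency level."""

    levels: dict[str, LevelCounts]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (lvl, c.count_real, c.count_randomized, c.count_overlap)
                for lvl, c in self.levels.items()
            ],
            columns=["level", "real", "randomized", "overlap"],
        )


def randomize_expression(
    expression: dict[str, ExpressionMatrix], seed: int, scheme: str = "permute_samples"
) -> dict[str, ExpressionMatrix]:
    """Break the gene-microbe pairing while preserving both marginals.

    ``permute_samples`` (default) shuffles which sample label each expression
    column carries, per cell type.  ``permute_genes`` shuffles each gene's
    values independently across samples, which additionally destroys the crew
    structure of expression.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, ExpressionMatrix] = {}
    for ct in sorted(expression):
        expr = expression[ct]
        values = expr.data.to_numpy(dtype=float).copy()
        if scheme == "permute_samples":
            perm = rng.permutation(values.shape[1])
            values = values[:, perm]
        elif scheme == "permute_genes":
            for i in range(values.shape[0]):
                values[i] = values[i, rng.permutation(values.shape[1])]
        else:
            raise ConfigurationError(f"unknown randomization scheme {scheme!r}")
        out[ct] = ExpressionMatrix(
            pd.DataFrame(values, index=expr.data.index, columns=expr.data.columns),
            cell_type=ct,
        )
    return out


def _run_pair_pipeline(expression, microbes, degs, cfg, scheme, transforms):
    candidates = run_screen_all(expression, microbes, degs, cfg, transforms=transforms)
    results = classify(infer_candidates(expression, microbes, candidates), scheme)
    return candidates, results


def _level_sets(candidates, results):
    return {
        "lasso": {c.pair_key() for c in candidates},
        "nominal": {r.pair_key() for r in results if r.nominal},
        "bonferroni": {r.pair_key() for r in results if r.bonf_005},
    }


def randomize_and_compare(
    expression: dict[str, ExpressionMatrix],
    microbes: dict[tuple[str, str], MicrobeAbundanceMatrix],
    degs: dict[str, list[str]],
    cfg: ScreenConfig | None = None,
    alpha: float = 0.05,
    n_randomizations: int = 1,
    seed: int = 0,
    randomization: str = "permute_samples",
    transforms=TRANSFORMS,
) -> NullComparison:
    """Run screen + inference on the real cohort and on randomized copies.

    Counts distinct pairs at the three stringency levels (non-zero LASSO
    coefficient, nominal p < 0.05, Bonferroni < 0.05) and the identity overlap
    between the real and randomized hit sets.  With several randomizations the
    randomized/overlap counts are averaged (rounded to nearest int).
    """
    cfg = cfg or ScreenConfig()
    scheme = BonferroniScheme.from_inputs(microbes, degs, alpha=alpha)
    real_sets = _level_sets(*_run_pair_pipeline(expression, microbes, degs, cfg, scheme, transforms))
    rand_counts = {lvl: [] for lvl in STRINGENCY_LEVELS}
    overlap_counts = {lvl: [] for lvl in STRINGENCY_LEVELS}
    for i in range(n_randomizations):
        shuffled = randomize_expression(expression, seed=seed + i, scheme=randomization)
        rand_sets = _level_sets(*_run_pair_pipeline(shuffled, microbes, degs, cfg, scheme, transforms))
        for lvl in STRINGENCY_LEVELS:
            rand_counts[lvl].append(len(rand_sets[lvl]))
            overlap_counts[lvl].append(len(real_sets[lvl] & rand_sets[lvl]))
    levels = {
        lvl: LevelCounts(
            count_real=len(real_sets[lvl]),
            count_randomized=int(round(float(np.mean(rand_counts[lvl])))),
            count_overlap=int(round(float(np.mean(overlap_counts[lvl])))),
        )
        for lvl in STRINGENCY_LEVELS
    }
    return NullComparison(levels=levels)


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    cols = [
        "cell_type", "gene", "microbe", "domain", "rank", "transform",
        "lasso_coefficient", "slope", "slope_se", "p_value", "crew_variance",
        "method", "converged", "nominal", "bonf_020", "bonf_005",
    ]
    frame = pd.DataFrame([[getattr(r, k) for k in cols] for r in results], columns=cols)
    frame["slope_sign"] = np.sign(frame["slope"]).astype(int) if len(frame) else []
    return frame
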