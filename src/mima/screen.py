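"""Stage 1 of the association pipeline: a LASSO screen per gene.

For every differentially expressed gene of a cell type, its centered/scaled
expression is regressed with an L1 penalty on *all* microbial features of one
(domain, rank) matrix on one log-scale transform.  Any non-zero coefficient at
the selected penalty marks the (gene, microbe) pair as a candidate
association; inference on candidates is stage 2's job.  The screen is run
separately for bacteria and viruses and separately per transform.

p >> n is the expected regime (tens of samples, up to hundreds of features);
features with zero variance are dropped with a warning, everything else goes
into the penalized fit.  The penalty is chosen by k-fold cross-validation
minimizing MSE by default, which keeps the screen sensitive; its false
positives are controlled downstream by the mixed model and the Bonferroni
scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .containers import ExpressionMatrix, MicrobeAbundanceMatrix
from .errors import AlignmentError, ConfigurationError
from .transforms import TransformedAbundance, center_scale, transform_abundance, TRANSFORMS
from .errors import DegeneratePredictorError

log = logging.getLogger("mima.screen")

_COEF_TOL = 1e-10


@dataclass
class ScreenConfig:
    """Penalty-selection strategy and solver numerics for the LASSO screen.

    The penalty path runs over ``n_alphas`` log-spaced values down to
    ``eps`` x the smallest penalty that zeroes every coefficient; correlated
    log-abundance predictors make very long paths expensive without changing
    the selected support, so the path is kept short by default.
    """

    lambda_strategy: str = "cv_min"  # cv_min | cv_1se | fixed
    n_folds: int = 5
    fixed_lambda: float | None = None
    n_alphas: int = 30
    eps: float = 1e-2
    tol: float = 1e-3
    max_iter: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.lambda_strategy not in ("cv_min", "cv_1se", "fixed"):
            raise ConfigurationError(f"unknown lambda_strategy {self.lambda_strategy!r}")
        if self.lambda_strategy == "fixed":
            if self.fixed_lambda is None or self.fixed_lambda < 0:
                raise ConfigurationError("fixed_lambda must be a non-negative number")
        elif self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2 when cross-validating")


@dataclass
class CandidateAssociation:
    """One (gene, microbe) pair with a non-zero LASSO coefficient."""

    cell_type: str
    gene: str
    microbe: str
    domain: str
    rank: str
    transform: str
    lasso_coefficient: float

    def pair_key(self) -> tuple:
        return (self.cell_type, self.gene, self.microbe, self.domain, self.rank, self.transform)


def _standardize_columns(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-SD columns (predictors standardized inside the fit); returns (X_std, keep_mask)."""
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Xs, keep


def _fit_support(y: np.ndarray, X: np.ndarray, cfg: ScreenConfig) -> np.ndarray:
    """Coefficients at the selected penalty (standardized predictor scale)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        if cfg.lambda_strategy == "fixed":
            model = Lasso(alpha=cfg.fixed_lambda, max_iter=cfg.max_iter, tol=cfg.tol)
            model.fit(X, y)
            return model.coef_
        cv = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
        lcv = LassoCV(alphas=cfg.n_alphas, eps=cfg.eps, cv=cv, max_iter=cfg.max_iter, tol=cfg.tol)
        lcv.fit(X, y)
        if cfg.lambda_strategy == "cv_min":
            return lcv.coef_
        # cv_1se: the sparsest penalty whose mean CV error is within one
        # standard error of the minimum (alphas_ is descending).
        mean_mse = lcv.mse_path_.mean(axis=1)
        se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(lcv.mse_path_.shape[1])
        i_min = int(np.argmin(mean_mse))
        within = np.nonzero(mean_mse <= mean_mse[i_min] + se[i_min])[0]
        alpha = float(lcv.alphas_[within.min()])
        model = Lasso(alpha=alpha, max_iter=cfg.max_iter, tol=cfg.tol)
        model.fit(X, y)
        return model.coef_


def lasso_screen(
    expr: ExpressionMatrix,
    microbes: TransformedAbundance,
    degs,
    cfg: ScreenConfig | None = None,
) -> list[CandidateAssociation]:
    """One penalized model per DEG against all features of one transformed matrix."""
    cfg = cfg or ScreenConfig()
    cfg.validate()
    if set(expr.sample_ids) != set(microbes.values.columns):
        raise AlignmentError(
            f"expression samples and {microbes.domain}/{microbes.rank} samples do not match"
        )
    values = microbes.values.loc[:, expr.sample_ids]  # align column order
    X_raw = values.to_numpy(dtype=float).T  # samples x features
    X, keep = _standardize_columns(X_raw)
    if (~keep).any():
        log.warning(
            "%s/%s/%s: dropped %d zero-variance feature(s)",
            microbes.domain, microbes.rank, microbes.transform, int((~keep).sum()),
        )
    features = values.index[keep]
    if X.shape[1] == 0:
        return []

    missing = [g for g in degs if g not in expr.data.index]
    if missing:
        raise AlignmentError(f"DEG(s) absent from expression matrix: {missing[:5]}")

    candidates: list[CandidateAssociation] = []
    for gene in degs:
        try:
            y = center_scale(expr.data.loc[gene].to_numpy(dtype=float))
        except DegeneratePredictorError:
            log.warning("skipping constant gene %s in cell type %s", gene, expr.cell_type)
            continue
        coef = _fit_support(y, X, cfg)
        for j in np.nonzero(np.abs(coef) > _COEF_TOL)[0]:
            candidates.append(
                CandidateAssociation(
                    cell_type=expr.cell_type,
                    gene=gene,
                    microbe=str(features[j]),
                    domain=microbes.domain,
                    rank=microbes.rank,
                    transform=microbes.transform,
                    lasso_coefficient=float(coef[j]),
                )
            )
    return candidates


def run_screen_all(
    expression: dict[str, ExpressionMatrix],
    microbes: dict[tuple[str, str], MicrobeAbundanceMatrix],
    degs: dict[str, list[str]],
    cfg: ScreenConfig | None = None,
    transforms=TRANSFORMS,
) -> list[CandidateAssociation]:
    """Concatenate the screen over cell types x (domain, rank) x transforms.

    ``degs`` maps cell type -> gene list; cell types without an entry are
    skipped.  Per-model failures are logged and collected, not fatal.
    """
    cfg = cfg or ScreenConfig()
    out: list[CandidateAssociation] = []
    n_models = 0
    for cell_type in sorted(expression):
        gene_list = degs.get(cell_type, [])
        if not gene_list:
            continue
        for (domain, rank) in sorted(microbes):
            for method in transforms:
                transformed = transform_abundance(microbes[(domain, rank)], method)
                n_models += 1
                try:
                    out.extend(lasso_screen(expression[cell_type], transformed, gene_list, cfg))
                except AlignmentError as exc:
                    log.warning("screen failed for %s/%s/%s/%s: %s", cell_type, domain, rank, method, exc)
    log.info("screen: %d model families, %d candidate associations", n_models, len(out))
    return out


def candidates_to_frame(candidates: list[CandidateAssociation]) -> pd.DataFrame:
    cols = ["cell_type", "gene", "microbe", "domain", "rank", "transform", "lasso_coefficient"]
    return pd.DataFrame([[getattr(c, k) for k in cols] for c in candidates], columns=cols)
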