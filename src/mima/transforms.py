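"""Abundance and expression transforms used by both association stages.

Microbial abundances are compositional and zero-heavy, so before any log-scale
operation every entry is shifted by a pseudocount equal to the smallest
strictly positive value of the matrix at hand.  Two log-scale views are then
available: a plain natural-log transform and the centered log-ratio (CLR),
taken per sample across features.  Host gene expression enters the regressions
centered and scaled to unit standard deviation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MicrobeAbundanceMatrix
from .errors import DegenerateMatrixError, DegeneratePredictorError

log = logging.getLogger("mima.transforms")

TRANSFORMS = ("log", "clr")


def _as_frame(m) -> pd.DataFrame:
    return m.data if isinstance(m, MicrobeAbundanceMatrix) else pd.DataFrame(m)


def pseudocount(m) -> float:
    """Smallest strictly positive entry of the matrix.

    A literal minimum would be 0 on any matrix with zeros, leaving the
    subsequent log undefined; the smallest positive value is the only reading
    that keeps the transform chain well-defined.
    """
    values = _as_frame(m).to_numpy(dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise DegenerateMatrixError("all-zero matrix: no positive entry to use as pseudocount")
    return float(positive.min())


def add_pseudocount(m):
    """Shift every entry by the matrix-wide smallest positive abundance."""
    pc = pseudocount(m)
    if isinstance(m, MicrobeAbundanceMatrix):
        return MicrobeAbundanceMatrix(m.data + pc, domain=m.domain, rank=m.rank, site=m.site)
    return _as_frame(m) + pc


def log_transform(m) -> pd.DataFrame:
    """Elementwise natural log; input must be strictly positive."""
    frame = _as_frame(m)
    if (frame.to_numpy(dtype=float) <= 0).any():
        raise DegenerateMatrixError("log transform requires strictly positive entries; add a pseudocount first")
    return np.log(frame)


def clr_transform(m) -> pd.DataFrame:
    """Centered log-ratio per sample: ln(x_i) - mean_j ln(x_j) within each column.

    Output columns sum to zero.  A single-feature matrix degenerates to an
    all-zero output; a warning is emitted and the result returned.
    """
    frame = _as_frame(m)
    logged = log_transform(frame)
    if frame.shape[0] == 1:
        warnings.warn("CLR on a single-feature matrix degenerates to zeros", stacklevel=2)
    return logged - logged.mean(axis=0)


def center_scale(v) -> np.ndarray:
    """Center to mean 0 and scale to unit sample SD (n-1 denominator)."""
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise DegeneratePredictorError("center_scale needs a 1-D vector with >=2 samples")
    sd = arr.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegeneratePredictorError("constant vector cannot be scaled to unit variance")
    return (arr - arr.mean()) / sd


@dataclass
class TransformedAbundance:
    """A microbial abundance matrix on the log or CLR scale, with provenance."""

    values: pd.DataFrame  # features x samples, log-scale
    domain: str
    rank: str
    transform: str  # "log" | "clr"
    site: str = "pooled"


def transform_abundance(m: MicrobeAbundanceMatrix, method: str) -> TransformedAbundance:
    """Pseudocount + log or CLR, tagged with the matrix provenance."""
    if method not in TRANSFORMS:
        raise ValueError(f"unknown transform {method!r}; expected one of {TRANSFORMS}")
    shifted = add_pseudocount(m.data)
    values = log_transform(shifted) if method == "log" else clr_transform(shifted)
    return TransformedAbundance(values=values, domain=m.domain, rank=m.rank, transform=method, site=m.site)
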