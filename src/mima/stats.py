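"""Small shared statistical primitives."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import ConfigurationError


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Inputs must lie in (0, 1]; outputs are >= raw and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def hypergeom_upper_tail(overlap: int, universe: int, set_a: int, set_b: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set_a, set_b draws)."""
    return float(stats.hypergeom.sf(overlap - 1, universe, set_a, set_b))
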