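"""Compound-gene interactome enrichment screen.

Tests whether each compound's interacting genes over-represent a DEG list
relative to the universal gene set (the union of all compounds' gene sets),
using the hypergeometric upper tail, with Bonferroni adjustment over the
number of compounds tested within one compound class (drugs, food compounds
and expression-perturbing compounds are separate families).  Edge confidence
scores, where present, are ignored by the statistic: membership is
presence/absence.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import CompoundInteractome
from .errors import ConfigurationError
from .stats import hypergeom_upper_tail

log = logging.getLogger("mima.compounds")

_TINY_P = float(np.finfo(float).tiny)


def build_universal_gene_set(interactome: CompoundInteractome) -> frozenset:
    """Union of all compounds' gene sets: every gene interacting with >= 1 compound."""
    if len(interactome) == 0:
        raise ConfigurationError("empty interactome")
    universal = frozenset().union(*interactome.gene_sets.values())
    log.info("universal gene set: %d genes across %d compounds", len(universal), len(interactome))
    return universal


def compound_enrichment(
    degs, interactome: CompoundInteractome, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-compound hypergeometric enrichment of the DEG list.

    DEGs outside the universal gene set are dropped (and counted in the log)
    before testing.  ``p_bonferroni`` multiplies by the number of compounds
    tested; ``significant`` is ``p_bonferroni < alpha``.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    universal = build_universal_gene_set(interactome)
    degs = set(degs)
    degs_in = degs & universal
    dropped = len(degs) - len(degs_in)
    if dropped:
        log.info("%d DEG(s) outside the universal gene set dropped", dropped)
    if not degs_in:
        raise ConfigurationError("no DEGs remain within the universal gene set")

    m = len(universal)
    n_deg = len(degs_in)
    n_tested = len(interactome)
    rows = []
    for compound in sorted(interactome.gene_sets):
        genes = interactome.gene_sets[compound]
        overlap = len(genes & degs_in)
        expected = len(genes) * n_deg / m
        p = float(np.clip(hypergeom_upper_tail(overlap, m, len(genes), n_deg), _TINY_P, 1.0))
        p_bonf = min(1.0, p * n_tested)
        rows.append((compound, len(genes), overlap, expected, p, p_bonf, p_bonf < alpha))
    return pd.DataFrame(
        rows,
        columns=["compound", "n_genes", "overlap", "expected", "p", "p_bonferroni", "significant"],
    ).sort_values(["p", "compound"], kind="mergesort").reset_index(drop=True)


def screen_compound_classes(
    degs_by_cell_type: dict[str, set],
    interactomes: dict[str, CompoundInteractome],
    alpha: float = 0.05,
) -> tuple[dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Run the enrichment per (cell type, compound class) and union the hits.

    Returns the per-combination tables and a deduplicated union of significant
    compounds with provenance (which cell types and classes flagged each).
    """
    if not degs_by_cell_type or not interactomes:
        raise ConfigurationError("need >= 1 cell type and >= 1 compound class")
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    provenance: dict[str, list[str]] = {}
    for cell_type in sorted(degs_by_cell_type):
        for cls in sorted(interactomes):
            try:
                table = compound_enrichment(degs_by_cell_type[cell_type], interactomes[cls], alpha)
            except ConfigurationError as exc:
                log.warning("skipping (%s, %s): %s", cell_type, cls, exc)
                continue
            tables[(cell_type, cls)] = table
            for compound in table.loc[table["significant"], "compound"]:
                provenance.setdefault(compound, []).append(f"{cell_type}/{cls}")
    union = pd.DataFrame(
        [(c, len(src), ";".join(src)) for c, src in sorted(provenance.items())],
        columns=["compound", "n_contexts", "contexts"],
    )
    return tables, union
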