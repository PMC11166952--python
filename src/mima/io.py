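"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with features in rows (first column ``feature_id``) and
sample ids in the header; gene-set collections as GMT; everything else as TSV
with a leading ``#`` comment line declaring the column schema.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .containers import (
    ExpressionMatrix,
    MicrobeAbundanceMatrix,
    PathwayCollection,
    CompoundInteractome,
    parse_sample_metadata,
)
from .errors import FormatError

log = logging.getLogger("mima.io")


def _read_tsv_matrix(path) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s): {dup[:5]}")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)][0]
        raise FormatError(f"{path}: ragged/missing values at feature {bad!r}")
    return frame


def _sample_meta(frame: pd.DataFrame, path, metadata_path=None) -> pd.DataFrame:
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        if not {"crew", "timepoint"} <= set(meta.columns):
            raise FormatError(f"{metadata_path}: sidecar needs 'crew' and 'timepoint' columns")
        missing = set(frame.columns) - set(meta.index)
        if missing:
            raise FormatError(f"{metadata_path}: no metadata for sample(s) {sorted(missing)[:5]}")
        return meta.loc[frame.columns]
    try:
        return parse_sample_metadata(frame.columns)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_expression_matrix(path, cell_type: str | None = None, metadata_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV; cell type defaults to the file stem."""
    frame = _read_tsv_matrix(path)
    meta = _sample_meta(frame, path, metadata_path)
    return ExpressionMatrix(frame, cell_type=cell_type or Path(path).stem, samples=meta)


def read_microbe_matrix(path, domain: str, rank: str, site: str = "pooled") -> MicrobeAbundanceMatrix:
    return MicrobeAbundanceMatrix(_read_tsv_matrix(path), domain=domain, rank=rank, site=site)


def read_matrix(path, kind: str = "expression", **kwargs):
    """Dispatching reader: ``kind`` is ``expression`` or ``microbe``."""
    if kind == "expression":
        return read_expression_matrix(path, **kwargs)
    if kind == "microbe":
        return read_microbe_matrix(path, **kwargs)
    raise FormatError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix, path) -> None:
    frame = matrix.data if hasattr(matrix, "data") else matrix
    frame = frame.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")


def read_gmt(path) -> PathwayCollection:
    """Standard GMT: one set per line, fields name <tab> description <tab> genes..."""
    collection = PathwayCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            name, description, *genes = fields
            if name in collection.sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(g for g in genes if g))
            if len(unique) < len([g for g in genes if g]):
                log.warning("%s:%d: duplicate genes within set %s deduplicated", path, lineno, name)
            collection.sets[name] = unique
            collection.descriptions[name] = description
    return collection


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            description = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_ranking(path) -> pd.Series:
    """Two-column TSV (gene, score) -> descending-score Series."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None, names=["gene", "score"])
    s = pd.Series(frame["score"].to_numpy(dtype=float), index=frame["gene"])
    return s.sort_values(ascending=False)


def write_ranking(ranking: pd.Series, path) -> None:
    ranking.rename("score").rename_axis("gene").to_csv(path, sep="\t", header=False)


def read_interactome(path, compound_class: str = "drug") -> CompoundInteractome:
    """2-column TSV (compound, gene), optional third confidence column."""
    frame = pd.read_csv(path, sep="\t", comment="#", header=None)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: interactome needs >= 2 columns (compound, gene)")
    gene_sets: dict[str, set] = {}
    confidence: dict[tuple[str, str], float] = {}
    for row in frame.itertuples(index=False):
        compound, gene = str(row[0]), str(row[1])
        gene_sets.setdefault(compound, set()).add(gene)
        if len(row) > 2 and pd.notna(row[2]):
            confidence[(compound, gene)] = float(row[2])
    return CompoundInteractome(gene_sets, compound_class=compound_class,
                               confidence=confidence or None)


def write_interactome(interactome: CompoundInteractome, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: compound\tgene\n")
        for compound in sorted(interactome.gene_sets):
            for gene in sorted(interactome.gene_sets[compound]):
                fh.write(f"{compound}\t{gene}\n")


def write_table(frame: pd.DataFrame, path) -> None:
    """TSV with a leading comment line declaring the column schema."""
    with open(path, "w") as fh:
        fh.write("# columns: " + "\t".join(map(str, frame.columns)) + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]
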