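"""In-memory containers for expression, abundance, pathway and interactome data.

Matrices are thin wrappers around a :class:`pandas.DataFrame` with features in
rows and samples in columns.  Sample identifiers follow the ``crew<k>_T<j>``
convention (crew member ``k``, timepoint ``j``); crew and timepoint labels are
parsed out into a metadata frame so downstream mixed models can group on crew.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError

SAMPLE_ID_RE = re.compile(r"^(?P<crew>crew\d+)_(?P<timepoint>T\d+)$")

#: Cell-type labels mirroring a PBMC annotation (aggregate plus 8 subpopulations).
DEFAULT_CELL_TYPES = (
    "PBMC",
    "CD4_T",
    "CD8_T",
    "other_T",
    "B",
    "NK",
    "CD14_Mono",
    "CD16_Mono",
    "DC",
)


def parse_sample_metadata(sample_ids) -> pd.DataFrame:
    """Parse ``crew<k>_T<j>`` sample ids into a (crew, timepoint) metadata frame.

    Raises :class:`FormatError` naming the first offending id.
    """
    rows = []
    for sid in sample_ids:
        m = SAMPLE_ID_RE.match(str(sid))
        if m is None:
            raise FormatError(
                f"sample id {sid!r} does not match the crew<k>_T<j> pattern; "
                "supply a metadata sidecar to use free-form sample names"
            )
        rows.append((sid, m.group("crew"), m.group("timepoint")))
    meta = pd.DataFrame(rows, columns=["sample", "crew", "timepoint"]).set_index("sample")
    return meta


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Pseudo-bulk gene expression for one cell type (genes x samples)."""

    data: pd.DataFrame
    cell_type: str
    samples: pd.DataFrame | None = None  # index = sample id; columns crew, timepoint

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        if self.samples is None:
            self.samples = parse_sample_metadata(self.data.columns)
        missing = set(self.data.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples without metadata: {sorted(missing)[:5]}")
        if self.samples["crew"].isna().any():
            raise FormatError("every sample must carry a crew id")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def crew_ids(self) -> pd.Series:
        """Crew label per sample, aligned to the column order of ``data``."""
        return self.samples.loc[self.data.columns, "crew"]


@dataclass
class MicrobeAbundanceMatrix:
    """Microbial feature abundances (features x samples) for one domain and rank.

    Domain is ``bacteria`` or ``virus``; rank is a taxonomic rank label such as
    ``phylum``/``genus``/``species``.  Body sites are pooled into a single
    matrix unless ``site`` says otherwise.
    """

    data: pd.DataFrame
    domain: str
    rank: str
    site: str = "pooled"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "feature")
        _check_unique(self.data.columns, "sample")
        if self.data.isna().any().any():
            raise FormatError(f"missing entries in {self.domain}/{self.rank} abundance matrix")
        if (self.data.values < 0).any():
            raise FormatError(f"negative abundances in {self.domain}/{self.rank} matrix")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns


@dataclass
class PathwayCollection:
    """Named gene sets (GMT-compatible): name -> ordered list of member genes."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


@dataclass
class CompoundInteractome:
    """Bipartite compound -> gene interaction sets for one compound class."""

    gene_sets: dict[str, frozenset]
    compound_class: str = "drug"
    confidence: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.gene_sets = {c: frozenset(g) for c, g in self.gene_sets.items()}
        empty = [c for c, g in self.gene_sets.items() if not g]
        if empty:
            raise FormatError(f"compound(s) with no interacting genes: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.gene_sets)
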