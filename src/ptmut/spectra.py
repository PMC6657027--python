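"""Amino-acid substitution spectra and their hierarchical clustering.

Each missense change (one amino acid to any of 19 others) is counted and
categorized either by the wild-type residue or by the impacted PTM class
(e.g. "S-phosphorylation" for changes landing on phosphoserines, with
changes on unannotated residues falling into the plain residue rows).
Rows are normalized to proportions, and rows and columns of the
normalized matrix are clustered independently by complete-linkage
agglomeration with Euclidean distance, matching the common heatmap
default.  Output is the ordered matrix plus linkage trees in
nested-bracket text; drawing is left to downstream tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .model import AMINO_ACIDS, MutationRecord, PTMSite

Grouping = Literal["wt_residue", "ptm_class"]
ColumnMode = Literal["to_residue", "change_type"]

#: 380 ordered missense change types A>C, A>D, ...
CHANGE_TYPES = [f"{a}>{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS if a != b]


@dataclass
class SubstitutionMatrix:
    counts: pd.DataFrame  # integer counts, rows = categories
    normalized: pd.DataFrame | None = None
    zero_rows: list[str] = field(default_factory=list)
    grouping: str = "wt_residue"
    #: number of extra row increments from mutations on multiply-annotated
    #: residues (ptm_class grouping only; 0 means counts are conserved)
    fanout_count: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def count_substitutions(
    mutations: Sequence[MutationRecord],
    sites: Sequence[PTMSite] = (),
    grouping: Grouping = "wt_residue",
    column_mode: ColumnMode = "to_residue",
) -> SubstitutionMatrix:
    """Tally missense changes into a category x destination count matrix.

    ``wt_residue`` grouping: one row per wild-type residue letter; every
    record counted exactly once (count conservation).  ``ptm_class``
    grouping: records landing on a PTM site are counted in that class's
    row (a residue bearing two PTM classes contributes to both rows — the
    fan-out is reported); records off any site fall into the plain
    residue rows.
    """
    if grouping not in ("wt_residue", "ptm_class"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if column_mode not in ("to_residue", "change_type"):
        raise ValueError(f"unknown column_mode {column_mode!r}")

    site_classes: dict[tuple[str, int], list[str]] = {}
    if grouping == "ptm_class":
        for s in sites:
            site_classes.setdefault((s.protein_id, s.position), [])
            if s.category not in site_classes[(s.protein_id, s.position)]:
                site_classes[(s.protein_id, s.position)].append(s.category)

    tallies: dict[tuple[str, str], int] = {}
    fanout = 0
    for m in mutations:
        col = m.mut_residue if column_mode == "to_residue" else f"{m.wt_residue}>{m.mut_residue}"
        if grouping == "wt_residue":
            rows = [m.wt_residue]
        else:
            classes = site_classes.get((m.protein_id, m.position), [])
            rows = classes if classes else [m.wt_residue]
            fanout += max(0, len(rows) - 1)
        for row in rows:
            tallies[(row, col)] = tallies.get((row, col), 0) + 1

    row_labels = sorted({r for r, _ in tallies})
    if grouping == "wt_residue":
        row_labels = sorted(set(row_labels) | set(AMINO_ACIDS))
    col_labels = list(AMINO_ACIDS) if column_mode == "to_residue" else CHANGE_TYPES
    counts = pd.DataFrame(0, index=row_labels, columns=col_labels, dtype=int)
    for (row, col), c in tallies.items():
        counts.loc[row, col] = c
    return SubstitutionMatrix(counts=counts, grouping=grouping, fanout_count=fanout)


def normalize_rows(matrix: SubstitutionMatrix) -> SubstitutionMatrix:
    """Divide each nonzero row by its sum; zero rows stay zero and are flagged."""
    counts = matrix.counts
    sums = counts.sum(axis=1)
    zero_rows = [str(r) for r in counts.index[sums == 0]]
    safe = sums.replace(0, 1)
    matrix.normalized = counts.div(safe, axis=0).astype(float)
    matrix.zero_rows = zero_rows
    return matrix


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_tree: str
    col_tree: str


def _linkage_to_brackets(linkage: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a linkage matrix as nested brackets with merge heights."""
    n = len(labels)
    nodes: dict[int, str] = {i: labels[i] for i in range(n)}
    for i, (left, right, height, _) in enumerate(linkage):
        nodes[n + i] = f"({nodes[int(left)]},{nodes[int(right)]}):{height:.6g}"
    return nodes[n + len(linkage) - 1] if len(linkage) else nodes[0]


def cluster_rows_cols(matrix: SubstitutionMatrix) -> ClusterResult:
    """Complete-linkage / Euclidean clustering of rows and columns.

    Operates on the row-normalized matrix (computing it if absent).  The
    leaf order is deterministic: scipy's agglomeration breaks distance
    ties by cluster index, i.e. by input order.
    """
    if matrix.normalized is None:
        normalize_rows(matrix)
    data = matrix.normalized.to_numpy(dtype=float)
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError(f"need >= 2 rows and columns to cluster, got {data.shape}")
    row_link = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    col_link = hierarchy.linkage(pdist(data.T, metric="euclidean"), method="complete")
    row_labels = [str(r) for r in matrix.normalized.index]
    col_labels = [str(c) for c in matrix.normalized.columns]
    row_order = [row_labels[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [col_labels[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        row_tree=_linkage_to_brackets(row_link, row_labels),
        col_tree=_linkage_to_brackets(col_link, col_labels),
    )
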