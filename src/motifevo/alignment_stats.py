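"""Column-level conservation analysis of a protein multiple alignment.

Implements the sequence-logo arithmetic (per-column Shannon entropy and
information content with the Schneider–Stephens small-sample correction
for a 20-letter alphabet), invariant-column detection, coordinate mapping
between a row's ungapped positions and alignment columns, and the
per-sequence motif-occupancy matrix: for each motif in a catalog, anchor
windows are located where a quarter or more of the rows carry a canonical
hit, and every row is then called canonical / variant / absent at each
anchor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from motifevo.io_formats import AMINO_ACIDS, GAP
from motifevo.motif_grammar import (
    DEFAULT_MAX_EDITS,
    MotifPattern,
    classify_variant,
    scan_sequence,
)

__all__ = [
    "AlignmentMatrix",
    "ColumnProfile",
    "column_profiles",
    "invariant_columns",
    "invariant_residue_census",
    "map_seq_to_column",
    "map_column_to_seq",
    "motif_occupancy_matrix",
    "ANCHOR_SUPPORT_FRACTION",
]

LOG2_20 = math.log2(20.0)

#: Fraction of rows that must carry a canonical hit over a column run for
#: that run to become a motif anchor window.
ANCHOR_SUPPORT_FRACTION = 0.25


@dataclass(frozen=True)
class AlignmentMatrix:
    """A rectangular gapped alignment; '-' is the only gap character."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")
        n = len(self.rows[0])
        for i, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise ValueError(f"ragged row {i!r}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @cached_property
    def _row_index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def row(self, seq_id: str) -> str:
        return self.rows[self._row_index[seq_id]]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")

    def column(self, col: int) -> str:
        """Column as a string, 1-based index."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} out of range 1..{self.n_columns}")
        return "".join(row[col - 1] for row in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Residue counts and logo statistics for one alignment column."""

    column: int  # 1-based
    counts: dict[str, int]
    n_nongap: int
    gap_count: int
    entropy_bits: float
    info_bits: float


def _column_entropy_info(counts: Mapping[str, int], n_nongap: int) -> tuple[float, float]:
    if n_nongap == 0:
        return 0.0, 0.0
    h = 0.0
    for c in counts.values():
        f = c / n_nongap
        h -= f * math.log2(f)
    # Schneider–Stephens small-sample correction, alphabet size 20
    e_n = 19.0 / (2.0 * math.log(2.0) * n_nongap)
    info = max(0.0, LOG2_20 - h - e_n)
    return h, info


def column_profiles(aln: AlignmentMatrix) -> list[ColumnProfile]:
    """Per-column residue counts, entropy and small-sample-corrected
    information content.  Gaps are excluded from frequency denominators;
    the unknown residue 'X' is counted as a residue category."""
    profiles: list[ColumnProfile] = []
    for col in range(1, aln.n_columns + 1):
        column = aln.column(col)
        counts: dict[str, int] = {}
        for c in column:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        n_nongap = sum(counts.values())
        h, info = _column_entropy_info(counts, n_nongap)
        profiles.append(
            ColumnProfile(
                column=col,
                counts=counts,
                n_nongap=n_nongap,
                gap_count=aln.n_rows - n_nongap,
                entropy_bits=h,
                info_bits=info,
            )
        )
    return profiles


def invariant_columns(aln: AlignmentMatrix, columns: Sequence[int] | None = None) -> list[int]:
    """Columns in which every row carries the same non-gap residue.

    A gap anywhere disqualifies the column, as does the unknown residue
    'X'.  ``columns`` optionally restricts the census to a subset (e.g.
    the positions resolvable in a structural model); default is all.
    """
    cols = range(1, aln.n_columns + 1) if columns is None else sorted(columns)
    out: list[int] = []
    for col in cols:
        column = aln.column(col)
        first = column[0]
        if first == GAP or first == "X":
            continue
        if all(c == first for c in column):
            out.append(col)
    return out


def invariant_residue_census(
    aln: AlignmentMatrix, residue: str, columns: Sequence[int] | None = None
) -> int:
    """Number of invariant columns whose conserved residue equals ``residue``."""
    if residue not in AMINO_ACIDS:
        raise ValueError(f"{residue!r} is not a canonical amino acid")
    return sum(
        1 for col in invariant_columns(aln, columns) if aln.rows[0][col - 1] == residue
    )


def _seq_to_col_map(row: str) -> list[int]:
    """0-based list: entry k = 0-based column of the row's (k+1)-th residue."""
    return [i for i, c in enumerate(row) if c != GAP]


def map_seq_to_column(aln: AlignmentMatrix, seq_id: str, seq_pos: int) -> int:
    """Alignment column (1-based) of the 1-based ungapped position ``seq_pos``."""
    cols = _seq_to_col_map(aln.row(seq_id))
    if not 1 <= seq_pos <= len(cols):
        raise IndexError(
            f"position {seq_pos} out of range 1..{len(cols)} for row {seq_id!r}"
        )
    return cols[seq_pos - 1] + 1


def map_column_to_seq(aln: AlignmentMatrix, seq_id: str, column: int) -> int | None:
    """Ungapped 1-based position at ``column``, or None on a gap column."""
    row = aln.row(seq_id)
    if not 1 <= column <= aln.n_columns:
        raise IndexError(f"column {column} out of range 1..{aln.n_columns}")
    if row[column - 1] == GAP:
        return None
    return column - row.count(GAP, 0, column - 1)


def motif_occupancy_matrix(
    aln: AlignmentMatrix,
    catalog: Mapping[str, MotifPattern],
    max_edits: int | Mapping[str, int] = DEFAULT_MAX_EDITS,
    anchor_support: float = ANCHOR_SUPPORT_FRACTION,
) -> pd.DataFrame:
    """Per-(sequence, motif-anchor) status table.

    For each pattern, canonical hits are located on the degapped rows and
    projected to alignment columns.  Maximal column runs supported by at
    least ``anchor_support`` of the rows become anchor windows; each row
    is then called at each anchor: ``canonical`` if one of its canonical
    hits overlaps the anchor, else ``variant:<text>`` if its residues
    across the anchor columns classify within the edit budget, else
    ``absent``.  Returns a DataFrame with columns seq_id, motif, anchor,
    col_start, col_end, status, observed, distance.
    """
    if not catalog:
        raise ValueError("empty motif catalog")
    if isinstance(max_edits, int):
        budgets = {name: max_edits for name in catalog}
    else:
        budgets = {name: max_edits.get(name, DEFAULT_MAX_EDITS) for name in catalog}
    n_rows, n_cols = aln.n_rows, aln.n_columns
    records: list[dict] = []
    degapped = {sid: aln.degapped(sid) for sid in aln.ids}
    col_maps = {sid: _seq_to_col_map(aln.row(sid)) for sid in aln.ids}

    for name, pattern in catalog.items():
        budget = budgets[name]
        # canonical hits per row, as 0-based column intervals
        hits: dict[str, list[tuple[int, int, str]]] = {}
        support = np.zeros(n_cols, dtype=int)
        for sid in aln.ids:
            row_hits = []
            cmap = col_maps[sid]
            for m in scan_sequence(degapped[sid], pattern, seq_id=sid):
                c0, c1 = cmap[m.start - 1], cmap[m.end - 1]
                row_hits.append((c0, c1, m.matched_text))
            hits[sid] = row_hits
            covered = np.zeros(n_cols, dtype=bool)
            for c0, c1, _ in row_hits:
                covered[c0 : c1 + 1] = True
            support += covered
        # anchor windows: maximal runs of columns with enough support
        threshold = anchor_support * n_rows
        anchored = support >= threshold
        anchors: list[tuple[int, int]] = []
        c = 0
        while c < n_cols:
            if anchored[c]:
                start = c
                while c < n_cols and anchored[c]:
                    c += 1
                anchors.append((start, c - 1))
            else:
                c += 1
        for a_idx, (a0, a1) in enumerate(anchors, start=1):
            for sid in aln.ids:
                overlapping = [
                    (c0, c1, text)
                    for c0, c1, text in hits[sid]
                    if c0 <= a1 and c1 >= a0
                ]
                if overlapping:
                    c0, c1, text = overlapping[0]
                    status, observed, distance = "canonical", text, 0
                else:
                    window = aln.row(sid)[a0 : a1 + 1].replace(GAP, "")
                    if window and abs(len(window) - len(pattern)) <= budget:
                        call = classify_variant(pattern, window, budget)
                        if call.status == "canonical":
                            status, observed, distance = "canonical", window, 0
                        elif call.status == "absent":
                            status, observed, distance = "absent", window, call.distance
                        else:
                            status, observed, distance = (
                                f"variant:{window}",
                                window,
                                call.distance,
                            )
                    else:
                        status, observed, distance = "absent", window, -1
                records.append(
                    {
                        "seq_id": sid,
                        "motif": name,
                        "anchor": a_idx,
                        "col_start": a0 + 1,
                        "col_end": a1 + 1,
                        "status": status,
                        "observed": observed,
                        "distance": distance,
                    }
                )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "seq_id",
            "motif",
            "anchor",
            "col_start",
            "col_end",
            "status",
            "observed",
            "distance",
        ],
    )


def logo_data(aln: AlignmentMatrix) -> pd.DataFrame:
    """Per column × residue stack heights f_a · info_bits, for logo plotting."""
    rows = []
    for prof in column_profiles(aln):
        for res, cnt in sorted(prof.counts.items()):
            rows.append(
                {
                    "column": prof.column,
                    "residue": res,
                    "height": (cnt / prof.n_nongap) * prof.info_bits,
                }
            )
    return pd.DataFrame.from_records(rows, columns=["column", "residue", "height"])
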