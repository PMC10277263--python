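"""Homologue detection by exact local alignment and phylogenetic profiling.

A query protein is searched against whole proteomes with an exact
Smith–Waterman–Gotoh local aligner (affine gaps, BLOSUM62, BLAST-default
penalties: gap open 11, extend 1).  The best-scoring target per proteome
is thresholded on percent identity (alignment columns, gaps in the
denominator) and query coverage (aligned query span over query length);
the defaults — identity >= 70, coverage > 80 — implement the classic
homologue-selection rule used for selenium-binding-protein screens.
Presence/absence calls across proteomes form a phylogenetic profile that
can be summarized per taxonomic rank.

The dynamic-programming fill is JIT-compiled with numba; the first call
in a fresh process pays a one-off compilation cost of a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from numba import njit

from motifevo.io_formats import SequenceRecord, TaxonRecord

__all__ = [
    "AlignParams",
    "Thresholds",
    "PairwiseAlignment",
    "HomologyCall",
    "ProfileMatrix",
    "align_pair",
    "align_score",
    "identity_and_coverage",
    "call_presence",
    "build_profile",
    "summarize_by_taxon",
    "distribution_stats",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)
_CHAR_TO_IDX = {c: i for i, c in enumerate(_ALPHABET)}
_BLOSUM62_ARR = np.asarray(_BLOSUM62, dtype=np.int32)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap local-alignment parameters (BLAST protein defaults).

    A gap of length k costs ``gap_open + k * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")

    def substitution_array(self) -> np.ndarray:
        if self.matrix == "BLOSUM62":
            return _BLOSUM62_ARR
        mat = substitution_matrices.load(self.matrix)
        if str(mat.alphabet) != _ALPHABET:
            raise ValueError(f"matrix {self.matrix} has an unexpected alphabet")
        return np.asarray(mat, dtype=np.int32)


@dataclass(frozen=True)
class Thresholds:
    """Homologue presence rule: identity >= min_identity_pct (inclusive)
    and coverage > min_coverage_pct (strict)."""

    min_identity_pct: float = 70.0
    min_coverage_pct: float = 80.0


@dataclass(frozen=True)
class PairwiseAlignment:
    query_id: str
    target_id: str
    aligned_query: str
    aligned_target: str
    score: float
    query_span: tuple[int, int]  # 1-based ungapped query positions covered
    target_span: tuple[int, int]

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    @property
    def n_identities(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_target)
            if a == b and a != "-"
        )


@dataclass(frozen=True)
class HomologyCall:
    proteome_id: str
    present: bool
    best_target_id: str | None
    identity_pct: float
    coverage_pct: float
    target_length: int
    score: float = 0.0


@dataclass(frozen=True)
class ProfileMatrix:
    query_id: str
    proteome_ids: tuple[str, ...]
    calls: dict[str, HomologyCall]

    def __post_init__(self) -> None:
        if set(self.proteome_ids) != set(self.calls):
            raise ValueError("calls do not match proteome_ids")

    def presence_vector(self) -> dict[str, bool]:
        return {p: self.calls[p].present for p in self.proteome_ids}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "proteome_id": p,
                    "present": int(c.present),
                    "best_target_id": c.best_target_id or "",
                    "identity_pct": round(c.identity_pct, 2),
                    "coverage_pct": round(c.coverage_pct, 2),
                    "target_length": c.target_length,
                    "score": c.score,
                }
                for p, c in ((p, self.calls[p]) for p in self.proteome_ids)
            ]
        )


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CHAR_TO_IDX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"residue {exc} not in substitution-matrix alphabet") from exc


@njit(cache=True)
def _gotoh_fill(q, t, sub, open_total, extend):  # pragma: no cover - jitted
    """Smith–Waterman–Gotoh fill.  Returns (H, E, F) score matrices.

    H[i, j]: best local alignment score ending at query i / target j.
    E: best score ending with a gap in the query (target residue consumed);
    F: with a gap in the target.  First gap residue costs ``open_total``
    (= gap_open + gap_extend), each further residue ``extend``.
    """
    m, n = q.shape[0], t.shape[0]
    NEG = -10**7
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e = E[i, j - 1] - extend
            e2 = H[i, j - 1] - open_total
            if e2 > e:
                e = e2
            E[i, j] = e
            f = F[i - 1, j] - extend
            f2 = H[i - 1, j] - open_total
            if f2 > f:
                f = f2
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[qi, t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


def align_score(
    query: SequenceRecord | str,
    target: SequenceRecord | str,
    params: AlignParams | None = None,
) -> int:
    """Optimal local alignment score only (no traceback)."""
    params = params or AlignParams()
    q = _encode(query.residues if isinstance(query, SequenceRecord) else query)
    t = _encode(target.residues if isinstance(target, SequenceRecord) else target)
    H, _, _ = _gotoh_fill(
        q, t, params.substitution_array(), params.gap_open + params.gap_extend, params.gap_extend
    )
    return int(H.max())


def align_pair(
    query: SequenceRecord,
    target: SequenceRecord,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Optimal local alignment under affine-gap scoring.

    Tie-breaking is deterministic: among equally scoring end cells the one
    with the smallest query-then-target coordinate is chosen, and the
    traceback prefers substitutions over gap moves, which favors shorter,
    leftmost alignments.
    """
    params = params or AlignParams()
    qs = query.residues
    ts = target.residues
    if not qs or not ts:
        raise ValueError("sequences must be non-empty")
    q = _encode(qs)
    t = _encode(ts)
    sub = params.substitution_array()
    open_total = params.gap_open + params.gap_extend
    extend = params.gap_extend
    H, E, F = _gotoh_fill(q, t, sub, open_total, extend)
    best = int(H.max())
    if best <= 0:
        # no positive-scoring local alignment; report the single best cell
        # as an empty alignment anchored nowhere
        return PairwiseAlignment(
            query_id=query.id,
            target_id=target.id,
            aligned_query="",
            aligned_target="",
            score=0.0,
            query_span=(0, 0),
            target_span=(0, 0),
        )
    ends = np.argwhere(H == best)
    # smallest i+j (shortest), then smallest i, then smallest j
    order = np.lexsort((ends[:, 1], ends[:, 0], ends.sum(axis=1)))
    i, j = map(int, ends[order[0]])
    aq: list[str] = []
    at: list[str] = []
    end_i, end_j = i, j
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            diag = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if h == diag:
                aq.append(qs[i - 1])
                at.append(ts[j - 1])
                i -= 1
                j -= 1
            elif h == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "E":  # gap in query, consume target residue j
            aq.append("-")
            at.append(ts[j - 1])
            if E[i, j] == H[i, j - 1] - open_total:
                state = "H"
            j -= 1
        else:  # state == "F": gap in target, consume query residue i
            aq.append(qs[i - 1])
            at.append("-")
            if F[i, j] == H[i - 1, j] - open_total:
                state = "H"
            i -= 1
    aq.reverse()
    at.reverse()
    return PairwiseAlignment(
        query_id=query.id,
        target_id=target.id,
        aligned_query="".join(aq),
        aligned_target="".join(at),
        score=float(best),
        query_span=(i + 1, end_i),
        target_span=(j + 1, end_j),
    )


def identity_and_coverage(pa: PairwiseAlignment, query_length: int) -> tuple[float, float]:
    """(identity_pct, coverage_pct) for one alignment.

    Identity uses all alignment columns (gap columns in the denominator);
    coverage is the aligned query span divided by the full query length.
    """
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    if pa.n_columns == 0:
        return 0.0, 0.0
    identity = 100.0 * pa.n_identities / pa.n_columns
    coverage = 100.0 * (pa.query_span[1] - pa.query_span[0] + 1) / query_length
    return identity, coverage


def call_presence(
    query: SequenceRecord,
    proteome: Sequence[SequenceRecord],
    proteome_id: str = "",
    thresholds: Thresholds | None = None,
    params: AlignParams | None = None,
) -> HomologyCall:
    """Best-hit presence/absence call of ``query`` in one proteome.

    Only the single best-scoring target is thresholded; ties go to the
    first target in proteome order.
    """
    thresholds = thresholds or Thresholds()
    params = params or AlignParams()
    if not proteome:
        return HomologyCall(
            proteome_id=proteome_id,
            present=False,
            best_target_id=None,
            identity_pct=0.0,
            coverage_pct=0.0,
            target_length=0,
        )
    best_idx, best_score = 0, -1
    for idx, target in enumerate(proteome):
        s = align_score(query, target, params)
        if s > best_score:
            best_idx, best_score = idx, s
    target = proteome[best_idx]
    pa = align_pair(query, target, params)
    identity, coverage = identity_and_coverage(pa, len(query.residues))
    present = (
        identity >= thresholds.min_identity_pct
        and coverage > thresholds.min_coverage_pct
    )
    return HomologyCall(
        proteome_id=proteome_id,
        present=present,
        best_target_id=target.id,
        identity_pct=identity,
        coverage_pct=coverage,
        target_length=len(target.residues),
        score=float(best_score),
    )


def build_profile(
    query: SequenceRecord,
    proteomes: Mapping[str, Sequence[SequenceRecord]] | Sequence[tuple[str, Sequence[SequenceRecord]]],
    thresholds: Thresholds | None = None,
    params: AlignParams | None = None,
) -> ProfileMatrix:
    """Presence/absence profile of ``query`` across proteomes."""
    if isinstance(proteomes, Mapping):
        items = list(proteomes.items())
    else:
        items = list(proteomes)
    ids = [p for p, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({p for p in ids if ids.count(p) > 1})
        raise ValueError(f"duplicate proteome ids: {dupes}")
    calls = {
        pid: call_presence(query, seqs, pid, thresholds, params) for pid, seqs in items
    }
    return ProfileMatrix(query_id=query.id, proteome_ids=tuple(ids), calls=calls)


def summarize_by_taxon(
    profile: ProfileMatrix,
    taxonomy: Sequence[TaxonRecord],
    rank: int = 1,
) -> pd.DataFrame:
    """Presence/absence counts per lineage group at 1-based rank depth.

    Groups are sorted by number of absences, descending; a TOTAL row sums
    all groups.
    """
    tax = {t.taxon_id: t for t in taxonomy}
    missing = [p for p in profile.proteome_ids if p not in tax]
    if missing:
        raise ValueError(f"proteomes without taxonomy records: {missing}")
    groups: dict[str, list[bool]] = {}
    for pid in profile.proteome_ids:
        label = tax[pid].rank(rank)
        groups.setdefault(label, []).append(profile.calls[pid].present)
    rows = [
        {
            "group": label,
            "n_present": sum(flags),
            "n_absent": len(flags) - sum(flags),
        }
        for label, flags in groups.items()
    ]
    rows.sort(key=lambda r: (-r["n_absent"], r["group"]))
    total = {
        "group": "TOTAL",
        "n_present": sum(r["n_present"] for r in rows),
        "n_absent": sum(r["n_absent"] for r in rows),
    }
    return pd.DataFrame.from_records(rows + [total], columns=["group", "n_present", "n_absent"])


def distribution_stats(profile: ProfileMatrix) -> tuple[float, float]:
    """(mean identity %, mean target length) over present calls."""
    present = [c for c in profile.calls.values() if c.present]
    if not present:
        raise ValueError("no present calls in profile")
    mean_id = float(np.mean([c.identity_pct for c in present]))
    mean_len = float(np.mean([c.target_length for c in present]))
    return mean_id, mean_len
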