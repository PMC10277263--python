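"""Degenerate motif grammar: compile, scan, and classify variants.

A motif is written in a small pattern language, one token per position:

* an uppercase letter — that literal residue (``C``),
* ``x`` — any of the 20 canonical residues,
* ``[ABC]`` — an enumerated residue class (``[GKRDN]``),
* ``{phi}`` / ``{pol}`` — a named property class (bulky hydrophobic /
  polar), used by the clathrin-binding box pLφpφp.

The unknown residue ``X`` satisfies no position, including ``x``: an
undetermined residue must never fabricate a motif hit.

Variant classification aligns an observed window against a pattern under
unit edit costs (a residue violating its position spec counts as one
substitution; insertions and deletions count one each) and reports the
minimum-edit decomposition, e.g. CSSS is a one-substitution variant of
CxxC and CSSSC a one-insertion variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from motifevo.io_formats import AMINO_ACIDS, SequenceRecord

__all__ = [
    "MotifPattern",
    "MotifMatch",
    "VariantCall",
    "PatternError",
    "compile_pattern",
    "builtin_catalog",
    "load_catalog",
    "scan_sequence",
    "classify_variant",
    "PROPERTY_CLASSES",
    "DEFAULT_MAX_EDITS",
]

#: Property classes for the clathrin-box style patterns.  φ (bulky
#: hydrophobic) and p (polar) are defined here and may be overridden via
#: ``compile_pattern(..., classes=...)``.  Tyrosine is deliberately a
#: member of both classes.
PROPERTY_CLASSES: dict[str, frozenset[str]] = {
    "phi": frozenset("FILMVWY"),  # bulky hydrophobic
    "pol": frozenset("CDEHKNQRSTY"),  # polar
}

DEFAULT_MAX_EDITS = 2


class PatternError(ValueError):
    """Raised for malformed pattern strings (carries the character offset)."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


@dataclass(frozen=True)
class PositionSpec:
    """One pattern position: the residues that satisfy it, plus a display token."""

    kind: str  # 'literal' | 'any' | 'enum' | 'prop'
    allowed: frozenset[str]
    token: str

    def matches(self, residue: str) -> bool:
        return residue in self.allowed


@dataclass(frozen=True)
class MotifPattern:
    name: str
    positions: tuple[PositionSpec, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError(f"pattern {self.name!r} has no positions")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    def matches_window(self, window: str) -> bool:
        return len(window) == len(self.positions) and all(
            spec.matches(c) for spec, c in zip(self.positions, window)
        )

    def __str__(self) -> str:
        return "".join(p.token for p in self.positions)


@dataclass(frozen=True)
class MotifMatch:
    """A pattern occurrence; coordinates are 1-based inclusive."""

    pattern_name: str
    seq_id: str
    start: int
    end: int
    matched_text: str


@dataclass(frozen=True)
class VariantCall:
    """Classified deviation of an observed window from a canonical motif.

    ``edits`` holds (1-based pattern position, pattern token or '-',
    observed residue or '-') triples; ``distance`` is their count.
    """

    pattern_name: str
    observed: str
    status: str  # canonical | substitution | insertion | deletion | absent
    edits: tuple[tuple[int, str, str], ...]
    distance: int


def compile_pattern(
    name: str,
    dsl_string: str,
    classes: Mapping[str, frozenset[str]] | None = None,
) -> MotifPattern:
    """Compile a pattern string into a :class:`MotifPattern`.

    >>> p = compile_pattern("starDEL", "[GKRDN]DEL")
    >>> len(p)
    4
    """
    class_table = dict(PROPERTY_CLASSES)
    if classes:
        class_table.update({k: frozenset(v) for k, v in classes.items()})
    if not dsl_string:
        raise PatternError("empty pattern string", 0)
    positions: list[PositionSpec] = []
    i = 0
    n = len(dsl_string)
    while i < n:
        c = dsl_string[i]
        if c == "x":
            positions.append(PositionSpec("any", frozenset(AMINO_ACIDS), "x"))
            i += 1
        elif c.isupper() and c in AMINO_ACIDS:
            positions.append(PositionSpec("literal", frozenset(c), c))
            i += 1
        elif c == "[":
            j = dsl_string.find("]", i)
            if j < 0:
                raise PatternError("unbalanced '['", i)
            members = dsl_string[i + 1 : j]
            if not members:
                raise PatternError("empty residue class '[]'", i)
            bad = set(members) - AMINO_ACIDS
            if bad:
                raise PatternError(f"non-residue characters {sorted(bad)} in class", i)
            positions.append(
                PositionSpec("enum", frozenset(members), f"[{members}]")
            )
            i = j + 1
        elif c == "{":
            j = dsl_string.find("}", i)
            if j < 0:
                raise PatternError("unbalanced '{'", i)
            cname = dsl_string[i + 1 : j]
            if cname not in class_table:
                raise PatternError(f"unknown property class {cname!r}", i)
            positions.append(PositionSpec("prop", class_table[cname], "{%s}" % cname))
            i = j + 1
        else:
            raise PatternError(f"unexpected character {c!r}", i)
    return MotifPattern(name=name, positions=tuple(positions), source=dsl_string)


#: Canonical motif catalog: the CC selenium-binding motif, the
#: thioredoxin-like CxxC redox motif and its CSSC instance, the *DEL
#: endoplasmic-reticulum retention signal, the HxD/HxxD metal-binding
#: motifs, the HxxHC metal-coordination motif and the clathrin-binding box.
BUILTIN_CATALOG_DSL: dict[str, str] = {
    "CC": "CC",
    "CxxC": "CxxC",
    "CSSC": "CSSC",
    "starDEL": "[GKRDN]DEL",
    "HxD": "HxD",
    "HxxD": "HxxD",
    "HxxHC": "HxxHC",
    "clathrin_box": "{pol}L{phi}{pol}{phi}{pol}",
}


def builtin_catalog() -> dict[str, MotifPattern]:
    return {name: compile_pattern(name, dsl) for name, dsl in BUILTIN_CATALOG_DSL.items()}


def load_catalog(path) -> tuple[dict[str, MotifPattern], dict[str, int]]:
    """Load a motif catalog from a YAML config.

    Format: ``{motifs: {name: {pattern: DSL, max_edits: int}}, classes:
    {phi: "FILMVWY", ...}}``; ``classes`` and per-motif ``max_edits`` are
    optional.  Returns (patterns, per-motif max_edits).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    classes = {
        k: frozenset(v) for k, v in (cfg.get("classes") or {}).items()
    } or None
    patterns: dict[str, MotifPattern] = {}
    max_edits: dict[str, int] = {}
    for name, entry in cfg["motifs"].items():
        if isinstance(entry, str):
            entry = {"pattern": entry}
        patterns[name] = compile_pattern(name, entry["pattern"], classes=classes)
        max_edits[name] = int(entry.get("max_edits", DEFAULT_MAX_EDITS))
    return patterns, max_edits


def scan_sequence(seq: SequenceRecord | str, pattern: MotifPattern, seq_id: str | None = None) -> list[MotifMatch]:
    """All windows of ``seq`` satisfying ``pattern``, in ascending start order.

    Overlapping and nested occurrences are all reported.  Coordinates are
    1-based inclusive.
    """
    if isinstance(seq, SequenceRecord):
        residues, sid = seq.residues, seq.id
    else:
        residues, sid = seq, (seq_id or "")
    m = len(pattern)
    matches: list[MotifMatch] = []
    # precompute per-position allowed sets for the hot loop
    specs = pattern.positions
    for start in range(len(residues) - m + 1):
        window = residues[start : start + m]
        ok = True
        for spec, c in zip(specs, window):
            if c not in spec.allowed:
                ok = False
                break
        if ok:
            matches.append(
                MotifMatch(
                    pattern_name=pattern.name,
                    seq_id=sid,
                    start=start + 1,
                    end=start + m,
                    matched_text=window,
                )
            )
    return matches


def _edit_dp(pattern: MotifPattern, window: str):
    """Minimum-edit DP table aligning the full pattern to the full window.

    Costs: residue satisfying its spec 0, violating 1 (substitution),
    insertion/deletion 1.  Returns (distance, edits) with a deterministic
    traceback preferring substitution/match over insertion over deletion,
    which also yields the leftmost edit placement among cost ties.
    """
    m, n = len(pattern), len(window)
    INF = m + n + 1
    dp = [[INF] * (n + 1) for _ in range(m + 1)]
    dp[0][0] = 0
    for i in range(1, m + 1):
        dp[i][0] = i
    for j in range(1, n + 1):
        dp[0][j] = j
    specs = pattern.positions
    for i in range(1, m + 1):
        allowed = specs[i - 1].allowed
        row, prev = dp[i], dp[i - 1]
        for j in range(1, n + 1):
            sub = prev[j - 1] + (0 if window[j - 1] in allowed else 1)
            ins = row[j - 1] + 1  # window residue j inserted
            dele = prev[j] + 1  # pattern position i deleted
            row[j] = min(sub, ins, dele)
    # traceback
    edits: list[tuple[int, str, str]] = []
    i, j = m, n
    while i > 0 or j > 0:
        cur = dp[i][j]
        if i > 0 and j > 0:
            cost = 0 if window[j - 1] in specs[i - 1].allowed else 1
            if dp[i - 1][j - 1] + cost == cur:
                if cost:
                    edits.append((i, specs[i - 1].token, window[j - 1]))
                i, j = i - 1, j - 1
                continue
        if j > 0 and dp[i][j - 1] + 1 == cur:
            edits.append((i + 1, "-", window[j - 1]))  # insertion before pattern pos i+1
            j -= 1
            continue
        # deletion of pattern position i
        edits.append((i, specs[i - 1].token, "-"))
        i -= 1
    edits.reverse()
    return dp[m][n], tuple(edits)


def classify_variant(pattern: MotifPattern, window: str, max_edits: int = DEFAULT_MAX_EDITS) -> VariantCall:
    """Classify ``window`` as canonical / variant / absent for ``pattern``.

    The status summarizes the edit composition of the minimum-edit
    alignment; mixed compositions take the majority edit type, ties broken
    substitution > insertion > deletion.  Distances above ``max_edits``
    yield status ``absent``.
    """
    bad = set(window) - AMINO_ACIDS - {"X"}
    if bad:
        raise ValueError(f"window contains non-residue characters: {sorted(bad)}")
    distance, edits = _edit_dp(pattern, window)
    if distance == 0:
        status = "canonical"
    elif distance > max_edits:
        status = "absent"
    else:
        kinds = []
        for pos, spec_tok, obs in edits:
            if spec_tok == "-":
                kinds.append("insertion")
            elif obs == "-":
                kinds.append("deletion")
            else:
                kinds.append("substitution")
        priority = {"substitution": 0, "insertion": 1, "deletion": 2}
        status = max(
            set(kinds), key=lambda k: (kinds.count(k), -priority[k])
        )
    return VariantCall(
        pattern_name=pattern.name,
        observed=window,
        status=status,
        edits=edits,
        distance=distance,
    )
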