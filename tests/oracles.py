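"""Independent brute-force oracles used by the test suite.

Each oracle deliberately re-derives its quantity by enumeration rather
than dynamic programming or set recursion, so it shares no algorithmic
shortcuts with the implementation it checks.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence


# ---------------------------------------------------------------- motif scan
def brute_scan(residues: str, pattern) -> list[tuple[int, int, str]]:
    """All pattern occurrences by testing every window position by position."""
    m = len(pattern.positions)
    out = []
    for start in range(len(residues) - m + 1):
        window = residues[start : start + m]
        if all(c in spec.allowed for spec, c in zip(pattern.positions, window)):
            out.append((start + 1, start + m, window))
    return out


# ------------------------------------------------------------- edit distance
def brute_edit_distance(pattern, window: str) -> int:
    """Minimum edits aligning pattern to window by exhaustive path recursion."""
    specs = pattern.positions
    best = [len(specs) + len(window) + 1]

    def go(i: int, j: int, cost: int) -> None:
        if cost >= best[0]:
            return
        if i == len(specs) and j == len(window):
            best[0] = cost
            return
        if i < len(specs) and j < len(window):
            go(i + 1, j + 1, cost + (0 if window[j] in specs[i].allowed else 1))
        if j < len(window):
            go(i, j + 1, cost + 1)  # insertion
        if i < len(specs):
            go(i + 1, j, cost + 1)  # deletion

    go(0, 0, 0)
    return best[0]


# ------------------------------------------------------------ local alignment
def brute_local_score(
    q: str,
    t: str,
    sub: Mapping[tuple[str, str], int],
    open_total: int,
    extend: int,
) -> int:
    """Best local affine-gap score by enumerating every alignment path.

    Paths may start and end anywhere; the score of every prefix of every
    path is considered (an optimal local alignment never starts or ends
    with a gap column, but recording prefixes costs nothing and keeps the
    oracle assumption-free).
    """
    m, n = len(q), len(t)
    best = 0

    def go(i: int, j: int, score: int, gapstate: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < m and j < n:
            go(i + 1, j + 1, score + sub[(q[i], t[j])], 0)
        if i < m:
            go(i + 1, j, score - (extend if gapstate == 1 else open_total), 1)
        if j < n:
            go(i, j + 1, score - (extend if gapstate == 2 else open_total), 2)

    for i0 in range(m):
        for j0 in range(n):
            go(i0, j0, 0, 0)
    return best


# ------------------------------------------------------------ small parsimony
def random_topology(labels: Sequence[str], rng) -> tuple:
    """Random rooted binary topology over ``labels`` as nested tuples."""
    nodes: list = list(labels)
    while len(nodes) > 1:
        i = int(rng.integers(len(nodes)))
        a = nodes.pop(i)
        j = int(rng.integers(len(nodes)))
        b = nodes.pop(j)
        nodes.append((a, b))
    return nodes[0]


def topology_to_newick(top) -> str:
    def fmt(node) -> str:
        if isinstance(node, tuple):
            return "(" + ",".join(fmt(c) for c in node) + ")"
        return str(node)

    return fmt(top) + ";"


def brute_fitch(top, states: Mapping[str, str]) -> int:
    """Minimum state changes by enumerating every ancestral assignment."""
    alphabet = sorted(set(states.values()))
    internals: list[tuple] = []

    def collect(node) -> None:
        if isinstance(node, tuple):
            internals.append(node)
            for c in node:
                collect(c)

    collect(top)
    index = {id(n): k for k, n in enumerate(internals)}

    def changes(assign: Sequence[str]) -> int:
        def state_of(node) -> str:
            return assign[index[id(node)]] if isinstance(node, tuple) else states[node]

        total = 0
        for node in internals:
            s = state_of(node)
            for child in node:
                if state_of(child) != s:
                    total += 1
        return total

    return min(
        changes(assign)
        for assign in itertools.product(alphabet, repeat=len(internals))
    )
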