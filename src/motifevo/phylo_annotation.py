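"""Motif gain/loss mapping on a phylogeny by small parsimony.

Per-leaf motif states (canonical, a named variant form, or absent) are
treated as unordered characters and the minimum number of state changes
on a rooted tree is computed with Fitch set operations, generalized to
multifurcations (Hartigan's extension: at each internal node the states
shared by the largest number of child sets are kept, and each child set
missing all of them contributes one change).  The tree is used as rooted
exactly as parsed — no re-rooting — matching pipelines that root with a
designated outgroup.

A deterministic top-down pass produces one optimal ancestral labeling
(parent state reused when allowed, otherwise the first child's preferred
state), from which per-branch change lists and clade summaries are
derived.  The change count itself is independent of tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from motifevo.io_formats import write_newick

__all__ = [
    "node_key",
    "assign_node_keys",
    "fitch_minimum_changes",
    "motif_event_report",
    "clade_consistency",
    "export_annotation",
    "tip_state_tables",
    "coarsen_states",
]

PRESENT = "present"
ABSENT = "absent"


def node_key(node: dendropy.Node) -> str:
    """Stable identifier for a node: its taxon/internal label if any."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return getattr(node, "_motifevo_key", "")


def assign_node_keys(tree: dendropy.Tree) -> None:
    """Give unlabeled internal nodes stable preorder keys (node1, node2, ...)."""
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None and not node.label:
            counter += 1
            node._motifevo_key = f"node{counter}"


def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon else (node.label or "")


def fitch_minimum_changes(
    tree: dendropy.Tree, states: Mapping[str, str]
) -> tuple[int, dict[str, str]]:
    """Minimum state changes on ``tree`` and one optimal ancestral labeling.

    ``states`` maps every leaf label to its state string.  Returns
    (min_changes, labeling) where labeling maps node keys (leaf labels and
    internal-node keys) to states.
    """
    assign_node_keys(tree)
    leaves = [n for n in tree.leaf_node_iter()]
    missing = [_leaf_label(n) for n in leaves if _leaf_label(n) not in states]
    if missing:
        raise ValueError(f"leaves without a state: {sorted(missing)}")

    changes = 0
    node_sets: dict[int, frozenset[str]] = {}
    # deterministic preference order per node: states ordered by first
    # appearance scanning children left to right
    pref_order: dict[int, list[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states[_leaf_label(node)]
            node_sets[id(node)] = frozenset([s])
            pref_order[id(node)] = [s]
        else:
            children = node.child_nodes()
            count: dict[str, int] = {}
            order: list[str] = []
            for child in children:
                for s in pref_order[id(child)]:
                    if s in node_sets[id(child)]:
                        if s not in count:
                            order.append(s)
                        count[s] = count.get(s, 0) + 1
            k = max(count.values())
            keep = frozenset(s for s, c in count.items() if c == k)
            node_sets[id(node)] = keep
            pref_order[id(node)] = [s for s in order if s in keep]
            changes += len(children) - k

    labeling: dict[str, str] = {}
    chosen: dict[int, str] = {}
    for node in tree.preorder_node_iter():
        nset = node_sets[id(node)]
        if node.parent_node is None:
            state = pref_order[id(node)][0]
        else:
            parent_state = chosen[id(node.parent_node)]
            state = parent_state if parent_state in nset else pref_order[id(node)][0]
        chosen[id(node)] = state
        labeling[node_key(node)] = state
    return changes, labeling


def tip_state_tables(occupancy: pd.DataFrame) -> dict[tuple[str, int], dict[str, str]]:
    """Split a motif-occupancy table into per-(motif, anchor) tip states."""
    tables: dict[tuple[str, int], dict[str, str]] = {}
    for (motif, anchor), grp in occupancy.groupby(["motif", "anchor"], sort=True):
        tables[(motif, int(anchor))] = dict(zip(grp["seq_id"], grp["status"]))
    return tables


def coarsen_states(states: Mapping[str, str]) -> dict[str, str]:
    """Collapse canonical and variant forms into a binary present/absent."""
    return {
        leaf: (ABSENT if s == ABSENT else PRESENT) for leaf, s in states.items()
    }


def motif_event_report(
    tree: dendropy.Tree,
    occupancy: pd.DataFrame,
    binary: bool = False,
) -> pd.DataFrame:
    """Per motif anchor: parsimony change count, root state, change branches.

    ``occupancy`` is the table produced by
    :func:`motifevo.alignment_stats.motif_occupancy_matrix`; its seq_ids
    must be exactly the tree's leaves.  With ``binary=True`` variant forms
    are collapsed into presence before counting.  Change branches are
    reported as ``parent->child`` node keys under the deterministic
    optimal labeling.
    """
    leaf_labels = {n.taxon.label for n in tree.leaf_node_iter() if n.taxon}
    matrix_ids = set(occupancy["seq_id"])
    if matrix_ids != leaf_labels:
        raise ValueError(
            f"leaf mismatch: only in tree {sorted(leaf_labels - matrix_ids)}, "
            f"only in matrix {sorted(matrix_ids - leaf_labels)}"
        )
    rows = []
    for (motif, anchor), states in tip_state_tables(occupancy).items():
        if binary:
            states = coarsen_states(states)
        n_changes, labeling = fitch_minimum_changes(tree, states)
        branches = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            ps = labeling[node_key(node.parent_node)]
            cs = labeling[node_key(node)]
            if ps != cs:
                branches.append(f"{node_key(node.parent_node)}->{node_key(node)}")
        root = tree.seed_node
        rows.append(
            {
                "motif": motif,
                "anchor": anchor,
                "min_changes": n_changes,
                "root_state": labeling[node_key(root)],
                "change_branches": ";".join(branches),
            }
        )
    return pd.DataFrame.from_records(
        rows, columns=["motif", "anchor", "min_changes", "root_state", "change_branches"]
    )


def clade_consistency(
    tree: dendropy.Tree, states: Mapping[str, str], clade: set[str]
) -> bool:
    """True iff ``clade`` is monophyletic and shares a single state."""
    leaf_labels = {n.taxon.label for n in tree.leaf_node_iter() if n.taxon}
    unknown = clade - leaf_labels
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if not clade:
        raise ValueError("empty clade")
    clade_states = {states[l] for l in clade}
    if len(clade_states) != 1:
        return False
    mrca = tree.mrca(taxon_labels=list(clade))
    descendants = {n.taxon.label for n in mrca.leaf_iter() if n.taxon}
    return descendants == clade


def export_annotation(
    tree: dendropy.Tree,
    occupancy: pd.DataFrame,
    out_prefix,
) -> tuple[Path, Path]:
    """Write per-leaf state TSV and a Newick copy for tree-annotation tools.

    Produces ``<prefix>.states.tsv`` (one row per leaf, one column per
    motif anchor, catalog order preserved) and ``<prefix>.nwk``.
    """
    out_prefix = Path(out_prefix)
    leaf_labels = [n.taxon.label for n in tree.leaf_node_iter() if n.taxon]
    tables = tip_state_tables(occupancy)
    missing = [
        leaf
        for leaf in leaf_labels
        for table in tables.values()
        if leaf not in table
    ]
    if missing:
        raise ValueError(f"leaves missing from occupancy matrix: {sorted(set(missing))}")
    # preserve catalog (file) order of motifs, then anchor order
    motif_order = list(dict.fromkeys(occupancy["motif"]))
    columns = sorted(tables, key=lambda ma: (motif_order.index(ma[0]), ma[1]))
    tsv_path = out_prefix.with_suffix(".states.tsv")
    with open(tsv_path, "w") as fh:
        header = ["leaf"] + [f"{m}_a{a}" for m, a in columns]
        fh.write("\t".join(header) + "\n")
        for leaf in leaf_labels:
            fh.write(
                "\t".join([leaf] + [tables[ma][leaf] for ma in columns]) + "\n"
            )
    nwk_path = out_prefix.with_suffix(".nwk")
    write_newick(tree, nwk_path)
    return tsv_path, nwk_path
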