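"""Protein-family simulator with known motif-evolution ground truth.

A root protein of configurable length (default 479 residues, the mean
length of the selenium-binding-protein homologue set this package
emulates) is evolved along a rooted tree.  Each branch applies

* per-site substitutions with probability ``subst_prob_per_branch``
  (uniform replacement among the other 19 residues, a Jukes–Cantor-like
  20-state model), and
* ``Poisson(indel_rate)`` indel events of geometric length,

everywhere except inside *protected* implant windows: short motifs
(CC, CSSC, KDEL, ...) written into the root sequence that change only
through designated *switch* events on designated branches (e.g. CSSC →
CSSS on one internal branch).  Every non-absent leaf also gets a decoy
proteome so that presence/absence profiling has ground truth.

The substitution model is deliberately simple so the expected leaf-root
identity has a closed form: after d branches at per-site probability p,

    E[identity] = 1/20 + (19/20) * (1 - 20 p / 19)**d,

which :func:`subst_prob_for_expected_identity` inverts; the default
``subst_prob_per_branch`` is calibrated so a depth-4 balanced tree yields
~58% expected identity, matching the 58.2% mean identity of the real
homologue set.  All randomness flows from a single integer seed; outputs
are byte-identical across runs with the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from motifevo.io_formats import (
    SequenceRecord,
    TaxonRecord,
    write_fasta,
    write_newick,
    write_taxonomy,
)
from motifevo.motif_grammar import compile_pattern, classify_variant
from motifevo.phylo_annotation import assign_node_keys, node_key

__all__ = [
    "Implant",
    "Switch",
    "SimulationConfig",
    "GroundTruth",
    "simulate_family",
    "make_decoys",
    "write_simulation",
    "expected_identity",
    "subst_prob_for_expected_identity",
    "balanced_tree_newick",
    "default_implants",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(_AA.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class Implant:
    """A motif written into the root sequence at a fixed position."""

    motif_name: str
    canonical_text: str
    root_position: int  # 1-based start in the root sequence
    protected: bool = True


@dataclass(frozen=True)
class Switch:
    """A designed motif change on one branch (identified by child node key)."""

    motif_name: str
    branch_id: str
    new_text: str


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_leaves: int = 16
    tree_mode: str = "random_yule"  # or "fixed_newick"
    newick: str | None = None
    root_length: int = 479
    subst_prob_per_branch: float = 0.1282  # depth-4 expected identity ~58%
    indel_rate: float = 0.5  # Poisson events per branch
    mean_indel_length: float = 3.0
    implants: tuple[Implant, ...] = ()
    switches: tuple[Switch, ...] = ()
    absent_leaves: frozenset[str] = frozenset()
    n_decoys: int = 20
    max_switch_edits: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.subst_prob_per_branch < 1:
            raise ValueError("subst_prob_per_branch must be in [0, 1)")
        if self.indel_rate < 0 or self.mean_indel_length < 1:
            raise ValueError("invalid indel parameters")
        if self.tree_mode not in ("random_yule", "fixed_newick"):
            raise ValueError(f"unknown tree_mode {self.tree_mode!r}")
        if self.tree_mode == "fixed_newick" and not self.newick:
            raise ValueError("fixed_newick mode requires a newick string")
        # implant windows must fit and not overlap
        spans = []
        for imp in self.implants:
            start = imp.root_position
            end = start + len(imp.canonical_text) - 1
            if start < 1 or end > self.root_length:
                raise ValueError(
                    f"implant {imp.motif_name} at {start}-{end} outside root of "
                    f"length {self.root_length}"
                )
            spans.append((start, end, imp.motif_name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping implants {n1} and {n2}")
        names = {imp.motif_name for imp in self.implants}
        if len(names) != len(self.implants):
            raise ValueError("duplicate implant motif names")
        for sw in self.switches:
            if sw.motif_name not in names:
                raise ValueError(f"switch references unknown motif {sw.motif_name!r}")
            canonical = next(
                i.canonical_text for i in self.implants if i.motif_name == sw.motif_name
            )
            pat = compile_pattern(sw.motif_name, canonical)
            dist = classify_variant(pat, sw.new_text, max_edits=len(canonical) + len(sw.new_text)).distance
            if dist > self.max_switch_edits:
                raise ValueError(
                    f"switch text {sw.new_text!r} is {dist} edits from canonical "
                    f"{canonical!r} (max {self.max_switch_edits})"
                )


@dataclass
class GroundTruth:
    """Everything the simulator knows that downstream analyses must recover."""

    motif_states: dict[tuple[str, str], str]  # (leaf, motif) -> state string
    motif_positions: dict[tuple[str, str], int]  # (leaf, motif) -> 1-based start
    motif_texts: dict[tuple[str, str], str]
    switch_branches: dict[str, list[str]]  # motif -> ["parent->child", ...]
    presence: dict[str, bool]  # leaf/proteome -> family present
    identity_to_root: dict[str, float]  # leaf -> realized identity
    root_sequence: str = ""


def expected_identity(subst_prob: float, depth: int) -> float:
    """Closed-form expected leaf-root identity after ``depth`` branches."""
    return 1.0 / 20.0 + (19.0 / 20.0) * (1.0 - 20.0 * subst_prob / 19.0) ** depth


def subst_prob_for_expected_identity(identity: float, depth: int) -> float:
    """Per-branch substitution probability giving the target expected identity."""
    if not 0.05 < identity <= 1.0:
        raise ValueError("identity must be in (0.05, 1]")
    base = (identity - 0.05) / 0.95
    return (19.0 / 20.0) * (1.0 - base ** (1.0 / depth))


def balanced_tree_newick(depth: int) -> str:
    """Fully balanced binary tree of 2**depth leaves L1..Ln, unit branches."""

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"L{lo + 1}"
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)})"

    return build(0, 2**depth) + ";"


def default_implants(root_length: int = 479) -> tuple[Implant, ...]:
    """Motif layout emulating the selenium-binding-protein architecture:
    an N-terminal CC pair, a KDEL retention signal, a CSSC redox motif,
    an HxD metal site, an HxxHC site and a clathrin-binding box."""
    implants = (
        Implant("CC", "CC", 20),
        Implant("starDEL", "KDEL", 110),
        Implant("CSSC", "CSSC", 130),
        Implant("HxD", "HID", 150),
        Implant("HxxHC", "HSSHC", 210),
        Implant("clathrin_box", "SLFSFS", 380),
    )
    last = max(i.root_position + len(i.canonical_text) - 1 for i in implants)
    if last > root_length:
        raise ValueError(f"root_length {root_length} too short for default implants")
    return implants


def _random_yule_tree(n_leaves: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random topology by uniform leaf splitting (Yule process order)."""
    tree = dendropy.Tree()
    tree.is_rooted = True
    leaves = [tree.seed_node]
    while len(leaves) < n_leaves:
        idx = int(rng.integers(len(leaves)))
        node = leaves.pop(idx)
        left = node.new_child(edge_length=1.0)
        right = node.new_child(edge_length=1.0)
        leaves.extend([left, right])
    ns = tree.taxon_namespace
    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = ns.new_taxon(f"L{k}")
    return tree


def _build_tree(config: SimulationConfig, rng: np.random.Generator) -> dendropy.Tree:
    if config.tree_mode == "fixed_newick":
        from motifevo.io_formats import parse_newick_string

        tree = parse_newick_string(config.newick)
    else:
        tree = _random_yule_tree(config.n_leaves, rng)
    assign_node_keys(tree)
    return tree


class _Lineage:
    """Mutable sequence state during the tree walk.

    ``origins[k]`` is the 0-based root position the k-th residue descends
    from (-1 for inserted residues); ``implant_ids[k]`` marks residues
    belonging to implant windows.
    """

    __slots__ = ("chars", "origins", "implant_ids")

    def __init__(self, chars: list[str], origins: list[int], implant_ids: list[int]):
        self.chars = chars
        self.origins = origins
        self.implant_ids = implant_ids

    def copy(self) -> "_Lineage":
        return _Lineage(list(self.chars), list(self.origins), list(self.implant_ids))


def _apply_switch(lin: _Lineage, implant_idx: int, implant: Implant, new_text: str) -> None:
    idxs = [k for k, i in enumerate(lin.implant_ids) if i == implant_idx]
    if not idxs:  # window lost (only possible for unprotected implants)
        return
    start = idxs[0]
    root0 = implant.root_position - 1
    for k in reversed(idxs):  # robust to windows split by prior indels
        del lin.chars[k], lin.origins[k], lin.implant_ids[k]
    lin.chars[start:start] = list(new_text)
    lin.origins[start:start] = [
        root0 + k if k < len(implant.canonical_text) else -1
        for k in range(len(new_text))
    ]
    lin.implant_ids[start:start] = [implant_idx] * len(new_text)


def _evolve_branch(
    lin: _Lineage,
    config: SimulationConfig,
    protected_ids: frozenset[int],
    rng: np.random.Generator,
) -> None:
    # substitutions at unprotected sites
    p = config.subst_prob_per_branch
    if p > 0:
        n = len(lin.chars)
        hits = np.flatnonzero(rng.random(n) < p)
        for k in hits:
            if lin.implant_ids[k] in protected_ids:
                continue
            current = lin.chars[k]
            choices = _AA.replace(current, "") if current in _AA else _AA
            lin.chars[k] = choices[int(rng.integers(len(choices)))]
    # indel events, never inside protected windows
    if config.indel_rate > 0:
        n_events = int(rng.poisson(config.indel_rate))
        for _ in range(n_events):
            is_insertion = bool(rng.random() < 0.5)
            length = int(rng.geometric(1.0 / config.mean_indel_length))
            n = len(lin.chars)
            if is_insertion:
                # gap positions strictly inside a protected window are barred
                allowed = [
                    g
                    for g in range(n + 1)
                    if not (
                        0 < g < n
                        and lin.implant_ids[g - 1] == lin.implant_ids[g]
                        and lin.implant_ids[g] in protected_ids
                    )
                ]
                g = allowed[int(rng.integers(len(allowed)))]
                ins = [_AA[int(rng.integers(20))] for _ in range(length)]
                lin.chars[g:g] = ins
                lin.origins[g:g] = [-1] * length
                lin.implant_ids[g:g] = [-1] * length
            else:
                unprotected = [
                    k for k in range(n) if lin.implant_ids[k] not in protected_ids
                ]
                if not unprotected:
                    continue
                start = unprotected[int(rng.integers(len(unprotected)))]
                end = start
                while (
                    end - start + 1 < length
                    and end + 1 < n
                    and lin.implant_ids[end + 1] not in protected_ids
                ):
                    end += 1
                if len(lin.chars) - (end - start + 1) < 1:
                    continue  # never delete the whole sequence
                del lin.chars[start : end + 1]
                del lin.origins[start : end + 1]
                del lin.implant_ids[start : end + 1]


def simulate_family(
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], dendropy.Tree, dict[str, list[SequenceRecord]], GroundTruth]:
    """Evolve a protein family along a tree.

    Returns (leaf sequences, tree, proteomes, ground truth).  Proteomes
    map each leaf label to its sequence list: the leaf's family sequence
    (omitted for ``absent_leaves``) plus ``n_decoys`` decoy proteins that
    are guaranteed not to satisfy the default presence rule against the
    root sequence.
    """
    rng = np.random.default_rng(config.seed)
    tree = _build_tree(config, rng)
    leaf_labels = [n.taxon.label for n in tree.leaf_node_iter()]
    unknown_absent = config.absent_leaves - set(leaf_labels)
    if unknown_absent:
        raise ValueError(f"absent_leaves not in tree: {sorted(unknown_absent)}")
    node_keys = {node_key(n) for n in tree.preorder_node_iter()}
    for sw in config.switches:
        if sw.branch_id not in node_keys or sw.branch_id == node_key(tree.seed_node):
            raise ValueError(f"switch branch {sw.branch_id!r} is not a non-root node key")

    # root sequence with implants written in
    chars = [_AA[int(rng.integers(20))] for _ in range(config.root_length)]
    origins = list(range(config.root_length))
    implant_ids = [-1] * config.root_length
    for idx, imp in enumerate(config.implants):
        s = imp.root_position - 1
        for k, ch in enumerate(imp.canonical_text):
            chars[s + k] = ch
            implant_ids[s + k] = idx
    root_chars = list(chars)
    protected_ids = frozenset(
        idx for idx, imp in enumerate(config.implants) if imp.protected
    )
    switches_by_branch: dict[str, list[Switch]] = {}
    for sw in config.switches:
        switches_by_branch.setdefault(sw.branch_id, []).append(sw)
    implant_index = {imp.motif_name: i for i, imp in enumerate(config.implants)}

    gt = GroundTruth(
        motif_states={},
        motif_positions={},
        motif_texts={},
        switch_branches={},
        presence={},
        identity_to_root={},
        root_sequence="".join(root_chars),
    )
    for sw in config.switches:
        parent_keys = {
            node_key(n): node_key(n.parent_node)
            for n in tree.preorder_node_iter()
            if n.parent_node is not None
        }
        gt.switch_branches.setdefault(sw.motif_name, []).append(
            f"{parent_keys[sw.branch_id]}->{sw.branch_id}"
        )

    # walk the tree; rng order fixed by preorder traversal
    lineages: dict[int, _Lineage] = {
        id(tree.seed_node): _Lineage(chars, origins, implant_ids)
    }
    leaf_records: list[SequenceRecord] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            lin = lineages[id(node)]
        else:
            lin = lineages[id(node.parent_node)].copy()
            key = node_key(node)
            for sw in switches_by_branch.get(key, ()):
                idx = implant_index[sw.motif_name]
                _apply_switch(lin, idx, config.implants[idx], sw.new_text)
            _evolve_branch(lin, config, protected_ids, rng)
            lineages[id(node)] = lin
        if node.is_leaf():
            label = node.taxon.label
            seq = "".join(lin.chars)
            leaf_records.append(SequenceRecord(id=label, residues=seq))
            matches = sum(
                1
                for k, o in enumerate(lin.origins)
                if o >= 0 and lin.chars[k] == root_chars[o]
            )
            gt.identity_to_root[label] = matches / config.root_length
            for idx, imp in enumerate(config.implants):
                idxs = [k for k, i in enumerate(lin.implant_ids) if i == idx]
                if not idxs:
                    gt.motif_states[(label, imp.motif_name)] = "absent"
                    gt.motif_positions[(label, imp.motif_name)] = 0
                    gt.motif_texts[(label, imp.motif_name)] = ""
                    continue
                text = "".join(lin.chars[k] for k in idxs)
                state = (
                    "canonical" if text == imp.canonical_text else f"variant:{text}"
                )
                gt.motif_states[(label, imp.motif_name)] = state
                gt.motif_positions[(label, imp.motif_name)] = idxs[0] + 1
                gt.motif_texts[(label, imp.motif_name)] = text

    # proteomes: family sequence (unless absent) + decoys, per leaf
    root_record = SequenceRecord(id="root", residues="".join(root_chars))
    proteomes: dict[str, list[SequenceRecord]] = {}
    for rec in leaf_records:
        present = rec.id not in config.absent_leaves
        gt.presence[rec.id] = present
        decoys = make_decoys(
            config.n_decoys,
            length_range=(
                max(30, int(0.95 * config.root_length)),
                int(1.25 * config.root_length),
            ),
            rng=rng,
            composition_from=root_record,
            reject_against=root_record,
            id_prefix=f"decoy_{rec.id}",
        )
        proteomes[rec.id] = ([rec] if present else []) + decoys
    return leaf_records, tree, proteomes, gt


def make_decoys(
    n: int,
    length_range: tuple[int, int] = (455, 599),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    composition_from: SequenceRecord | None = None,
    reject_against: SequenceRecord | None = None,
    id_prefix: str = "decoy",
    max_retries: int = 50,
) -> list[SequenceRecord]:
    """Random decoy proteins that do not pass the homologue presence rule.

    Residue composition matches ``composition_from`` when given (uniform
    otherwise).  When ``reject_against`` is given, each decoy is verified
    against that query with the profiler's default thresholds and
    redrawn if it would (pathologically) be called present.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if composition_from is not None:
        counts = np.array(
            [composition_from.residues.count(a) for a in _AA], dtype=float
        )
        probs = counts / counts.sum()
    else:
        probs = np.full(20, 1.0 / 20.0)
    out: list[SequenceRecord] = []
    if reject_against is not None:
        from motifevo.homology_profiler import (
            Thresholds,
            align_pair,
            identity_and_coverage,
        )

        thresholds = Thresholds()
    for k in range(n):
        for attempt in range(max_retries):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            seq = "".join(
                _AA[i] for i in rng.choice(20, size=length, p=probs)
            )
            rec = SequenceRecord(id=f"{id_prefix}_{k + 1}", residues=seq)
            if reject_against is None:
                out.append(rec)
                break
            pa = align_pair(reject_against, rec)
            ident, cov = identity_and_coverage(pa, len(reject_against.residues))
            if not (
                ident >= thresholds.min_identity_pct
                and cov > thresholds.min_coverage_pct
            ):
                out.append(rec)
                break
        else:
            raise RuntimeError(
                f"could not draw a non-homologous decoy in {max_retries} tries"
            )
    return out


def write_simulation(
    outdir,
    leaves: Sequence[SequenceRecord],
    tree: dendropy.Tree,
    proteomes: dict[str, list[SequenceRecord]],
    gt: GroundTruth,
) -> None:
    """Write family FASTA, Newick, per-leaf proteome FASTAs, a taxonomy
    TSV (lineages = node-key paths root to leaf) and ground-truth TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(leaves, outdir / "family.fasta")
    write_newick(tree, outdir / "tree.nwk")
    pdir = outdir / "proteomes"
    pdir.mkdir(exist_ok=True)
    for pid, seqs in proteomes.items():
        if seqs:
            write_fasta(seqs, pdir / f"{pid}.fasta")
        else:
            (pdir / f"{pid}.fasta").write_text("")
    taxa = []
    for leaf in tree.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(node_key(node))
            node = node.parent_node
        taxa.append(TaxonRecord(taxon_id=leaf.taxon.label, lineage=tuple(reversed(path))))
    write_taxonomy(taxa, outdir / "taxonomy.tsv")
    with open(outdir / "truth_motifs.tsv", "w") as fh:
        fh.write("leaf\tmotif\tstate\tposition\ttext\n")
        for (leaf, motif), state in sorted(gt.motif_states.items()):
            fh.write(
                f"{leaf}\t{motif}\t{state}\t{gt.motif_positions[(leaf, motif)]}\t"
                f"{gt.motif_texts[(leaf, motif)]}\n"
            )
    with open(outdir / "truth_presence.tsv", "w") as fh:
        fh.write("proteome_id\tpresent\tidentity_to_root\n")
        for leaf in sorted(gt.presence):
            fh.write(
                f"{leaf}\t{int(gt.presence[leaf])}\t{gt.identity_to_root[leaf]:.4f}\n"
            )
    with open(outdir / "truth_switches.tsv", "w") as fh:
        fh.write("motif\tbranch\n")
        for motif, branches in sorted(gt.switch_branches.items()):
            for b in branches:
                fh.write(f"{motif}\t{b}\n")
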