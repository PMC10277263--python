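import numpy as np
import pytest

from motifevo.homology_profiler import build_profile
from motifevo.io_formats import SequenceRecord
from motifevo.motif_grammar import builtin_catalog, scan_sequence
from motifevo.phylo_annotation import fitch_minimum_changes, node_key
from motifevo.synthetic_data import (
    GroundTruth,
    Implant,
    SimulationConfig,
    Switch,
    balanced_tree_newick,
    default_implants,
    expected_identity,
    make_decoys,
    simulate_family,
    subst_prob_for_expected_identity,
    write_simulation,
)


def _config(**kw):
    base = dict(
        seed=11,
        tree_mode="fixed_newick",
        newick=balanced_tree_newick(3),
        n_leaves=8,
        root_length=200,
        subst_prob_per_branch=0.05,
        indel_rate=0.3,
        mean_indel_length=2.0,
        implants=(
            Implant("CSSC", "CSSC", 40),
            Implant("starDEL", "KDEL", 80),
        ),
        n_decoys=2,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_overlapping_implants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            _config(implants=(Implant("a", "CSSC", 40), Implant("b", "KDEL", 42)))

    def test_implant_outside_root_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            _config(implants=(Implant("a", "KDEL", 199),))

    def test_switch_on_unknown_motif_rejected(self):
        with pytest.raises(ValueError, match="unknown motif"):
            _config(switches=(Switch("nope", "node2", "CSSS"),))

    def test_switch_too_far_from_canonical_rejected(self):
        with pytest.raises(ValueError, match="edits"):
            _config(switches=(Switch("CSSC", "node2", "WWWWWWW"),))

    def test_switch_on_unknown_branch_rejected(self):
        cfg = _config(switches=(Switch("CSSC", "node99", "CSSS"),))
        with pytest.raises(ValueError, match="node99"):
            simulate_family(cfg)


class TestSimulateFamily:
    def test_zero_mutation_limit(self):
        cfg = _config(subst_prob_per_branch=0.0, indel_rate=0.0)
        leaves, tree, proteomes, gt = simulate_family(cfg)
        assert len({l.residues for l in leaves}) == 1
        assert all(v == 1.0 for v in gt.identity_to_root.values())
        cat = builtin_catalog()
        for leaf in leaves:
            starts = [m.start for m in scan_sequence(leaf, cat["CSSC"])]
            assert 40 in starts
            starts = [m.start for m in scan_sequence(leaf, cat["starDEL"])]
            assert 80 in starts

    def test_determinism(self):
        cfg = _config()
        a = simulate_family(cfg)
        b = simulate_family(cfg)
        assert [l.residues for l in a[0]] == [l.residues for l in b[0]]
        assert a[3].motif_states == b[3].motif_states
        assert {p: [s.residues for s in v] for p, v in a[2].items()} == {
            p: [s.residues for s in v] for p, v in b[2].items()
        }

    def test_protected_motifs_survive_heavy_mutation(self):
        cfg = _config(seed=3, subst_prob_per_branch=0.25, indel_rate=1.5)
        leaves, _, _, gt = simulate_family(cfg)
        cat = builtin_catalog()
        for leaf in leaves:
            for motif, canonical in (("CSSC", "CSSC"), ("starDEL", "KDEL")):
                pos = gt.motif_positions[(leaf.id, motif)]
                assert gt.motif_states[(leaf.id, motif)] == "canonical"
                assert leaf.residues[pos - 1 : pos - 1 + 4] == canonical
                assert pos in [m.start for m in scan_sequence(leaf, cat[motif])]

    def test_designed_switch_recovered_by_parsimony(self):
        cfg = _config(
            seed=5,
            switches=(Switch("CSSC", "node3", "CSSS"),),
            indel_rate=0.5,
        )
        leaves, tree, _, gt = simulate_family(cfg)
        assert gt.switch_branches == {"CSSC": ["node2->node3"]}
        states = {l.id: gt.motif_states[(l.id, "CSSC")] for l in leaves}
        assert set(states.values()) == {"canonical", "variant:CSSS"}
        n, labeling = fitch_minimum_changes(tree, states)
        assert n == 1
        changed = [
            f"{node_key(node.parent_node)}->{node_key(node)}"
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
            and labeling[node_key(node)] != labeling[node_key(node.parent_node)]
        ]
        assert changed == ["node2->node3"]

    def test_mean_identity_matches_binomial_expectation(self):
        # depth-4 balanced tree at p chosen for ~60% expected identity
        p = subst_prob_for_expected_identity(0.60, 4)
        realized = []
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                tree_mode="fixed_newick",
                newick=balanced_tree_newick(4),
                root_length=300,
                subst_prob_per_branch=p,
                indel_rate=0.0,
                n_decoys=0,
            )
            _, _, _, gt = simulate_family(cfg)
            realized.extend(gt.identity_to_root.values())
        assert np.mean(realized) == pytest.approx(0.60, abs=0.03)

    def test_identity_monotone_in_subst_prob(self):
        means = []
        for p in (0.02, 0.10, 0.25):
            cfg = _config(seed=9, subst_prob_per_branch=p, indel_rate=0.0)
            _, _, _, gt = simulate_family(cfg)
            means.append(np.mean(list(gt.identity_to_root.values())))
        assert means[0] > means[1] > means[2]

    def test_absent_leaves_lack_family_but_keep_decoys(self):
        cfg = _config(absent_leaves=frozenset({"L2", "L5"}))
        leaves, _, proteomes, gt = simulate_family(cfg)
        assert gt.presence == {l.id: l.id not in ("L2", "L5") for l in leaves}
        assert len(proteomes["L2"]) == 2  # decoys only
        assert len(proteomes["L1"]) == 3
        assert proteomes["L1"][0].id == "L1"

    def test_profile_recovers_designed_presence(self):
        cfg = _config(
            seed=21,
            subst_prob_per_branch=subst_prob_for_expected_identity(0.90, 3),
            absent_leaves=frozenset({"L4"}),
        )
        leaves, _, proteomes, gt = simulate_family(cfg)
        root = SequenceRecord(id="query", residues=gt.root_sequence)
        profile = build_profile(root, proteomes)
        assert profile.presence_vector() == gt.presence

    def test_root_sequence_carries_implants(self):
        cfg = _config(subst_prob_per_branch=0.0, indel_rate=0.0)
        leaves, _, _, gt = simulate_family(cfg)
        assert gt.root_sequence == leaves[0].residues
        assert gt.root_sequence[39:43] == "CSSC"

    def test_random_yule_mode(self):
        cfg = SimulationConfig(
            seed=2, n_leaves=12, root_length=100, indel_rate=0.2, n_decoys=0
        )
        leaves, tree, _, _ = simulate_family(cfg)
        assert len(leaves) == 12
        assert sorted(l.id for l in leaves) == sorted(
            n.taxon.label for n in tree.leaf_node_iter()
        )


class TestDecoys:
    def test_zero_is_empty(self):
        assert make_decoys(0, seed=1) == []

    def test_determinism(self):
        a = make_decoys(5, seed=4)
        b = make_decoys(5, seed=4)
        assert [r.residues for r in a] == [r.residues for r in b]

    def test_decoys_never_called_present(self, rng):
        from conftest import random_protein
        from motifevo.homology_profiler import call_presence

        query = SequenceRecord(id="q", residues=random_protein(rng, 200))
        decoys = make_decoys(
            5,
            length_range=(180, 220),
            seed=8,
            composition_from=query,
            reject_against=query,
        )
        assert not call_presence(query, decoys, "p").present


class TestWriteSimulation:
    def test_files_round_trip(self, tmp_path):
        from motifevo.io_formats import read_fasta, read_newick, read_taxonomy

        cfg = _config(absent_leaves=frozenset({"L3"}))
        leaves, tree, proteomes, gt = simulate_family(cfg)
        write_simulation(tmp_path, leaves, tree, proteomes, gt)
        fam = read_fasta(tmp_path / "family.fasta")
        assert [r.residues for r in fam] == [r.residues for r in leaves]
        back = read_newick(tmp_path / "tree.nwk")
        assert sorted(l.taxon.label for l in back.leaf_node_iter()) == sorted(
            l.id for l in leaves
        )
        taxa = read_taxonomy(tmp_path / "taxonomy.tsv")
        assert {t.taxon_id for t in taxa} == {l.id for l in leaves}
        assert all(t.lineage[0] == "node1" for t in taxa)
        presence = (tmp_path / "truth_presence.tsv").read_text()
        assert "L3\t0" in presence
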