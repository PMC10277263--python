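import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from conftest import AA, random_protein
from motifevo.homology_profiler import (
    AlignParams,
    PairwiseAlignment,
    Thresholds,
    align_pair,
    align_score,
    build_profile,
    call_presence,
    distribution_stats,
    identity_and_coverage,
    summarize_by_taxon,
)
from motifevo.io_formats import SequenceRecord, TaxonRecord
from oracles import brute_local_score

PARAMS = AlignParams()
_B62 = substitution_matrices.load("BLOSUM62")
SUB = {(a, b): int(_B62[a, b]) for a in "ACDE" for b in "ACDE"}


def _rec(i, s):
    return SequenceRecord(id=i, residues=s)


def _mutate(seq, n_subs, rng):
    """Replace exactly n_subs positions with a different residue."""
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = AA[(AA.index(out[p]) + 1 + int(rng.integers(19))) % 20]
    return "".join(out)


class TestAlignPair:
    def test_self_alignment_of_identical_50mers(self, rng):
        s = random_protein(rng, 50)
        pa = align_pair(_rec("q", s), _rec("t", s))
        assert pa.n_identities == pa.n_columns == 50
        assert pa.query_span == (1, 50)
        assert identity_and_coverage(pa, 50) == (100.0, 100.0)

    def test_embedded_segment(self):
        pa = align_pair(_rec("q", "MKV"), _rec("t", "AAAMKVAAA"))
        assert (pa.aligned_query, pa.aligned_target) == ("MKV", "MKV")
        assert pa.target_span == (4, 6)

    def test_gapped_alignment_reconstruction(self, rng):
        s = random_protein(rng, 80)
        target = s[:40] + s[50:]  # 10-residue deletion
        pa = align_pair(_rec("q", s), _rec("t", target))
        assert pa.aligned_query.replace("-", "") in s
        assert pa.aligned_target.replace("-", "") in target
        assert pa.n_columns >= 70

    def test_score_matches_exhaustive_enumeration_small(self, rng):
        for _ in range(60):
            m, n = int(rng.integers(1, 7)), int(rng.integers(1, 7))
            q = "".join("ACDE"[i] for i in rng.integers(0, 4, m))
            t = "".join("ACDE"[i] for i in rng.integers(0, 4, n))
            expected = brute_local_score(q, t, SUB, 12, 1)
            assert align_score(q, t, PARAMS) == expected

    def test_score_matches_biopython_on_long_pairs(self, rng):
        aligner = Align.PairwiseAligner(
            mode="local",
            substitution_matrix=_B62,
            open_gap_score=-12,
            extend_gap_score=-1,
        )
        for _ in range(5):
            q = random_protein(rng, 200)
            t = _mutate(q, 60, rng)
            assert align_score(q, t, PARAMS) == aligner.score(q, t)

    def test_score_symmetric(self, rng):
        q, t = random_protein(rng, 40), random_protein(rng, 55)
        assert align_score(q, t) == align_score(t, q)

    def test_score_at_least_best_single_match(self, rng):
        q, t = random_protein(rng, 30), random_protein(rng, 30)
        best_single = max(int(_B62[a, b]) for a in set(q) for b in set(t))
        if best_single > 0:
            assert align_score(q, t) >= best_single

    def test_nonpositive_gap_penalties_rejected(self):
        with pytest.raises(ValueError):
            AlignParams(gap_open=0)


class TestIdentityCoverage:
    def test_identity_counts_gap_columns(self):
        pa = PairwiseAlignment(
            query_id="q",
            target_id="t",
            aligned_query="MKVL-WYCDE",
            aligned_target="MKVLAWY-DE",
            score=1.0,
            query_span=(1, 9),
            target_span=(1, 9),
        )
        ident, _ = identity_and_coverage(pa, 9)
        assert ident == pytest.approx(100.0 * 8 / 10)

    def test_coverage_span_convention(self):
        pa = PairwiseAlignment(
            query_id="q",
            target_id="t",
            aligned_query="A" * 380,
            aligned_target="A" * 380,
            score=1.0,
            query_span=(101, 480),
            target_span=(1, 380),
        )
        _, cov = identity_and_coverage(pa, 480)
        assert cov == pytest.approx(79.17, abs=0.01)  # just under the 80 threshold

    def test_bad_query_length_rejected(self):
        pa = align_pair(_rec("q", "MKV"), _rec("t", "MKV"))
        with pytest.raises(ValueError):
            identity_and_coverage(pa, 0)


class TestPresence:
    def test_exact_copy_is_present(self, rng):
        q = _rec("q", random_protein(rng, 100))
        call = call_presence(q, [_rec("copy", q.residues)], "p1")
        assert call.present and call.best_target_id == "copy"

    def test_unrelated_proteome_is_absent(self, rng):
        q = _rec("q", random_protein(rng, 100))
        proteome = [_rec(f"d{i}", random_protein(rng, 120)) for i in range(5)]
        assert not call_presence(q, proteome, "p1").present

    def test_empty_proteome_absent(self, rng):
        call = call_presence(_rec("q", "MKVLL"), [], "p1")
        assert not call.present and call.best_target_id is None

    @pytest.mark.parametrize("n_subs,expected", [(35, False), (25, True)])
    def test_identity_controlled_homologue(self, rng, n_subs, expected):
        # 100-mer with n substitutions: identity ~ (100 - n)%, threshold 70
        q = _rec("q", random_protein(rng, 100))
        target = _rec("hom", _mutate(q.residues, n_subs, rng))
        call = call_presence(q, [target], "p1")
        assert call.present is expected

    def test_presence_monotone_in_thresholds(self, rng):
        q = _rec("q", random_protein(rng, 100))
        target = _rec("hom", _mutate(q.residues, 20, rng))
        loose = call_presence(q, [target], "p", Thresholds(60.0, 70.0))
        tight = call_presence(q, [target], "p", Thresholds(90.0, 95.0))
        assert loose.present >= tight.present
        assert loose.identity_pct == tight.identity_pct  # thresholds never change the alignment


class TestProfile:
    def test_designed_presence_counts(self, rng):
        q = _rec("q", random_protein(rng, 80))
        proteomes = {}
        for i in range(6):
            proteomes[f"hom{i}"] = [
                _rec("h", _mutate(q.residues, 8, rng)),
                _rec("d", random_protein(rng, 90)),
            ]
        for i in range(4):
            proteomes[f"bg{i}"] = [_rec("d", random_protein(rng, 90))]
        profile = build_profile(q, proteomes)
        present = profile.presence_vector()
        assert sum(present.values()) == 6
        assert all(present[f"hom{i}"] for i in range(6))

    def test_order_invariance_and_duplicate_ids(self, rng):
        q = _rec("q", random_protein(rng, 60))
        items = [("a", [_rec("x", q.residues)]), ("b", [])]
        p1 = build_profile(q, items)
        p2 = build_profile(q, items[::-1])
        assert p1.presence_vector() == p2.presence_vector()
        with pytest.raises(ValueError, match="duplicate"):
            build_profile(q, items + [("a", [])])

    def test_summarize_by_taxon(self, rng):
        q = _rec("q", random_protein(rng, 60))
        proteomes = {
            "f1": [],
            "f2": [],
            "p1": [_rec("x", q.residues)],
        }
        taxonomy = [
            TaxonRecord("f1", ("Eukaryota", "Fungi")),
            TaxonRecord("f2", ("Eukaryota", "Fungi")),
            TaxonRecord("p1", ("Eukaryota", "Viridiplantae")),
        ]
        table = summarize_by_taxon(build_profile(q, proteomes), taxonomy, rank=2)
        rows = table.set_index("group")
        assert tuple(rows.loc["Fungi"]) == (0, 2)
        assert tuple(rows.loc["Viridiplantae"]) == (1, 0)
        assert tuple(rows.loc["TOTAL"]) == (1, 2)
        assert table["group"].iloc[0] == "Fungi"  # sorted by absences

    def test_summarize_missing_taxonomy_errors(self, rng):
        q = _rec("q", random_protein(rng, 60))
        profile = build_profile(q, {"p1": [_rec("x", q.residues)]})
        with pytest.raises(ValueError, match="p1"):
            summarize_by_taxon(profile, [], rank=1)

    def test_distribution_stats(self, rng):
        q = _rec("q", random_protein(rng, 100))
        proteomes = {
            "a": [_rec("h1", q.residues)],
            "b": [_rec("h2", _mutate(q.residues, 10, rng))],
            "c": [],
        }
        profile = build_profile(q, proteomes)
        mean_id, mean_len = distribution_stats(profile)
        ids = [profile.calls[p].identity_pct for p in ("a", "b")]
        assert mean_id == pytest.approx(sum(ids) / 2)
        assert mean_len == pytest.approx(100.0)
        with pytest.raises(ValueError):
            distribution_stats(build_profile(q, {"c": []}))
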