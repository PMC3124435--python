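import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mimomap.align import (
    BLOSUM62_BACKGROUND,
    Mimotope,
    SubstitutionModel,
    _blosum62_array,
    align_query_to_graph,
    batch_best_scores,
    bb_upper_bound,
    blosum62_model,
    brute_force_best_path,
    default_substitution_model,
    derive_nnk_matrix,
    nnk_adjusted_logodds,
    nnk_codon_counts,
    nnk_frequencies,
    read_matrix_text,
    read_mimotopes,
    write_matrix_text,
)
from mimomap.structure import AA_INDEX, AMINO_ACIDS

from conftest import make_graph, random_patch_graph


class TestNnkMatrix:
    def test_codon_counts_enumerate_the_32_nnk_codons(self):
        counts = nnk_codon_counts()
        assert sum(counts.values()) == 32
        assert counts["L"] == 3      # TTG, CTT, CTG
        assert counts["M"] == 1      # ATG only
        assert counts["R"] == 3 and counts["S"] == 3
        assert counts["*"] == 1      # TAG

    def test_frequencies_normalised_over_coding_codons(self):
        f = nnk_frequencies()
        assert f.sum() == pytest.approx(1.0)
        assert f[AA_INDEX["L"]] == pytest.approx(3 / 31)

    def test_substituting_original_background_reproduces_blosum62(self):
        b62 = _blosum62_array()
        f = np.array([BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
        assert np.array_equal(nnk_adjusted_logodds(b62, f, f), b62)

    def test_uniform_background_shifts_rows_by_log_ratio(self):
        b62 = _blosum62_array()
        f = np.array([BLOSUM62_BACKGROUND[a] for a in AMINO_ACIDS])
        uniform = np.full(20, 1 / 20)
        got = nnk_adjusted_logodds(b62, f, uniform)
        expected = np.rint(b62 + (np.log2(f * 20) / 0.5)[:, None])
        assert np.array_equal(got, expected)

    def test_bad_codon_counts_rejected(self):
        counts = nnk_codon_counts()
        counts["L"] += 1
        with pytest.raises(ValueError):
            derive_nnk_matrix(codon_counts=counts)

    def test_packaged_matrix_matches_fresh_derivation(self, subst):
        fresh = derive_nnk_matrix()
        assert np.array_equal(subst.matrix, fresh.matrix)

    def test_matrix_text_roundtrip(self, subst, tmp_path):
        buf = io.StringIO()
        write_matrix_text(subst, buf, comment="test")
        buf.seek(0)
        back = read_matrix_text(buf)
        assert np.array_equal(back.matrix, subst.matrix)

    def test_gap_penalty_must_be_negative(self):
        with pytest.raises(ValueError):
            SubstitutionModel(np.zeros((20, 20)) + 1, gap_penalty=0.5)


class TestMimotopeIo:
    def test_plain_text_and_fasta(self, tmp_path):
        plain = tmp_path / "m.txt"
        plain.write_text("YGVKN\nacdef\n")
        mims = read_mimotopes(plain)
        assert [m.sequence for m in mims] == ["YGVKN", "ACDEF"]
        fasta = tmp_path / "m.fa"
        fasta.write_text(">pep1\nYGV\nKN\n>pep2\nWWW\n")
        mims = read_mimotopes(fasta)
        assert [(m.label, m.sequence) for m in mims] == [("pep1", "YGVKN"), ("pep2", "WWW")]

    def test_invalid_letters_rejected(self):
        with pytest.raises(ValueError):
            Mimotope("YGXB1")
        with pytest.raises(ValueError):
            Mimotope("")


class TestAlignment:
    def test_single_vertex_graph(self, subst):
        g = make_graph(["Y"], [])
        aln = align_query_to_graph(g, Mimotope("Y"), subst)
        assert aln.raw_score == subst.score("Y", "Y")
        assert aln.path_vertices == [0]

    def test_forced_chain_path_recovers_epitope_order(self, subst):
        # a linear 5-vertex graph spelling the epitope: the best path for the
        # identical query is the chain itself, scored by the matrix diagonal
        g = make_graph(list("YGVKN"), [(0, 1), (1, 2), (2, 3), (3, 4)])
        aln = align_query_to_graph(g, Mimotope("YGVKN"), subst)
        diag = sum(subst.score(a, a) for a in "YGVKN")
        assert aln.raw_score == pytest.approx(diag)
        assert aln.path_vertices == [0, 1, 2, 3, 4]
        assert aln.recomputed_score(subst) == pytest.approx(aln.raw_score)

    def test_edgeless_graph_still_aligns_single_residues(self, subst):
        g = make_graph(["A", "W"], [])
        aln = align_query_to_graph(g, Mimotope("WW"), subst)
        assert aln.raw_score == subst.score("W", "W")

    @pytest.mark.parametrize("allow_ins", [False, True])
    def test_dp_equals_oracle_and_batch_on_random_instances(self, subst, allow_ins):
        rng = np.random.default_rng(20240901)
        for _ in range(40):
            g = random_patch_graph(rng, int(rng.integers(3, 8)), rng.uniform(0.3, 0.6))
            q = Mimotope("".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, int(rng.integers(3, 7)))))
            dp = align_query_to_graph(g, q, subst, allow_insertions=allow_ins)
            bf = brute_force_best_path(g, q, subst, allow_insertions=allow_ins)
            bt = batch_best_scores(g, q.indices[None, :], subst, allow_insertions=allow_ins)[0]
            assert dp.raw_score == bf.raw_score == bt
            assert dp.recomputed_score(subst) == pytest.approx(dp.raw_score)

    def test_score_floor_never_negative(self):
        hostile = SubstitutionModel(np.full((20, 20), -7.0), gap_penalty=-9.0)
        g = make_graph(list("AC"), [(0, 1)])
        aln = align_query_to_graph(g, Mimotope("WW"), hostile)
        assert aln.raw_score == 0.0
        assert aln.steps == []

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_vertex_relabeling_leaves_score_unchanged(self, seed):
        subst = blosum62_model()
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g = random_patch_graph(rng, n, 0.5)
        q = Mimotope("".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 4)))
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        g2 = make_graph(
            [g.vertex_aa[inv[i]] for i in range(n)],
            [(int(perm[i]), int(perm[j])) for i, j in g.edges],
        )
        s1 = align_query_to_graph(g, q, subst).raw_score
        s2 = align_query_to_graph(g2, q, subst).raw_score
        assert s1 == s2

    def test_positive_matrix_shift_never_decreases_score(self, subst):
        rng = np.random.default_rng(77)
        g = random_patch_graph(rng, 6, 0.5)
        q = Mimotope("YGVKN")
        base = align_query_to_graph(g, q, subst).raw_score
        shifted_model = SubstitutionModel(subst.matrix + 3.0, subst.gap_penalty)
        shifted = align_query_to_graph(g, q, shifted_model).raw_score
        assert shifted >= base

    def test_oracle_guard_on_large_graphs(self, subst):
        rng = np.random.default_rng(0)
        g = random_patch_graph(rng, 13, 0.3)
        with pytest.raises(ValueError):
            brute_force_best_path(g, Mimotope("AAA"), subst)


class TestBranchAndBound:
    def test_upper_bound_arithmetic(self, subst):
        assert bb_upper_bound(12.5, 0, subst) == 12.5
        assert bb_upper_bound(1.0, 3, subst) == 1.0 + 3 * subst.max_entry
        with pytest.raises(ValueError):
            bb_upper_bound(0.0, -1, subst)

    def test_bound_is_admissible_for_prefix_completions(self, subst):
        # best(prefix of length i) + bound(remaining) can never undercut the
        # best complete alignment
        rng = np.random.default_rng(5)
        for _ in range(20):
            g = random_patch_graph(rng, 6, 0.5)
            q = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 5))
            full = align_query_to_graph(g, Mimotope(q), subst).raw_score
            for i in range(1, len(q)):
                prefix_best = align_query_to_graph(g, Mimotope(q[:i]), subst).raw_score
                assert bb_upper_bound(prefix_best, len(q) - i, subst) >= full

    def test_pruning_changes_nothing_but_state_counts(self, subst):
        rng = np.random.default_rng(99)
        for _ in range(30):
            g = random_patch_graph(rng, int(rng.integers(4, 9)), 0.5)
            q = Mimotope("".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 5)))
            pruned = align_query_to_graph(g, q, subst, use_bb=True)
            full = align_query_to_graph(g, q, subst, use_bb=False)
            assert pruned.raw_score == full.raw_score
            assert pruned.n_states <= full.n_states
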