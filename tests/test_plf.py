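"""Likelihood kernel: pattern compression, pruning updates, scaling, root
assembly, accumulator."""

import math
from collections import Counter

import numpy as np
import pytest

import plfkit as pk
from plfkit.plf import (AlignmentFormatError, UnderflowError,
                        compress_alignment, leaf_likelihoods,
                        pipelined_accumulate, root_log_likelihood,
                        scale_conditional, tree_log_likelihood,
                        update_conditional)
from plfkit.trees import Node, Tree

from conftest import brute_force_lnl, random_instance


def two_leaf_tree(len_a=0.0, len_b=0.0):
    root = Node(age=max(len_a, len_b))
    root.add_child(Node("x", length=len_a))
    root.add_child(Node("y", length=len_b))
    return Tree(root)


class TestCompression:
    def test_identical_columns_collapse(self):
        seqs = {f"t{i}": "A" * 10 for i in range(4)}
        pa = compress_alignment(seqs)
        assert pa.n_patterns == 1
        assert list(pa.num_sites) == [10]

    def test_distinct_columns_stay(self):
        cols = ["ACGT", "AGCT", "TTTT", "CCCC", "GGGG", "ACGA", "TGCA",
                "AAAC", "CATG", "GTAC"]
        seqs = {f"t{i}": "".join(c[i] for c in cols) for i in range(4)}
        pa = compress_alignment(seqs)
        assert pa.n_patterns == 10
        assert list(pa.num_sites) == [1] * 10

    def test_matches_hash_tally(self):
        rng = np.random.default_rng(0)
        L, n = 500, 8
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), L))
                for i in range(n)}
        pa = compress_alignment(seqs)
        tally = Counter("".join(seqs[t][i] for t in pa.taxa)
                        for i in range(L))
        assert pa.n_sites == 500
        assert pa.n_patterns == len(tally)
        for row, count in zip(pa.patterns, pa.num_sites):
            assert tally["".join(row)] == count

    def test_first_occurrence_order(self):
        seqs = {"a": "GGA", "b": "GGA"}
        pa = compress_alignment(seqs)
        assert "".join(pa.patterns[0]) == "GG"
        assert list(pa.num_sites) == [2, 1]

    def test_format_errors(self):
        with pytest.raises(AlignmentFormatError):
            compress_alignment({"a": "ACG", "b": "AC"})
        with pytest.raises(AlignmentFormatError):
            compress_alignment({})
        with pytest.raises(AlignmentFormatError):
            compress_alignment({"a": "ACG"})


class TestLeafLikelihoods:
    @pytest.mark.parametrize("code,row", [
        ("A", (1, 0, 0, 0)), ("C", (0, 1, 0, 0)), ("G", (0, 0, 1, 0)),
        ("T", (0, 0, 0, 1)), ("R", (1, 0, 1, 0)), ("Y", (0, 1, 0, 1)),
        ("N", (1, 1, 1, 1)), ("-", (1, 1, 1, 1)),
    ])
    def test_iupac_rows(self, code, row):
        assert tuple(leaf_likelihoods([code])[0]) == row

    def test_invalid_code_names_position(self):
        with pytest.raises(AlignmentFormatError, match="position 2"):
            leaf_likelihoods(["A", "C", "X"])


class TestUpdateConditional:
    def test_identity_matrices(self):
        clp = np.array([[1.0, 0, 0, 0]])
        out = update_conditional(clp, clp, np.eye(4), np.eye(4))
        assert np.allclose(out, clp)

    def test_uniform_matrices(self):
        P = np.full((4, 4), 0.25)
        out = update_conditional(np.eye(4)[:1], np.eye(4)[2:3], P, P)
        assert np.allclose(out, 0.0625)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_nested_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        p = 7
        ci, cj = rng.random((p, 4)), rng.random((p, 4))
        Pi, Pj = rng.random((4, 4)), rng.random((4, 4))
        out = update_conditional(ci, cj, Pi, Pj)
        for c in range(p):
            for N in range(4):
                expect = (sum(Pi[N][M] * ci[c][M] for M in range(4))
                          * sum(Pj[N][M] * cj[c][M] for M in range(4)))
                assert out[c, N] == pytest.approx(expect, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            update_conditional(np.ones((2, 4)), np.ones((3, 4)),
                               np.eye(4), np.eye(4))


class TestScaling:
    def test_basic_normalization(self):
        clp = np.array([[0.5, 0.25, 0.125, 0.0625]])
        out, sv = scale_conditional(clp, np.zeros(1), "exact")
        assert np.allclose(out, [[1.0, 0.5, 0.25, 0.125]])
        assert sv.scp[0] == 0.5
        assert sv.ln_scaler[0] == pytest.approx(math.log(0.5))

    def test_already_normalized_row(self):
        clp = np.array([[1.0, 0.3, 0.3, 0.1]])
        out, sv = scale_conditional(clp, np.array([-2.5]), "exact")
        assert np.allclose(out, clp)
        assert sv.ln_scaler[0] == pytest.approx(-2.5)
        assert np.max(out, axis=1) == pytest.approx(1.0)

    def test_zero_row_raises_with_index(self):
        clp = np.array([[1.0, 0.5, 0.5, 0.5], [0.0, 0.0, 0.0, 0.0]])
        with pytest.raises(UnderflowError, match="pattern 1"):
            scale_conditional(clp, np.zeros(2), "exact")


class TestRootLogLikelihood:
    def test_single_pattern_uniform_priors(self):
        lnl = root_log_likelihood(np.array([[1.0, 0, 0, 0]]), np.zeros(1),
                                  np.full(4, 0.25), np.array([1]), "exact")
        assert lnl == pytest.approx(math.log(0.25))

    def test_num_sites_linearity(self):
        clp = np.array([[0.8, 0.1, 0.05, 0.05]])
        one = root_log_likelihood(clp, np.array([-1.0]), np.full(4, 0.25),
                                  np.array([1]), "exact")
        two = root_log_likelihood(clp, np.array([-1.0]), np.full(4, 0.25),
                                  np.array([2]), "exact")
        assert two == pytest.approx(2 * one)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            root_log_likelihood(np.ones((2, 4)), np.zeros(1),
                                np.full(4, 0.25), np.array([1, 1]))


class TestTreeLogLikelihood:
    def test_two_leaves_zero_branches(self):
        tree = two_leaf_tree()
        data = compress_alignment({"x": "ACGTACGT", "y": "ACGTACGT"})
        lnl = tree_log_likelihood(tree, pk.GTRParams.jc(), data)
        assert lnl == pytest.approx(8 * math.log(0.25))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_three_taxon_enumeration_oracle(self, seed):
        tree, params, seqs = random_instance(seed, n_taxa=3, length=4)
        data = compress_alignment(seqs)
        lnl = tree_log_likelihood(tree, params, data)
        assert lnl == pytest.approx(brute_force_lnl(tree, params, seqs),
                                    rel=1e-10)

    @pytest.mark.parametrize("seed", [2, 3])
    def test_five_taxon_enumeration_oracle(self, seed):
        tree, params, seqs = random_instance(seed, n_taxa=5, length=10)
        lnl = tree_log_likelihood(tree, params, compress_alignment(seqs))
        assert lnl == pytest.approx(brute_force_lnl(tree, params, seqs),
                                    rel=1e-10)

    @pytest.mark.parametrize("seed", range(3))
    def test_scaling_neutrality(self, seed):
        tree, params, seqs = random_instance(seed, n_taxa=6, length=40)
        data = compress_alignment(seqs)
        on = tree_log_likelihood(tree, params, data, scale=True)
        off = tree_log_likelihood(tree, params, data, scale=False)
        assert on == pytest.approx(off, abs=1e-9 * max(1.0, abs(off)))

    def test_pattern_compression_neutrality(self):
        tree, params, seqs = random_instance(5, n_taxa=6, length=60)
        compressed = compress_alignment(seqs)
        lnl = tree_log_likelihood(tree, params, compressed)
        # column-by-column evaluation on the uncompressed alignment
        total = 0.0
        for i in range(60):
            col = {t: s[i] for t, s in seqs.items()}
            total += tree_log_likelihood(tree, params, compress_alignment(
                {t: c + c for t, c in col.items()})) / 2.0
        assert lnl == pytest.approx(total, abs=1e-9 * abs(total))

    def test_ambiguity_codes_marginalize(self):
        # an N leaf contributes a factor-of-one compatibility row, so a
        # fully ambiguous column equals the likelihood marginalized over it
        tree, params, seqs = random_instance(6, n_taxa=4, length=6)
        seqs = {t: s for t, s in seqs.items()}
        first = next(iter(seqs))
        seqs_n = dict(seqs)
        seqs_n[first] = "N" + seqs[first][1:]
        lnl = tree_log_likelihood(tree, params, compress_alignment(seqs_n))
        assert lnl == pytest.approx(brute_force_lnl(tree, params, seqs_n),
                                    rel=1e-10)

    def test_faithful_mode_tracks_double(self):
        tree, params, seqs = random_instance(7, n_taxa=6, length=100)
        data = compress_alignment(seqs)
        d = tree_log_likelihood(tree, params, data, precision="double")
        f = tree_log_likelihood(tree, params, data, precision="faithful")
        assert f == pytest.approx(d, rel=1e-5)
        assert f != d  # rounding to single precision must be observable

    def test_taxon_mismatch_lists_offenders(self):
        tree = two_leaf_tree()
        data = compress_alignment({"x": "AC", "z": "AC"})
        with pytest.raises(ValueError, match="z"):
            tree_log_likelihood(tree, pk.GTRParams.jc(), data)

    def test_backend_orderings_finite(self):
        tree, params, seqs = random_instance(8, n_taxa=6, length=80)
        data = compress_alignment(seqs)
        exact = tree_log_likelihood(tree, params, data, "exact")
        cheb = tree_log_likelihood(tree, params, data, "chebyshev")
        des = tree_log_likelihood(tree, params, data, "desoras")
        assert math.isfinite(cheb) and math.isfinite(des)
        # the de Soras backend only perturbs scaler logs (max 7e-3 each)
        assert abs(des - exact) < 1.0


class TestPipelinedAccumulate:
    def test_fourteen_ones(self):
        assert pipelined_accumulate(np.ones(14), depth=14) == 14.0

    def test_empty_input(self):
        assert pipelined_accumulate([]) == 0.0

    def test_depth_one_is_sequential(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=100)
        assert pipelined_accumulate(v, depth=1) == pytest.approx(
            math.fsum(v), rel=1e-12)

    @pytest.mark.parametrize("depth", [2, 14, 31])
    def test_matches_sequential_sum(self, depth):
        rng = np.random.default_rng(depth)
        v = rng.normal(scale=100.0, size=10_000)
        seq = 0.0
        for x in v:
            seq += x
        assert pipelined_accumulate(v, depth=depth) == pytest.approx(
            seq, rel=1e-9)

    def test_invalid_depth(self):
        with pytest.raises(ValueError):
            pipelined_accumulate([1.0], depth=0)
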