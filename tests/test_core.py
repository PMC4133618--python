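import numpy as np
import pytest

from comdp import (
    MutationMatrix,
    collapse_metagenes,
    coverage,
    load_matrix,
    pair_stats,
    weight_W,
)

from conftest import make_matrix, random_matrix


class TestLoadMatrix:
    def test_matrix_format_round_trip(self, f1, tmp_path):
        path = tmp_path / "m.tsv"
        f1.write_tsv(path)
        A = load_matrix(path, format="matrix")
        assert A.samples == f1.samples
        assert A.genes == f1.genes
        assert np.array_equal(A.cells, f1.cells)
        assert tuple(A.column_sums) == (2, 2, 2, 2, 1, 1)

    def test_pairs_format_single_event(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("s1\tg1\n")
        A = load_matrix(path, format="pairs")
        assert (A.m, A.n) == (1, 1)
        assert A.cells[0, 0] == 1

    def test_pairs_format_duplicates_collapse(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("s1\tg1\ns1\tg1\ns2\tg2\n")
        A = load_matrix(path, format="pairs")
        assert A.cells.sum() == 2

    def test_non_binary_cell_is_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample\tg1\tg2\ns1\t0\t2\n")
        with pytest.raises(ValueError, match="g2"):
            load_matrix(path, format="matrix")

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("sample\tg1\n")
        with pytest.raises(ValueError, match="empty"):
            load_matrix(path, format="matrix")

    def test_duplicate_identifiers_rejected(self):
        cells = np.ones((2, 1), dtype=np.uint8)
        with pytest.raises(ValueError, match="duplicate sample"):
            MutationMatrix(("s1", "s1"), ("g1",), cells)


class TestCollapseMetagenes:
    def test_identical_profiles_merge(self, f1):
        collapsed, metagenes = collapse_metagenes(f1)
        assert (collapsed.m, collapsed.n) == (5, 5)
        assert "g5|g6" in collapsed.genes
        assert [mg.members for mg in metagenes] == [("g5", "g6")]

    def test_distinct_profiles_unchanged(self):
        A = make_matrix({"a": ["s1"], "b": ["s2"], "c": ["s1", "s2"]})
        collapsed, metagenes = collapse_metagenes(A)
        assert collapsed.genes == A.genes
        assert metagenes == []

    def test_all_zero_column_dropped(self):
        cells = np.array([[1, 0], [1, 0]], dtype=np.uint8)
        A = MutationMatrix(("s1", "s2"), ("g1", "gz"), cells)
        collapsed, _ = collapse_metagenes(A)
        assert "gz" not in collapsed.genes

    def test_idempotent_and_event_conserving(self, f1):
        once, _ = collapse_metagenes(f1)
        twice, mg2 = collapse_metagenes(once)
        assert twice.genes == once.genes
        assert mg2 == []
        # one shared column replaces g5+g6: 10 events -> 9
        assert once.cells.sum() == 9


class TestCoverageAndWeight:
    def test_coverage_examples(self, f1):
        assert coverage(f1, ["g1"]) == {"s1", "s2"}
        assert coverage(f1, []) == frozenset()
        assert coverage(f1, ["g1", "g3"]) == {"s1", "s2", "s3"}

    def test_unknown_gene_named_in_error(self, f1):
        with pytest.raises(KeyError, match="nope"):
            coverage(f1, ["nope"])

    @pytest.mark.parametrize(
        "genes,expected",
        [(["g1", "g2"], 4), (["g1"], 2), (["g1", "g3"], 2), ([], 0)],
    )
    def test_weight_examples(self, f1, genes, expected):
        assert weight_W(f1, genes) == expected

    def test_weight_two_forms_agree_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            A = random_matrix(rng, m=rng.integers(3, 10), n=rng.integers(2, 8))
            size = int(rng.integers(1, A.n + 1))
            S = list(rng.choice(A.genes, size=size, replace=False))
            cov = coverage(A, S)
            omega = sum(len(coverage(A, [g])) for g in S) - len(cov)
            assert weight_W(A, S) == len(cov) - omega


class TestPairStats:
    def test_cooccurring_pair(self, f1):
        st = pair_stats(f1, ["g1", "g2"], ["g3", "g4"], lam=10, eta=-2)
        assert (st.c, st.b, st.d) == (4, 4, 0)
        assert st.ratio == 1.0
        assert st.H == 40

    def test_disjoint_coverage_pair(self, f1):
        st = pair_stats(f1, ["g1", "g2"], ["g5"], lam=10, eta=-2)
        assert (st.c, st.b, st.d) == (0, 5, 5)
        assert st.ratio == 0.0

    def test_overlapping_sets_rejected(self, f1):
        with pytest.raises(ValueError, match="disjoint"):
            pair_stats(f1, ["g1", "g2"], ["g2", "g3"])

    def test_empty_pair_ratio_zero(self):
        A = make_matrix({"a": ["s1"]})
        st = pair_stats(A, [], [], lam=10, eta=-2)
        assert st.b == 0 and st.ratio == 0.0

    def test_multi_dendrix_identity_on_random_inputs(self):
        """At lambda=2, eta=1 the pairwise objective is exactly W(S)+W(T)."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            A = random_matrix(rng, m=rng.integers(3, 12), n=rng.integers(2, 9))
            genes = list(A.genes)
            rng.shuffle(genes)
            cut = int(rng.integers(1, len(genes)))
            size = int(rng.integers(cut, len(genes) + 1))
            S, T = genes[:cut], genes[cut:size]
            st = pair_stats(A, S, T, lam=2, eta=1)
            assert st.H == weight_W(A, S) + weight_W(A, T)

    def test_union_weight_identity_when_no_common_coverage(self, f1):
        # eta=1 with c=0 collapses H to the single-set weight of the union
        st = pair_stats(f1, ["g1", "g2"], ["g5"], lam=-10, eta=1)
        assert st.c == 0
        assert st.H == weight_W(f1, ["g1", "g2", "g5"])

    def test_ratio_invariant_under_reordering(self, f1):
        perm_rows = [3, 0, 4, 1, 2]
        perm_cols = [5, 2, 0, 1, 4, 3]
        B = MutationMatrix(
            tuple(f1.samples[i] for i in perm_rows),
            tuple(f1.genes[j] for j in perm_cols),
            f1.cells[np.ix_(perm_rows, perm_cols)],
        )
        a = pair_stats(f1, ["g1", "g2"], ["g3", "g4"])
        b = pair_stats(B, ["g1", "g2"], ["g3", "g4"])
        assert a.ratio == b.ratio and a.c == b.c and a.H == b.H
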