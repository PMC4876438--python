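import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wmnet.core import (
    ConnectivityMatrix,
    ValidationError,
    check_no_isolated_nodes,
    load_matrix,
    load_phenotypes,
    n_possible_edges,
    sparsity_of,
    threshold_by_sparsity,
)

from conftest import net_from_edges


def write_matrix(tmp_path, text, name="subj.txt"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadMatrix:
    def test_minimal_symmetric_file(self, tmp_path):
        path = write_matrix(tmp_path, "0 0.5 0.2\n0.5 0 0.1\n0.2 0.1 0\n")
        m = load_matrix(path)
        assert m.n_nodes == 3
        assert m.subject_id == "subj"
        assert m.weights[0, 1] == 0.5

    def test_comma_delimited(self, tmp_path):
        path = write_matrix(tmp_path, "0,0.5,0.2\n0.5,0,0.1\n0.2,0.1,0\n")
        assert load_matrix(path).n_nodes == 3

    def test_asymmetric_is_error(self, tmp_path):
        path = write_matrix(tmp_path, "0 0.2 0\n0.3 0 0.1\n0 0.1 0\n")
        with pytest.raises(ValidationError, match="asymmetric"):
            load_matrix(path)

    @pytest.mark.parametrize("text,match", [
        ("0 -0.2 0\n-0.2 0 0.1\n0 0.1 0\n", "negative"),
        ("0 nan 0\nnan 0 0.1\n0 0.1 0\n", "finite"),
        ("0 0.5\n0.5 0\n0.1 0.2\n", "square"),
        ("0 1\n1 0\n", "3 nodes"),
    ])
    def test_invalid_inputs(self, tmp_path, text, match):
        path = write_matrix(tmp_path, text)
        with pytest.raises(ValidationError, match=match):
            load_matrix(path)

    def test_label_count_mismatch(self, tmp_path):
        mat = write_matrix(tmp_path, "0 0.5 0.2\n0.5 0 0.1\n0.2 0.1 0\n")
        labels = tmp_path / "labels.txt"
        labels.write_text("a\nb\n")
        with pytest.raises(ValidationError, match="labels"):
            load_matrix(mat, labels)

    def test_atlas_cohort_fixture(self, default_subject):
        """90 regions with 45 per hemisphere under the default atlas."""
        assert default_subject.n_nodes == 90
        left = [l for l in default_subject.node_labels if l.endswith("_L")]
        right = [l for l in default_subject.node_labels if l.endswith("_R")]
        assert len(left) == len(right) == 45
        assert "Parietal_Inf_R" in default_subject.node_labels


class TestSparsity:
    def test_fully_connected(self):
        t = net_from_edges(4, [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)])
        assert sparsity_of(t) == 1.0

    def test_half_connected(self):
        t = net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert sparsity_of(t) == 0.5

    def test_generator_exceeds_grid_max(self, default_subject):
        # direct nonzero count, independent of the sparsity helper
        w = default_subject.weights
        n = w.shape[0]
        count = sum(
            1 for i in range(n) for j in range(i + 1, n) if w[i, j] != 0
        )
        assert count / n_possible_edges(n) > 0.27
        assert sparsity_of(default_subject) == count / n_possible_edges(n)


class TestThreshold:
    def test_identity_at_full_sparsity(self):
        t = net_from_edges(4, [(0, 1, 0.3), (0, 2, 0.7), (0, 3, 0.2),
                               (1, 2, 0.9), (1, 3, 0.4), (2, 3, 0.5)],
                           binary=False)
        out = threshold_by_sparsity(t, 1.0)
        np.testing.assert_array_equal(out.weights, t.weights)

    def test_rank_order_retention(self):
        t = net_from_edges(3, [(0, 1, 0.9), (0, 2, 0.1), (1, 2, 0.5)],
                           binary=False)
        out = threshold_by_sparsity(t, 2 / 3)
        assert out.weights[0, 1] == 0.9
        assert out.weights[1, 2] == 0.5
        assert out.weights[0, 2] == 0.0

    def test_edge_count_at_nine_percent(self, default_subject):
        """0.09 * 4005 = 360.45 rounds to 360 retained pairs."""
        out = threshold_by_sparsity(default_subject, 0.09)
        assert np.count_nonzero(np.triu(out.weights, 1)) == 360
        assert out.sparsity == 360 / 4005

    def test_binary_mode_is_zero_one(self, default_subject):
        out = threshold_by_sparsity(default_subject, 0.11, binary=True)
        assert set(np.unique(out.weights)) == {0.0, 1.0}

    def test_exceeding_raw_sparsity_is_error(self):
        t = net_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        with pytest.raises(ValueError, match="exceeds raw sparsity"):
            threshold_by_sparsity(t, 0.9)

    def test_tie_break_is_deterministic(self):
        t = net_from_edges(4, [(0, 1, 0.5), (0, 2, 0.5), (1, 3, 0.5),
                               (2, 3, 0.5)], binary=False)
        out = threshold_by_sparsity(t, 2 / 6)
        # lexicographically first pairs win the tie
        assert out.weights[0, 1] == 0.5 and out.weights[0, 2] == 0.5
        assert out.weights[1, 3] == 0.0 and out.weights[2, 3] == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_threshold_invariants(self, seed):
        """Idempotence, nested edge sets, and exact achieved sparsity."""
        from conftest import random_weighted_network

        t = random_weighted_network(10, 0.7, seed)
        raw = sparsity_of(t)
        n_pairs = n_possible_edges(10)
        s1, s2 = 0.3 * raw, 0.8 * raw
        t1 = threshold_by_sparsity(t, s1)
        t2 = threshold_by_sparsity(t, s2)
        # achieved sparsity is exactly k / n_pairs
        k1 = np.count_nonzero(np.triu(t1.weights, 1))
        assert t1.sparsity == k1 / n_pairs
        assert sparsity_of(t1) == t1.sparsity
        # nesting: edges at the lower sparsity survive at the higher one
        assert np.all(t2.weights[t1.weights > 0] > 0)
        # retained weights are a subset of the raw weights
        assert np.all(t1.weights[t1.weights > 0]
                      == t.weights[t1.weights > 0])
        # idempotence at the same sparsity
        again = threshold_by_sparsity(t1, t1.sparsity)
        np.testing.assert_array_equal(again.weights, t1.weights)


class TestIsolatedNodes:
    def test_triangle_ok(self):
        t = net_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert check_no_isolated_nodes(t)

    def test_zero_row_detected(self):
        t = net_from_edges(4, [(0, 1), (1, 2), (0, 2)])
        assert not check_no_isolated_nodes(t)

    def test_generator_gate_at_grid_minimum(self, default_subject):
        out = threshold_by_sparsity(default_subject, 0.09)
        degrees = (out.weights > 0).sum(axis=1)
        assert degrees.min() >= 1


class TestPhenotypes:
    def test_roundtrip_and_validation(self, tmp_path):
        path = tmp_path / "phenotypes.tsv"
        path.write_text(
            "subject_id\tgroup\tmbea\ttone\tage\tsex\tiq\tbrain_size\n"
            "s1\tcontrol\t90\t95\t21\tF\t120\t1400\n"
            "s2\tamusic\t60\t80\t22\tM\t118\t1380\n"
        )
        table = load_phenotypes(path)
        assert list(table["subject_id"]) == ["s1", "s2"]

    def test_single_group_rejected(self, tmp_path):
        path = tmp_path / "phenotypes.tsv"
        path.write_text(
            "subject_id\tgroup\tmbea\ttone\tage\tsex\tiq\tbrain_size\n"
            "s1\tcontrol\t90\t95\t21\tF\t120\t1400\n"
        )
        with pytest.raises(ValidationError, match="two group"):
            load_phenotypes(path)

    def test_score_range_checked(self, tmp_path):
        path = tmp_path / "phenotypes.tsv"
        path.write_text(
            "subject_id\tgroup\tmbea\ttone\tage\tsex\tiq\tbrain_size\n"
            "s1\tcontrol\t90\t120\t21\tF\t120\t1400\n"
            "s2\tamusic\t60\t80\t22\tM\t118\t1380\n"
        )
        with pytest.raises(ValidationError, match="outside"):
            load_phenotypes(path)
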