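"""Clustering diseases by age pattern: distances, recovery, determinism."""

import numpy as np
import pandas as pd
import pytest

from agemap.clustering import cluster_diseases, cut_tree, to_newick
from agemap.matrix import AgeDiseaseMatrix
from agemap.synthetic import AgeComponent, DiseaseSpec, generate_matrix_pair


def _matrix(rows: dict) -> AgeDiseaseMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = range(df.shape[1])
    return AgeDiseaseMatrix("mouse", 1.0, df, normalized=True)


def _two_group_specs(n_per_group=4):
    """Young narrow peaks vs old wide peaks (two classic pattern shapes)."""
    young = [
        DiseaseSpec(f"Y:{i}", f"young{i}", age_model=[AgeComponent(15 + i, 4.0)],
                    planted_shift_days=30)
        for i in range(n_per_group)
    ]
    old = [
        DiseaseSpec(f"O:{i}", f"old{i}", age_model=[AgeComponent(75 + i, 18.0)],
                    planted_shift_days=30)
        for i in range(n_per_group)
    ]
    return young + old


def _mouse_matrix(specs, noise_cv, seed):
    _, mouse, _ = generate_matrix_pair(specs, noise_cv=noise_cv, seed=seed)
    return mouse


def test_identical_rows_merge_at_height_zero():
    v = np.exp(-0.5 * ((np.arange(50) - 20) / 5.0) ** 2)
    dend = cluster_diseases(_matrix({"a": v, "b": v.copy(), "c": np.arange(50.0)}))
    assert dend.merge_heights.min() == pytest.approx(0.0, abs=1e-12)


def test_affine_transform_of_row_is_distance_zero():
    v = np.exp(-0.5 * ((np.arange(50) - 20) / 5.0) ** 2)
    dend = cluster_diseases(_matrix({"a": v, "b": 3.5 * v + 1.0, "c": np.arange(50.0)}))
    groups = cut_tree(dend, 2)
    assert groups["a"] == groups["b"] != groups["c"]


def test_average_linkage_heights_match_hand_computation():
    """Three leaves: the second merge height is the mean of the two
    leaf-to-cluster distances (average linkage, brute-force oracle)."""
    rows = {
        "a": np.array([1.0, 2.0, 3.0, 4.0, 5.0, 7.0]),
        "b": np.array([1.0, 2.1, 2.9, 4.2, 5.1, 6.8]),
        "c": np.array([5.0, 1.0, 4.0, 0.5, 3.0, 1.0]),
    }
    def d(x, y):
        return 1 - np.corrcoef(rows[x], rows[y])[0, 1]

    dend = cluster_diseases(_matrix(rows))
    heights = sorted(dend.merge_heights)
    assert heights[0] == pytest.approx(d("a", "b"), abs=1e-12)
    assert heights[1] == pytest.approx((d("a", "c") + d("b", "c")) / 2, abs=1e-12)


def test_merge_heights_nondecreasing_and_leaves_complete():
    mat = _mouse_matrix(_two_group_specs(), noise_cv=0.2, seed=3)
    dend = cluster_diseases(mat)
    assert (np.diff(dend.merge_heights) >= -1e-12).all()
    assert sorted(dend.labels) == sorted(mat.diseases)


def test_two_planted_groups_split_exactly_at_k2():
    mat = _mouse_matrix(_two_group_specs(), noise_cv=0.0, seed=1)
    groups = cut_tree(cluster_diseases(mat), 2)
    young = {groups[c] for c in groups if c.startswith("Y:")}
    old = {groups[c] for c in groups if c.startswith("O:")}
    assert len(young) == 1 and len(old) == 1 and young != old


def test_row_permutation_leaves_merge_heights_unchanged():
    mat = _mouse_matrix(_two_group_specs(), noise_cv=0.1, seed=9)
    dend1 = cluster_diseases(mat)
    perm = mat.data.sample(frac=1.0, random_state=4)
    dend2 = cluster_diseases(AgeDiseaseMatrix("mouse", 1.0, perm, normalized=True))
    assert np.allclose(sorted(dend1.merge_heights), sorted(dend2.merge_heights), atol=1e-9)


def test_cut_tree_bounds_and_extremes():
    mat = _mouse_matrix(_two_group_specs(2), noise_cv=0.0, seed=2)
    dend = cluster_diseases(mat)
    assert len(set(cut_tree(dend, 1).values())) == 1
    assert len(set(cut_tree(dend, dend.n_leaves).values())) == dend.n_leaves
    with pytest.raises(ValueError):
        cut_tree(dend, 0)
    with pytest.raises(ValueError):
        cut_tree(dend, dend.n_leaves + 1)


def test_zero_variance_row_removed_and_too_few_rows_error():
    v = np.exp(-0.5 * ((np.arange(50) - 20) / 5.0) ** 2)
    dend = cluster_diseases(_matrix({"a": v, "b": v[::-1], "flat": np.ones(50)}))
    assert "flat" not in dend.labels
    with pytest.raises(ValueError, match="at least 2"):
        cluster_diseases(_matrix({"a": v, "flat": np.ones(50)}))


def test_newick_export_parses_and_preserves_leaves():
    import io

    from Bio import Phylo

    mat = _mouse_matrix(_two_group_specs(3), noise_cv=0.0, seed=6)
    dend = cluster_diseases(mat)
    tree = Phylo.read(io.StringIO(to_newick(dend)), "newick")
    leaves = {t.name for t in tree.get_terminals()}
    assert leaves == set(dend.labels)
    # path length from root to any leaf equals the root merge height
    depths = tree.depths()
    leaf_depths = {c: d for c, d in depths.items() if c.name in leaves}
    assert np.allclose(list(leaf_depths.values()), dend.merge_heights.max(), atol=1e-6)
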