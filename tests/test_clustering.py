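"""Outlier removal, k-means mode assignment, bootstrap, z-test, contours."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hprw import (
    TAGS,
    bootstrap_proportions,
    cluster_cells,
    joint_density_contours,
    label_and_merge,
    remove_outliers,
    two_proportion_z_test,
)
from hprw.clustering import TAG_HIGH, TAG_LOW, TAG_MID


def blobs(centers, sizes, sd, seed=0):
    rng = np.random.default_rng(seed)
    pts = [rng.normal(c, sd, size=(n, 2)) for c, n in zip(centers, sizes)]
    return np.vstack(pts)


# --- outliers -----------------------------------------------------------


def test_far_point_is_the_only_outlier():
    rng = np.random.default_rng(1)
    blob = rng.normal([0.5, 2.0], [0.02, 0.05], size=(100, 2))
    # far on both axes so the blob stays tight after z-standardization
    x = np.vstack([blob, [[10.0, 30.0]]])
    inliers = remove_outliers(x, eps=0.5, min_pts=5)
    assert inliers[:100].all() and not inliers[100]


def test_identical_points_are_all_inliers():
    x = np.tile([[0.5, 2.0]], (20, 1))
    assert remove_outliers(x).all()


def test_empty_and_tiny_inputs():
    assert remove_outliers(np.empty((0, 2))).size == 0
    with pytest.warns(UserWarning, match="keeping all"):
        mask = remove_outliers(np.zeros((3, 2)), min_pts=5)
    assert mask.all()


# --- k-means ------------------------------------------------------------


def test_two_blob_perfect_recovery():
    x = blobs([[0.2, 1.0], [0.9, 4.0]], [60, 40], sd=0.01)
    report = cluster_cells(x, k=2, seed=0)
    labels = report.labels
    assert len(set(labels[:60])) == 1 and len(set(labels[60:])) == 1
    assert labels[0] != labels[-1]
    # centroids back in original units
    got = sorted(report.centroids[:, 1])
    assert got[0] == pytest.approx(1.0, abs=0.05) and got[1] == pytest.approx(4.0, abs=0.05)


def test_k1_centroid_is_mean():
    x = blobs([[0.5, 2.0]], [50], sd=0.1)
    report = cluster_cells(x, k=1, seed=0, silhouette_range=(2, 1))
    assert np.allclose(report.centroids[0], x.mean(axis=0))


def test_clustering_deterministic():
    x = blobs([[0.2, 1.0], [0.9, 4.0], [0.5, 2.0]], [40, 40, 40], sd=0.05)
    r1 = cluster_cells(x, k=3, seed=7)
    r2 = cluster_cells(x, k=3, seed=7)
    assert np.array_equal(r1.labels, r2.labels)
    assert np.allclose(r1.centroids, r2.centroids)


def test_too_few_cells_error():
    with pytest.raises(ValueError, match="k=4"):
        cluster_cells(np.zeros((3, 2)), k=4)


def test_silhouette_reported_as_diagnostic():
    x = blobs([[0.2, 1.0], [0.9, 4.0]], [50, 50], sd=0.02)
    report = cluster_cells(x, k=2, seed=0)
    assert set(report.silhouette_by_k) == {2, 3, 4, 5, 6}
    assert report.silhouette_by_k[2] > 0.8  # well-separated pair


# --- tag rule and merging ----------------------------------------------


def _report_with_centroids(centroids, labels):
    from hprw.clustering import ClusterReport

    centroids = np.asarray(centroids, dtype=float)
    return ClusterReport(
        inlier_mask=np.ones(len(labels), dtype=bool),
        centroids=centroids,
        labels=np.asarray(labels),
        k_used=len(centroids),
        silhouette_by_k={},
    )


def test_k4_merge_rule_and_proportions():
    # centroids as (q, a); activities 4, 1.5, 0.3, 0.05
    cent = [[0.8, 4.0], [0.7, 1.5], [0.3, 0.3], [0.1, 0.05]]
    labels = [0] * 60 + [1] * 25 + [2] * 10 + [3] * 5
    report = label_and_merge(_report_with_centroids(cent, labels))
    assert report.tags == [TAG_HIGH, TAG_MID, TAG_LOW, TAG_LOW]
    assert report.proportions == pytest.approx(
        {TAG_HIGH: 0.60, TAG_MID: 0.25, TAG_LOW: 0.15}
    )


def test_k3_rule_uses_persistence_for_low_activity_pair():
    cent = [[0.9, 4.0], [0.9, 1.0], [0.2, 1.0]]
    report = label_and_merge(_report_with_centroids(cent, [0, 1, 2]))
    assert report.tags == [TAG_HIGH, TAG_MID, TAG_LOW]


def test_tag_rule_invariant_to_index_permutation():
    cent = [[0.8, 4.0], [0.7, 1.5], [0.3, 0.3], [0.1, 0.05]]
    labels = [0] * 60 + [1] * 25 + [2] * 10 + [3] * 5
    base = label_and_merge(_report_with_centroids(cent, labels))
    perm = [2, 0, 3, 1]  # relabel clusters
    cent_p = [cent[i] for i in np.argsort(perm)]
    labels_p = [perm[c] for c in labels]
    permuted = label_and_merge(_report_with_centroids(cent_p, labels_p))
    assert permuted.proportions == base.proportions


def test_activity_tie_broken_by_persistence():
    cent = [[0.8, 4.0], [0.6, 1.0], [0.2, 1.0], [0.4, 1.0]]
    report = label_and_merge(_report_with_centroids(cent, [0, 1, 2, 3]))
    # among tied a=1.0 the two lowest-q merge; highest-q of them is mid
    assert report.tags == [TAG_HIGH, TAG_MID, TAG_LOW, TAG_LOW]
    assert any("tie" in n for n in report.notes)


def test_merge_requires_k_3_or_4():
    with pytest.raises(ValueError):
        label_and_merge(_report_with_centroids([[0, 1], [0, 2]], [0, 1]))


# --- bootstrap ----------------------------------------------------------


def test_bootstrap_single_rep_equals_hand_run():
    x = blobs([[0.2, 0.5], [0.8, 3.0], [0.8, 1.2]], [50, 30, 20], sd=0.03, seed=2)
    seed = 11
    boot = bootstrap_proportions(x, k=3, n_reps=1, seed=seed)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=len(x))
    rep_seed = int(rng.integers(0, 2**31 - 1))
    sub = x[idx]
    inl = remove_outliers(sub)
    rep = label_and_merge(cluster_cells(sub, k=3, seed=rep_seed, inlier_mask=inl,
                                        silhouette_range=(2, 1)))
    for tag in TAGS:
        assert boot.mean_proportions[tag] == pytest.approx(rep.proportions[tag])


def test_bootstrap_single_blob_concentrates():
    x = blobs([[0.5, 2.0]], [80], sd=0.02, seed=3)
    boot = bootstrap_proportions(x, k=3, n_reps=5, seed=0, min_pts=3, eps=1.0)
    total = sum(boot.mean_proportions.values())
    assert total == pytest.approx(1.0, abs=1e-6)
    assert boot.mean_cumulative[TAGS[-1]] == pytest.approx(1.0, abs=1e-9)


def test_bootstrap_proportions_sum_to_one():
    x = blobs([[0.2, 0.5], [0.8, 3.0], [0.8, 1.2]], [50, 30, 20], sd=0.03, seed=4)
    boot = bootstrap_proportions(x, k=3, n_reps=10, seed=1)
    assert sum(boot.mean_proportions.values()) == pytest.approx(1.0, abs=1e-6)


# --- z-test -------------------------------------------------------------


def test_ztest_equal_proportions():
    z, p = two_proportion_z_test(30, 100, 15, 50)
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_ztest_worked_example():
    z, p = two_proportion_z_test(30, 100, 50, 100)
    assert z == pytest.approx(-2.886751, abs=1e-5)
    assert p == pytest.approx(0.0038924, abs=1e-6)


def test_ztest_antisymmetry():
    z1, p1 = two_proportion_z_test(12, 40, 30, 70)
    z2, p2 = two_proportion_z_test(30, 70, 12, 40)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)


def test_ztest_degenerate_pool():
    z, p = two_proportion_z_test(0, 10, 0, 20)
    assert np.isnan(z) and p == 1.0
    with pytest.raises(ValueError):
        two_proportion_z_test(5, 4, 1, 10)


# --- contours -----------------------------------------------------------


def test_contour_single_bin():
    cs = joint_density_contours(np.full(10, 0.55), np.full(10, 2.05),
                                bins=(10, 10), a_domain=(0, 10))
    for level in cs.levels:
        assert cs.masks[level].sum() == 1
        assert cs.contained_mass(level) == 1.0


def test_contour_uniform_mass_half_region():
    """Uniform mass over a 10x10 grid: the 50% region holds exactly 50 bins."""
    q = (np.arange(100) % 10 + 0.5) / 10
    a = (np.arange(100) // 10 + 0.5)
    cs = joint_density_contours(q, a, bins=(10, 10), a_domain=(0, 10))
    assert cs.masks[0.5].sum() == 50
    assert cs.contained_mass(0.5) == pytest.approx(0.5)


def test_contour_thresholds_monotone():
    rng = np.random.default_rng(5)
    q = np.clip(rng.normal(0.5, 0.15, 4000), 0, 1)
    a = np.clip(rng.normal(3, 0.8, 4000), 0, 10)
    cs = joint_density_contours(q, a)
    assert cs.thresholds[0.5] >= cs.thresholds[0.8] >= cs.thresholds[0.95]
    for level in cs.levels:
        assert cs.contained_mass(level) >= level


def test_contour_marginals_and_exclusion():
    q = np.array([0.5, 0.5, 1.5])  # third point outside q domain
    a = np.array([2.0, 3.0, 2.0])
    cs = joint_density_contours(q, a, bins=(5, 5), a_domain=(0, 10))
    assert cs.n_excluded == 1
    assert cs.marginal_q.sum() == pytest.approx(1.0)
    assert cs.marginal_a.sum() == pytest.approx(1.0)


def test_contour_empty_domain_error():
    with pytest.raises(ValueError):
        joint_density_contours(np.array([2.0]), np.array([2.0]))


def test_fixed_inlier_bootstrap_mode():
    x = blobs([[0.2, 0.5], [0.8, 3.0], [0.8, 1.2]], [50, 30, 20], sd=0.03, seed=6)
    boot = bootstrap_proportions(x, k=3, n_reps=10, seed=2, refit_outliers=False)
    assert sum(boot.mean_proportions.values()) == pytest.approx(1.0, abs=1e-6)
    for tag, frac in zip(TAGS, (0.3, 0.2, 0.5)):
        assert boot.mean_proportions[tag] == pytest.approx(frac, abs=0.06)


def test_k_distance_curve_sorted():
    from hprw import k_distance

    x = blobs([[0.2, 0.5], [0.8, 3.0]], [40, 40], sd=0.05, seed=7)
    d = k_distance(x, k=5)
    assert d.shape == (80,)
    assert np.all(np.diff(d) >= 0)


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    x1=st.integers(0, 50), n1=st.integers(1, 50),
    x2=st.integers(0, 50), n2=st.integers(1, 50),
)
def test_ztest_sign_and_symmetry_property(x1, n1, x2, n2):
    """z carries the sign of p1 - p2 and swapping groups negates it."""
    x1, x2 = min(x1, n1), min(x2, n2)
    z, p = two_proportion_z_test(x1, n1, x2, n2)
    z_swap, p_swap = two_proportion_z_test(x2, n2, x1, n1)
    if np.isnan(z):
        assert p == 1.0 and np.isnan(z_swap)
        return
    assert 0.0 <= p <= 1.0
    assert np.sign(z) == np.sign(x1 / n1 - x2 / n2)
    assert z == pytest.approx(-z_swap) and p == pytest.approx(p_swap)
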