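"""Distance matrices, PCoA/PCA, standardization, variable screening."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes

from exuvar.distances import (
    DistanceMatrix,
    bray_curtis,
    euclidean_geographic,
    membership_distance,
    membership_distances,
    ordination_distance,
    pca,
    pca_distance,
    pcoa,
    select_uncorrelated,
    standardize,
)


def frame(rows, index=None, cols=None):
    rows = np.asarray(rows, dtype=float)
    index = index or [f"a{i}" for i in range(rows.shape[0])]
    cols = cols or [f"v{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=index, columns=cols)


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([0.2, 0.8], [0.2, 0.8], 0.0),
            ([1.0, 0.0], [0.0, 1.0], 1.0),
            ([0.2, 0.8], [0.5, 0.5], 0.3),
        ],
    )
    def test_pairwise_values(self, x, y, expected):
        dm = bray_curtis(frame([x, y]))
        assert dm.d[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_subset_and_partition(self):
        rng = np.random.default_rng(0)
        tab = frame(rng.random((6, 10)))
        labels = ["p1"] * 4 + ["p2"] * 6
        subsets = {
            p: [c for c, l in zip(tab.columns, labels) if l == p]
            for p in ("p1", "p2")
        }
        total = sum(len(v) for v in subsets.values())
        assert total == tab.shape[1]
        for ids in subsets.values():
            dm = bray_curtis(tab, feature_subset=ids)
            assert dm.d.max() <= 1.0 and dm.d.min() >= 0.0

    def test_zero_profile_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(frame([[0.0, 0.0], [1.0, 1.0]]))

    def test_triangle_violations_counted_not_fatal(self):
        d = np.array(
            [[0, 0.9, 0.1], [0.9, 0, 0.1], [0.1, 0.1, 0]]
        )
        dm = DistanceMatrix(["a", "b", "c"], d, kind="bray_curtis")
        assert dm.triangle_violations() >= 1


class TestPcoa:
    def test_collinear_points_single_axis(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        d = np.abs(pts - pts.T)
        ord_ = pcoa(DistanceMatrix(["a", "b", "c"], d), k=1)
        assert ord_.variance_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_duality_with_pca(self):
        """PCoA of Euclidean distances == PCA of the generating cloud."""
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, (20, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        tab = frame(pts)
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(list(tab.index), squareform(pdist(pts)))
        ord_pcoa = pcoa(dm, k=3)
        ord_pca = pca(tab, n_axes=3)
        np.testing.assert_allclose(
            ord_pcoa.variance_fraction, ord_pca.variance_fraction, atol=1e-8
        )

    def test_configuration_recovered_up_to_rotation(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (15, 2))
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix([f"a{i}" for i in range(15)], squareform(pdist(pts)))
        coords = pcoa(dm, k=2).coordinates.to_numpy()
        _, _, disparity = procrustes(pts - pts.mean(0), coords)
        assert disparity < 1e-6

    def test_non_euclidean_fractions_bounded(self):
        d = np.array(
            [[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0.05]]
        )
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        with pytest.warns(UserWarning):
            ord_ = pcoa(DistanceMatrix(list("abcd"), d), k=4)
        assert (ord_.variance_fraction <= 1 + 1e-12).all()


class TestStandardize:
    def test_hand_zscores(self):
        # (1,2,3): mean 2, sd sqrt(2/3) -> z = (-1.2247, 0, 1.2247)
        z = standardize(frame([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(
            z.iloc[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8
        )

    def test_idempotent_on_standardized(self):
        rng = np.random.default_rng(3)
        tab = frame(rng.normal(0, 1, (50, 3)))
        z1 = standardize(tab)
        z2 = standardize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_constant_column_named(self):
        with pytest.raises(ValueError, match="v1"):
            standardize(frame([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))

    def test_variance_scaling_switch(self):
        # (2,4,6): mean 4, population variance 8/3 -> (-0.75, 0, 0.75)
        tab = frame([[2.0], [4.0], [6.0]])
        z = standardize(tab, by="variance")
        np.testing.assert_allclose(z.iloc[:, 0], [-0.75, 0.0, 0.75], atol=1e-12)


class TestPcaDistance:
    def test_low_rank_table_fully_explained(self):
        rng = np.random.default_rng(4)
        basis = rng.normal(0, 1, (2, 6))
        scores = rng.normal(0, 1, (30, 2))
        tab = frame(scores @ basis)
        with pytest.warns(UserWarning, match="rank"):
            ord_, dm = pca_distance(tab, n_axes=3)
        assert ord_.variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert dm.n == 30

    def test_distance_matches_scores(self):
        rng = np.random.default_rng(5)
        tab = frame(rng.normal(0, 1, (12, 5)))
        ord_, dm = pca_distance(standardize(tab), n_axes=3)
        from scipy.spatial.distance import pdist, squareform

        np.testing.assert_allclose(
            dm.d, squareform(pdist(ord_.coordinates.to_numpy())), atol=1e-12
        )


class TestGeographic:
    def test_345_triangle_and_translation(self):
        tab = frame([[0.0, 0.0], [3.0, 4.0]], cols=["lon", "lat"])
        dm = euclidean_geographic(tab)
        assert dm.d[0, 1] == pytest.approx(5.0)
        dm2 = euclidean_geographic(tab + 10.0)
        np.testing.assert_allclose(dm.d, dm2.d, atol=1e-12)


class TestMembership:
    def test_absolute_difference(self):
        m = pd.Series([0.7, 0.7, 0.9, 0.4], index=list("abcd"))
        dm = membership_distance(m)
        assert dm.d[0, 1] == 0.0
        assert dm.d[2, 3] == pytest.approx(0.5)

    def test_four_matrices_from_table(self):
        rng = np.random.default_rng(6)
        mem = rng.dirichlet([1, 1, 1, 1], size=8)
        tab = frame(mem, cols=["C1", "C2", "C3", "C4"])
        mats = membership_distances(tab)
        assert sorted(mats) == ["C1", "C2", "C3", "C4"]
        assert all(m.n == 8 for m in mats.values())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            membership_distance(pd.Series([0.5, 1.2]))


class TestSelectUncorrelated:
    def test_perfect_pair_drops_second(self):
        x = np.arange(10.0)
        tab = frame(np.column_stack([x, 2 * x + 1]), cols=["A", "B"])
        assert select_uncorrelated(tab) == ["A"]

    def test_orthogonal_all_kept(self):
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(0, 1, (40, 3)))
        tab = frame(q, cols=["A", "B", "C"])
        assert select_uncorrelated(tab) == ["A", "B", "C"]

    def test_greedy_chain(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 400)
        e1, e2 = rng.normal(0, 1, (2, 400))
        b = 0.8 * a + 0.6 * e1  # r(A,B) ~ 0.8
        c = 0.8 * b + 0.6 * e2  # r(B,C) ~ 0.8, r(A,C) ~ 0.64 < 0.7
        tab = frame(np.column_stack([a, b, c]), cols=["A", "B", "C"])
        assert select_uncorrelated(tab, threshold=0.7) == ["A", "C"]
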