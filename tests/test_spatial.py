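import numpy as np
import pytest

from colocal.data_model import CellImage, ImageSet, Window
from colocal.spatial import (
    CORRECTIONS,
    DEFAULT_RADII,
    CurveEstimate,
    RadiusGrid,
    colocalization_score,
    kcross,
    lcross,
    score_all,
)

from .oracles import naive_kcross
from .conftest import random_image


class TestRadiusGrid:
    def test_single_radius_is_legal(self):
        assert len(RadiusGrid([25.0])) == 1

    @pytest.mark.parametrize("bad", [[], [0.0, 10.0], [10.0, 10.0], [10.0, 5.0]])
    def test_invalid_grids_raise(self, bad):
        with pytest.raises(ValueError):
            RadiusGrid(bad)

    def test_default_grid(self):
        assert DEFAULT_RADII == tuple(float(r) for r in range(10, 101, 10))


class TestKcross:
    def test_single_pair_closed_form(self, one_pair_image):
        k = kcross(one_pair_image, "i", "j", [10.0], correction="none")
        assert k.values[0] == pytest.approx(10_000.0)
        assert kcross(one_pair_image, "i", "j", [4.0], "none").values[0] == 0.0

    def test_zero_count_gives_undefined_curve(self, one_pair_image):
        k = kcross(one_pair_image, "i", "missing", [10.0])
        assert np.isnan(k.values).all()
        assert not k.defined

    def test_unknown_correction_raises(self, one_pair_image):
        with pytest.raises(ValueError, match="correction"):
            kcross(one_pair_image, "i", "j", [10.0], correction="banana")

    @pytest.mark.parametrize("correction", CORRECTIONS)
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_naive_double_loop(self, correction, seed):
        """Cross-type K equals a brute-force ordered-pair sum, for every
        edge correction, on random patterns."""
        rng = np.random.default_rng(seed)
        n_i = int(rng.integers(5, 50))
        n_j = int(rng.integers(5, 50))
        img = random_image(rng, n_i, n_j, side=500.0)
        radii = [25.0, 50.0, 100.0, 200.0]
        got = kcross(img, "i", "j", radii, correction).values
        want = naive_kcross(img, "i", "j", radii, correction)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    @pytest.mark.parametrize("correction", CORRECTIONS)
    def test_same_type_matches_naive_and_excludes_self_pairs(self, correction):
        rng = np.random.default_rng(123)
        img = random_image(rng, 40, 0, side=300.0)
        radii = [20.0, 60.0, 150.0]
        got = kcross(img, "i", "i", radii, correction).values
        want = naive_kcross(img, "i", "i", radii, correction)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    @pytest.mark.parametrize("correction", CORRECTIONS)
    def test_monotone_in_radius(self, correction):
        rng = np.random.default_rng(7)
        img = random_image(rng, 30, 30)
        k = kcross(img, "i", "j", DEFAULT_RADII, correction).values
        assert (np.diff(k) >= 0).all()

    def test_symmetry_of_pair_counts_without_correction(self):
        """n_i n_j K_ij / W is the unordered pair count: symmetric in (i,j)."""
        rng = np.random.default_rng(99)
        img = random_image(rng, 20, 35)
        kij = kcross(img, "i", "j", DEFAULT_RADII, "none")
        kji = kcross(img, "j", "i", DEFAULT_RADII, "none")
        np.testing.assert_allclose(
            kij.n_i * kij.n_j * kij.values, kji.n_i * kji.n_j * kji.values,
            rtol=1e-12,
        )


class TestLcross:
    def test_csr_identity(self):
        r = np.array([10.0, 20.0, 30.0])
        k = CurveEstimate(RadiusGrid(r), np.pi * r**2, "K", "i", "j", "none")
        np.testing.assert_allclose(lcross(k).values, r, rtol=1e-14)

    def test_zero_and_closed_form(self, one_pair_image):
        k = kcross(one_pair_image, "i", "j", [4.0, 10.0], "none")
        l_curve = lcross(k)
        assert l_curve.values[0] == 0.0
        assert l_curve.values[1] == pytest.approx(np.sqrt(10_000 / np.pi))

    def test_rejects_l_input(self, one_pair_image):
        l_curve = lcross(kcross(one_pair_image, "i", "j", [10.0], "none"))
        with pytest.raises(ValueError):
            lcross(l_curve)

    def test_nan_propagates(self, one_pair_image):
        k = kcross(one_pair_image, "i", "nope", [10.0])
        assert np.isnan(lcross(k).values).all()


class TestColocalizationScore:
    def test_null_identity_zero(self):
        """Sum of L - r vanishes when L equals the Poisson reference."""
        r = np.asarray(DEFAULT_RADII)
        k = CurveEstimate(RadiusGrid(r), np.pi * r**2, "K", "i", "j", "none")
        u = float(np.sum(lcross(k).values - r))
        assert u == pytest.approx(0.0, abs=1e-10)

    def test_single_radius_reduces_to_l_minus_r(self, one_pair_image):
        u, n_i, n_j = colocalization_score(one_pair_image, "i", "j", [10.0], "none")
        assert (n_i, n_j) == (1, 1)
        assert u == pytest.approx(np.sqrt(10_000 / np.pi) - 10.0)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    @pytest.mark.parametrize("correction", CORRECTIONS)
    def test_scale_equivariance(self, c, correction):
        """Scaling coordinates, window and radii by c scales u by c."""
        rng = np.random.default_rng(5)
        img = random_image(rng, 30, 30, side=500.0)
        scaled = CellImage("s", img.x * c, img.y * c, img.marks,
                           Window(0, 500.0 * c, 0, 500.0 * c))
        radii = np.array([20.0, 50.0, 90.0])
        u1, *_ = colocalization_score(img, "i", "j", radii, correction)
        u2, *_ = colocalization_score(scaled, "i", "j", radii * c, correction)
        assert u2 == pytest.approx(c * u1, rel=1e-9)

    def test_undefined_when_count_zero(self, one_pair_image):
        u, n_i, n_j = colocalization_score(one_pair_image, "i", "ghost", [10.0])
        assert np.isnan(u) and n_j == 0


class TestScoreAll:
    def test_cardinality_with_self_pairs(self, small_study):
        study, _ = small_study
        t = score_all(study, ["A", "B"])
        assert len(t) == len(study) * 4
        pairs = set(map(tuple, t[["type_i", "type_j"]].drop_duplicates().values))
        assert pairs == {("A", "A"), ("A", "B"), ("B", "A"), ("B", "B")}

    @pytest.mark.parametrize("correction", CORRECTIONS)
    def test_rows_match_single_scores(self, small_study, correction):
        """Every table row reproduces colocalization_score called singly."""
        study, _ = small_study
        t = score_all(study, ["A", "B"], correction=correction)
        sub = t.iloc[:: max(len(t) // 12, 1)]
        for row in sub.itertuples():
            u, n_i, n_j = colocalization_score(
                study.images[row.image_id], row.type_i, row.type_j,
                DEFAULT_RADII, correction,
            )
            assert (n_i, n_j) == (row.n_i, row.n_j)
            if np.isnan(u):
                assert np.isnan(row.u)
            else:
                assert row.u == pytest.approx(u, rel=1e-9, abs=1e-9)

    def test_absent_type_raises(self, small_study):
        study, _ = small_study
        with pytest.raises(ValueError, match="ghost"):
            score_all(study, ["A", "ghost"])

    def test_zero_count_row_is_missing_not_error(self, window100):
        s = ImageSet()
        s.add_image(CellImage("a", [10.0, 20.0, 30.0], [10.0, 20.0, 30.0],
                              ["t1", "t1", "t2"], window100), "p1", "g")
        s.add_image(CellImage("b", [10.0, 20.0], [10.0, 20.0],
                              ["t1", "t1"], window100), "p2", "g")
        t = score_all(s, ["t1", "t2"])
        missing = t[(t.image_id == "b") & (t.type_j == "t2")]
        assert missing["u"].isna().all()
        assert (missing["n_j"] == 0).all()
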