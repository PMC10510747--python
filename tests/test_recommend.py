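import numpy as np
import pytest
from scipy.stats import chisquare

from dbtlsim.design_space import DesignGrid, enumerate_designs
from dbtlsim.recommend import (
    RecommendationDistribution,
    curve_to_distribution,
    recommend_designs,
    threshold_sweep,
)


@pytest.fixture(scope="module")
def space27():
    grid = DesignGrid(enzymes=("a", "b", "c"), levels=(0.5, 1.0, 2.0))
    return grid, enumerate_designs(grid)


def brute_force_sweep(y, designs, grid, n_eval):
    """Exhaustive recount oracle for the threshold sweep."""
    y = np.clip(y, 0.0, None)
    thresholds = np.linspace(0.0, y.max(), n_eval)
    freqs, kept, counts = [], [], []
    for lam in thresholds:
        surv = designs[y >= lam]
        if len(surv) == 0:
            break
        f = np.zeros((grid.n_enzymes, grid.n_levels))
        for j in range(grid.n_enzymes):
            for p, lv in enumerate(grid.levels):
                f[j, p] = np.sum(surv[:, j] == lv) / len(surv)
        freqs.append(f)
        kept.append(lam)
        counts.append(len(surv))
    return np.array(kept), np.array(freqs), np.array(counts)


class TestThresholdSweep:
    def test_zero_threshold_frequencies_are_exactly_uniform(self, space27):
        grid, designs = space27
        y = np.random.default_rng(0).uniform(0.1, 2.0, len(designs))
        curve = threshold_sweep(y, designs, grid)
        assert np.all(curve.frequencies[0] == 1.0 / grid.n_levels)

    def test_single_survivor_near_maximum(self, space27):
        grid, designs = space27
        y = np.linspace(0.1, 1.0, len(designs))  # unique maximum at last design
        curve = threshold_sweep(y, designs, grid, n_eval=50)
        top = curve.frequencies[-1]
        winner = designs[np.argmax(y)]
        for j, lv in enumerate(winner):
            p = grid.levels.index(lv)
            assert top[j, p] == 1.0
            assert np.all(np.delete(top[j], p) == 0.0)

    def test_matches_brute_force_recount(self, space27):
        grid, designs = space27
        rng = np.random.default_rng(1)
        for _ in range(10):
            y = rng.uniform(0.0, 3.0, len(designs))
            curve = threshold_sweep(y, designs, grid, n_eval=40)
            kept, freqs, counts = brute_force_sweep(y, designs, grid, 40)
            np.testing.assert_allclose(curve.thresholds, kept)
            np.testing.assert_allclose(curve.frequencies, freqs, atol=1e-12)
            np.testing.assert_array_equal(curve.n_survivors, counts)

    def test_survivor_count_monotone_nonincreasing(self, space27):
        grid, designs = space27
        y = np.random.default_rng(2).uniform(0.0, 1.0, len(designs))
        curve = threshold_sweep(y, designs, grid)
        assert np.all(np.diff(curve.n_survivors) <= 0)

    def test_frequencies_sum_to_one_at_every_threshold(self, space27):
        grid, designs = space27
        y = np.random.default_rng(3).uniform(0.0, 1.0, len(designs))
        curve = threshold_sweep(y, designs, grid)
        np.testing.assert_allclose(curve.frequencies.sum(axis=2), 1.0, atol=1e-9)

    def test_all_nonpositive_predictions_rejected(self, space27):
        grid, designs = space27
        with pytest.raises(ValueError, match="degenerate"):
            threshold_sweep(np.full(len(designs), -1.0), designs, grid)


class TestDistribution:
    def test_flat_curves_give_uniform_distribution(self, space27):
        grid, designs = space27
        y = np.ones(len(designs))  # every design identical: curves are flat
        dist = curve_to_distribution(threshold_sweep(y, designs, grid))
        np.testing.assert_allclose(dist.probs, 1.0 / grid.n_levels, atol=1e-12)

    def test_dominant_level_receives_largest_probability(self, space27):
        grid, designs = space27
        y = np.where(designs[:, 0] == 2.0, 2.0, 0.5)  # enzyme a at level 2 wins
        dist = curve_to_distribution(threshold_sweep(y, designs, grid))
        assert dist.probs[0].argmax() == grid.levels.index(2.0)

    def test_two_level_degenerate_curve(self):
        from dbtlsim.recommend import ThresholdCurve

        grid = DesignGrid(enzymes=("a",), levels=(1.0, 2.0))
        thresholds = np.linspace(0.0, 1.0, 10)
        freqs = np.tile([[1.0, 0.0]], (10, 1, 1))  # frequencies (1, 0) throughout
        curve = ThresholdCurve(
            thresholds=thresholds,
            frequencies=freqs,
            n_survivors=np.full(10, 2),
            grid=grid,
        )
        dist = curve_to_distribution(curve)
        np.testing.assert_allclose(dist.probs[0], [1.0, 0.0], atol=1e-12)

    def test_normalization_within_tolerance(self, space27):
        grid, designs = space27
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.uniform(0.0, 1.0, len(designs))
            dist = curve_to_distribution(threshold_sweep(y, designs, grid))
            np.testing.assert_allclose(dist.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_equivariance(self, space27):
        """Multiplying predictions by c > 0 leaves the distribution unchanged."""
        grid, designs = space27
        y = np.random.default_rng(5).uniform(0.0, 1.0, len(designs))
        d1 = curve_to_distribution(threshold_sweep(y, designs, grid))
        d2 = curve_to_distribution(threshold_sweep(7.3 * y, designs, grid))
        np.testing.assert_allclose(d1.probs, d2.probs, atol=1e-12)


class TestRecommendDesigns:
    def test_deterministic_distribution_gives_identical_designs(self):
        grid = DesignGrid(enzymes=("a", "b"), levels=(0.5, 1.0, 2.0))
        probs = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        dist = RecommendationDistribution(probs=probs, grid=grid)
        designs = recommend_designs(dist, 25, seed=0)
        assert np.all(designs == [2.0, 0.5])

    def test_uniform_distribution_matches_equal_sampling(self):
        grid = DesignGrid(enzymes=("a",), levels=(0.5, 1.0, 2.0))
        dist = RecommendationDistribution(probs=np.full((1, 3), 1 / 3), grid=grid)
        designs = recommend_designs(dist, 60_000, seed=1)
        _, counts = np.unique(designs[:, 0], return_counts=True)
        assert chisquare(counts).pvalue > 0.01

    def test_perfect_predictor_boosts_the_optimum(self, params, toy_grid, toy_landscape):
        """With true fluxes as predictions, the best design's levels are favoured."""
        X = toy_landscape[list(toy_grid.enzymes)].to_numpy()
        y = toy_landscape["relative_flux"].to_numpy()
        best = X[np.argmax(y)]
        dist = curve_to_distribution(threshold_sweep(y, X, toy_grid))
        for j, lv in enumerate(best):
            p = toy_grid.levels.index(lv)
            assert dist.probs[j, p] > 1.0 / toy_grid.n_levels

    def test_sampling_reproducible(self):
        grid = DesignGrid(enzymes=("a", "b"), levels=(0.5, 1.0, 2.0))
        dist = RecommendationDistribution(probs=np.full((2, 3), 1 / 3), grid=grid)
        a = recommend_designs(dist, 40, seed=2)
        b = recommend_designs(dist, 40, seed=2)
        np.testing.assert_array_equal(a, b)
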