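import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from embryovar import synthetic, variability
from embryovar.geometry import NeighbourGraph
from embryovar.tables_io import ConsistencyError, ExpressionTable
from embryovar.variability import (
    apply_pv_filter,
    channel_concordance,
    count_histogram,
    fano_factor,
    nascent_ratio,
    numerical_variability,
    proportional_variability,
    score_embryo,
)

counts = st.integers(min_value=0, max_value=20)
groups = st.lists(counts, min_size=1, max_size=8)


class TestFano:
    @pytest.mark.parametrize(
        "values,expected",
        [([5] * 7, 0.0), ([0, 0, 4], 8 / 3), ([0, 0, 0], 0.0), ([7], 0.0)],
    )
    def test_known_values(self, values, expected):
        assert fano_factor(values) == pytest.approx(expected)

    def test_poisson_limit(self):
        rng = np.random.default_rng(12)
        draws = rng.poisson(20, size=100_000)
        assert fano_factor(draws) == pytest.approx(1.0, abs=0.02)

    def test_rejects_negative_and_fractional(self):
        with pytest.raises(ValueError):
            fano_factor([1, -2])
        with pytest.raises(ValueError):
            fano_factor([1.5, 2])

    @given(groups)
    def test_permutation_invariant_and_zero_for_constant(self, values):
        assert fano_factor(values) == pytest.approx(fano_factor(values[::-1]))
        assert fano_factor([max(values, default=1) or 1] * 5) == 0.0

    def test_sample_variance_option(self):
        assert fano_factor([0, 0, 4], variance="sample") == pytest.approx((16 / 3) / (4 / 3))


class TestNV:
    def test_single_transcript_among_zeros(self):
        assert numerical_variability(1, [0] * 6, 550) == pytest.approx(1 / 550)

    def test_no_variability(self):
        assert numerical_variability(7, [7, 7, 7], 100) == 0.0

    def test_maximal_case(self):
        assert numerical_variability(200, [0, 0, 0], 200) == 1.0

    def test_isolated_cell_is_zero(self):
        assert numerical_variability(5, [], 100) == 0.0

    def test_population_max_must_dominate(self):
        with pytest.raises(ValueError):
            numerical_variability(10, [3], 5)

    @given(counts, st.lists(counts, min_size=1, max_size=8), st.integers(0, 10))
    def test_shift_invariance(self, x, nb, c):
        base = numerical_variability(x, nb, 40)
        shifted = numerical_variability(x + c, [v + c for v in nb], 40 + c)
        # same population_max must be used for a fair comparison
        shifted_same_max = numerical_variability(x + c, [v + c for v in nb], 40)
        assert shifted_same_max == pytest.approx(base)
        assert shifted <= base + 1e-12 or c == 0


class TestPV:
    def test_isolated_single_transcript_scores_one(self):
        assert proportional_variability(1, [0] * 6) == 1.0

    def test_constant_group_scores_zero(self):
        assert proportional_variability(42, [42] * 4) == 0.0

    def test_half(self):
        assert proportional_variability(10, [5, 5, 5, 5]) == pytest.approx(0.5)

    def test_all_zero_group(self):
        assert proportional_variability(0, [0, 0, 0]) == 0.0

    def test_same_difference_larger_baseline_scores_lower(self):
        lo = proportional_variability(40, [10, 10, 10])
        hi_baseline = proportional_variability(240, [210, 210, 210])
        assert hi_baseline < lo

    @given(counts, st.lists(counts, min_size=1, max_size=8))
    def test_bounds(self, x, nb):
        pv = proportional_variability(x, nb)
        nv = numerical_variability(x, nb, 20)
        assert 0.0 <= pv <= 1.0
        assert 0.0 <= nv <= 1.0


class TestPVFilter:
    def test_silent_surroundings_filtered_to_zero(self):
        group = [1] + [0] * 6  # mean 1/7 < 1
        pv = proportional_variability(1, [0] * 6)
        assert pv == 1.0
        assert apply_pv_filter(pv, group) == 0.0

    def test_threshold_is_inclusive(self):
        assert apply_pv_filter(0.4, [1] * 7) == 0.4

    def test_expressing_group_retained(self):
        assert apply_pv_filter(0.25, [40, 35, 38]) == 0.25


class TestScoreEmbryo:
    def _chain(self, values, gene="eve"):
        ids = pd.Index([f"c{i}" for i in range(len(values))], name="cell_id")
        expr = ExpressionTable(
            counts=pd.DataFrame({gene: values}, index=ids),
            centroids=pd.DataFrame(
                {"centroid_x_um": np.arange(len(values), dtype=float),
                 "centroid_y_um": 0.0, "centroid_z_um": 0.0},
                index=ids,
            ),
        )
        edges = [(f"c{i}", f"c{i+1}") for i in range(len(values) - 1)]
        graph = NeighbourGraph.from_edges(list(ids), edges, "contact", 0.6)
        return expr, graph

    def test_three_cell_chain_peak(self):
        expr, graph = self._chain([0, 10, 0])
        scores = score_embryo(expr, graph).for_gene("eve")
        assert scores.loc["c1", "nv"] == pytest.approx(1.0)
        assert scores.loc["c1", "pv_raw"] == pytest.approx(1.0)

    def test_all_zero_gene_scores_zero(self):
        expr, graph = self._chain([0, 0, 0, 0])
        scores = score_embryo(expr, graph)
        assert (scores.frame[["fano", "nv", "pv_raw", "pv_filtered"]] == 0).all().all()

    def test_isolated_cells_flagged_and_zero(self):
        expr, _ = self._chain([5, 9, 3])
        graph = NeighbourGraph.from_edges(["c0", "c1", "c2"], [("c0", "c1")], "contact")
        frame = score_embryo(expr, graph).for_gene("eve")
        assert bool(frame.loc["c2", "isolated"])
        assert frame.loc["c2", ["fano", "nv", "pv_raw"]].eq(0).all()

    def test_graph_cell_missing_from_table_raises(self):
        expr, _ = self._chain([1, 2])
        graph = NeighbourGraph.from_edges(["c0", "c1", "ghost"], [], "contact")
        with pytest.raises(ConsistencyError, match="ghost"):
            score_embryo(expr, graph)

    def test_order_independent(self):
        expr, graph = self._chain([3, 8, 0, 12, 12])
        shuffled = ExpressionTable(
            counts=expr.counts.iloc[::-1], centroids=expr.centroids.iloc[::-1]
        )
        a = score_embryo(expr, graph).frame.set_index(["cell_id", "gene"]).sort_index()
        b = score_embryo(shuffled, graph).frame.set_index(["cell_id", "gene"]).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_fano_highlights_stripe_edges(self):
        spec = synthetic.PatternSpec("eve", "stripes", peak_mean_count=80.0,
                                     stripe_sigma=0.03)
        params = synthetic.SimParams(
            n_cells_target=600, aspect=6.0, seed=21, genes=[spec],
            count_noise="poisson",
        )
        cells, truth = synthetic.generate_lattice(params)
        expr = synthetic.sample_counts(cells, [spec], params, seed=22)
        frame = score_embryo(expr, truth).for_gene("eve")
        ap = pd.Series({c.cell_id: c.ap for c in cells})
        centres = np.linspace(spec.stripe_lo, spec.stripe_hi, spec.n_stripes)
        dist = ap.apply(lambda p: np.abs(centres - p).min())
        centre_cells = dist[dist <= 0.3 * spec.stripe_sigma].index
        edge_cells = dist[(dist >= spec.stripe_sigma) & (dist <= 2 * spec.stripe_sigma)].index
        assert len(centre_cells) > 10 and len(edge_cells) > 10
        assert frame.loc[edge_cells, "fano"].mean() > frame.loc[centre_cells, "fano"].mean()


class TestScenarioConsistency:
    """The defining behavioural contrasts between Fano, NV and PV."""

    def test_nv_constant_pv_decreasing_across_shifted_baselines(self):
        pop_max = 550
        base_x, base_nb = 330, [30] * 6  # large proportional + numerical contrast
        shift = 200
        nv_low = numerical_variability(base_x, base_nb, pop_max)
        nv_high = numerical_variability(base_x + shift, [v + shift for v in base_nb], pop_max)
        assert nv_low == pytest.approx(nv_high)
        pv_low = proportional_variability(base_x, base_nb)
        pv_high = proportional_variability(base_x + shift, [v + shift for v in base_nb])
        assert pv_high < pv_low

    def test_focal_equal_to_all_but_one_neighbour_scores_low(self):
        x, nb = 30, [30, 30, 30, 30, 30, 330]
        assert numerical_variability(x, nb, 550) < 0.2
        assert proportional_variability(x, nb) < 0.2
        assert proportional_variability(x, nb) < proportional_variability(330, [30] * 6)


class TestHistogram:
    def test_bins_of_five_zero_excluded(self):
        assert count_histogram([0, 1, 5, 6]) == {"1-5": 2, "6-10": 1}

    def test_empty_and_all_zero(self):
        assert count_histogram([]) == {}
        assert count_histogram([0, 0, 0]) == {}

    def test_zero_included_when_requested(self):
        # zeros get their own bin so the positive bins keep the 1-based edges
        h = count_histogram([0, 3], exclude_zero=False)
        assert h == {"0": 1, "1-5": 1}

    def test_conservation_over_random_draws(self):
        rng = np.random.default_rng(5)
        draws = rng.poisson(12, size=10_000)
        hist = count_histogram(list(draws))
        assert sum(hist.values()) == int((draws > 0).sum())

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            count_histogram([3, -1])


class TestNascentRatio:
    @pytest.mark.parametrize("site,single,expected", [(100, 10, 10.0), (0, 10, 0.0)])
    def test_simple_ratios(self, site, single, expected):
        assert nascent_ratio(site, single) == expected

    def test_sum_of_k_singles_gives_k(self):
        rng = np.random.default_rng(7)
        singles = rng.lognormal(0, 0.2, size=200)
        k = 12
        site = singles[:k].sum()
        assert nascent_ratio(site, singles[:k].mean()) == pytest.approx(k)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            nascent_ratio(10, 0)


class TestConcordance:
    def test_identical_vectors(self):
        assert channel_concordance([1, 5, 9, 2], [1, 5, 9, 2]) == pytest.approx(1.0)

    def test_reversed_ranks(self):
        assert channel_concordance([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_constant_vector_reported_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(channel_concordance([3, 3, 3], [1, 2, 3]))

    def test_thinned_channels_of_patterned_counts_concordant(self):
        params = synthetic.SimParams(n_cells_target=500, seed=31)
        cells, _ = synthetic.generate_lattice(params)
        spec = synthetic.PatternSpec("Kr", "broad_domain", peak_mean_count=120.0)
        expr = synthetic.sample_counts(cells, [spec], params, seed=32)
        a, b = synthetic.thin_two_channels(expr, p=0.5, seed=33)
        r = channel_concordance(a.counts["Kr"], b.counts["Kr"])
        assert r > 0.9
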