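import warnings

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.genmod.cov_struct import Independence
from statsmodels.genmod.generalized_estimating_equations import GEE
import pandas as pd

from riverkill import (
    InsufficientDataError,
    RiverFrame,
    ShoreTransect,
    extrapolate_total,
    fit_abundance_smooth,
    idw_surface,
    predict_sections,
    rate_of_change,
)
from riverkill.shore import estimate_shore_total


def make_transects(kms, counts, taxon="mussel", sites=None):
    sites = sites or [f"S{i:03d}" for i in range(len(kms))]
    return [
        ShoreTransect(site_id=s, river_km=float(k), bank="left", counts={taxon: int(c)})
        for s, k, c in zip(sites, kms, counts)
    ]


class TestAbundanceSmooth:
    def test_constant_counts_give_flat_fit(self):
        kms = np.linspace(0, 100, 40)
        model = fit_abundance_smooth(make_transects(kms, [7] * 40), "mussel")
        preds = model.predict(np.linspace(0, 100, 50))
        assert np.max(np.abs(preds - 7.0)) < 0.1

    def test_recovers_known_smooth_trend(self):
        rng = np.random.default_rng(11)
        kms = np.sort(rng.uniform(0, 100, 200))
        truth = np.exp(2.0 + np.sin(kms / 15.0))
        counts = rng.poisson(truth)
        model = fit_abundance_smooth(make_transects(kms, counts), "mussel")
        interior = (kms > np.quantile(kms, 0.05)) & (kms < np.quantile(kms, 0.95))
        rel = np.abs(model.predict(kms[interior]) - truth[interior]) / truth[interior]
        assert np.max(rel) < 0.15

    def test_all_zero_counts_warns_and_returns_flat_zero(self):
        kms = np.linspace(0, 50, 30)
        with pytest.warns(UserWarning, match="zero"):
            model = fit_abundance_smooth(make_transects(kms, [0] * 30), "mussel")
        assert model.all_zero
        assert np.all(model.predict([0.0, 25.0, 50.0]) == 0.0)

    def test_too_few_transects_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_abundance_smooth(make_transects([0, 10, 20], [1, 2, 3]), "mussel")

    def test_degenerate_km_spread_rejected(self):
        kms = [0.0] * 10 + [5.0] * 10
        with pytest.raises(InsufficientDataError):
            fit_abundance_smooth(
                make_transects(kms, range(20)), "mussel", basis_dim=5
            )


class TestRateOfChange:
    def _sectioned(self, counts_per_section, per_section=10, rng_seed=3):
        rng = np.random.default_rng(rng_seed)
        transects = []
        for sec, level in enumerate(counts_per_section):
            for j in range(per_section):
                transects.append(
                    ShoreTransect(
                        site_id=f"site{sec}_{j % 3}",
                        river_km=sec * 10.0 + rng.uniform(0, 10),
                        bank="left",
                        counts={"mussel": int(level)},
                    )
                )
        return transects

    def test_flat_counts_give_null_slope(self):
        res = rate_of_change(self._sectioned([5, 5, 5, 5]), "mussel", 10.0)
        assert abs(res.slope_per_section) < res.robust_se + 1e-9

    def test_geometric_growth_recovers_log_two(self):
        res = rate_of_change(
            self._sectioned([2, 4, 8, 16], per_section=30), "mussel", 10.0
        )
        assert res.slope_per_section == pytest.approx(np.log(2.0), rel=0.05)

    def test_matches_independence_working_correlation_when_uncorrelated(self):
        rng = np.random.default_rng(4)
        kms = rng.uniform(0, 60, 120)
        section = np.floor((kms - kms.min()) / 10).astype(int)
        counts = rng.poisson(np.exp(2.0 - 0.1 * section))
        sites = [f"c{i % 10}" for i in range(120)]
        transects = make_transects(kms, counts, sites=sites)
        res = rate_of_change(transects, "mussel", 10.0)
        df = pd.DataFrame({"y": counts, "section": section, "site": sites})
        indep = GEE.from_formula(
            "y ~ section", groups="site", data=df,
            family=sm.families.Poisson(), cov_struct=Independence(),
        ).fit()
        assert res.slope_per_section == pytest.approx(
            float(indep.params["section"]), rel=0.01
        )

    def test_too_few_sections_rejected(self):
        with pytest.raises(InsufficientDataError):
            rate_of_change(self._sectioned([5, 5]), "mussel", 10.0)


class TestPredictSections:
    def test_constant_fit_predicts_identically(self):
        kms = np.linspace(0, 100, 40)
        model = fit_abundance_smooth(make_transects(kms, [7] * 40), "mussel")
        preds = predict_sections(model, [10.0, 50.0, 90.0])
        assert np.allclose(preds, preds[0], atol=0.05)

    def test_in_sample_predictions_match_fitted_values(self):
        rng = np.random.default_rng(9)
        kms = np.sort(rng.uniform(0, 100, 60))
        counts = rng.poisson(np.exp(1.5 + 0.01 * kms))
        model = fit_abundance_smooth(make_transects(kms, counts), "mussel")
        assert np.allclose(
            model.predict(kms), np.asarray(model._result.fittedvalues), rtol=1e-6
        )

    def test_out_of_range_midpoint_warns_but_predicts(self):
        kms = np.linspace(10, 90, 40)
        model = fit_abundance_smooth(make_transects(kms, [7] * 40), "mussel")
        with pytest.warns(UserWarning, match="outside"):
            preds = predict_sections(model, [0.0, 50.0, 100.0])
        assert preds.shape == (3,)
        assert np.all(preds > 0)


class TestExtrapolateTotal:
    @pytest.mark.parametrize(
        "mean, length_km, banks, expected",
        [
            (3.0, 109.0, 2, 65_400.0),
            (1.0, 0.01, 1, 1.0),  # river exactly one transect long
            (0.0, 500.0, 2, 0.0),
        ],
    )
    def test_two_bank_arithmetic(self, mean, length_km, banks, expected):
        assert extrapolate_total(mean, length_km, 10.0, banks) == pytest.approx(
            expected
        )

    def test_linear_in_mean_and_length(self):
        base = extrapolate_total(3.0, 100.0)
        assert extrapolate_total(6.0, 100.0) == pytest.approx(2 * base)
        assert extrapolate_total(3.0, 200.0) == pytest.approx(2 * base)

    def test_transect_length_rescaling_leaves_total_invariant(self):
        # halving the transect length halves the per-transect mean
        assert extrapolate_total(3.0, 100.0, 10.0) == pytest.approx(
            extrapolate_total(1.5, 100.0, 5.0)
        )

    def test_invalid_transect_length_rejected(self):
        with pytest.raises(ValueError):
            extrapolate_total(3.0, 100.0, 0.0)


class TestIDWSurface:
    def test_single_point_gives_constant_surface(self):
        surf = idw_surface([(0.0, 0.0, 100.0)], [0, 1, 2], [0, 1])
        assert np.allclose(surf.log10_values, 2.0)
        assert np.allclose(surf.values, 100.0)

    def test_symmetric_midpoint_averages_log_values(self):
        for power in (0.5, 1.0, 2.0, 4.0):
            surf = idw_surface(
                [(-1.0, 0.0, 10.0), (1.0, 0.0, 1000.0)], [0.0], [0.0], power=power
            )
            assert surf.log10_values[0, 0] == pytest.approx((1.0 + 3.0) / 2)

    def test_exact_at_data_points(self):
        surf = idw_surface(
            [(0.0, 0.0, 25.0), (2.0, 2.0, 400.0)], [0.0, 1.0, 2.0], [0.0, 2.0]
        )
        assert surf.log10_values[0, 0] == pytest.approx(np.log10(25.0))
        assert surf.log10_values[1, 2] == pytest.approx(np.log10(400.0))

    def test_surface_bounded_by_input_log_range(self):
        rng = np.random.default_rng(2)
        pts = [(x, y, v) for x, y, v in zip(
            rng.uniform(0, 10, 20), rng.uniform(0, 10, 20), rng.uniform(0.1, 100, 20)
        )]
        logs = np.log10([v for _, _, v in pts])
        surf = idw_surface(pts, np.linspace(0, 10, 15), np.linspace(0, 10, 15))
        assert surf.log10_values.min() >= logs.min() - 1e-9
        assert surf.log10_values.max() <= logs.max() + 1e-9

    def test_non_positive_values_excluded_before_log(self):
        surf = idw_surface(
            [(0.0, 0.0, 0.0), (1.0, 0.0, 100.0)], [0.0, 1.0], [0.0]
        )
        assert np.allclose(surf.log10_values, 2.0)

    def test_all_non_positive_rejected(self):
        with pytest.raises(InsufficientDataError):
            idw_surface([(0.0, 0.0, 0.0)], [0.0], [0.0])


class TestEstimateShoreTotal:
    def test_flat_deposition_recovered(self):
        rng = np.random.default_rng(17)
        frame = RiverFrame(0.0, 100.0)
        # 4 carcasses per 10-m transect on each bank -> 2 * 10000 * 4 = 80k
        kms = rng.uniform(0, 100, 60)
        counts = rng.poisson(4.0, 60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            total, (lo, hi), _ = estimate_shore_total(
                make_transects(kms, counts), "mussel", frame, seed=0
            )
        assert total == pytest.approx(80_000.0, rel=0.15)
        assert lo < total < hi
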