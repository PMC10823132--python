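import numpy as np
import pytest

from riverkill import (
    InsufficientDataError,
    LengthWeightCoeff,
    ScenarioConfig,
    UnknownTaxonError,
    VertebrateRecord,
    extrapolate_vertebrates,
    habitat_effect,
    mean_individual_mass,
    simulate_vertebrates,
    transect_biomass,
)
from riverkill.shore import extrapolate_total


def record(taxon, count, lengths=(), transect="t1", km=0.0, habitat="sandy"):
    return VertebrateRecord(
        transect_id=transect, river_km=km, habitat=habitat,
        taxon=taxon, count=count, lengths=tuple(lengths),
    )


class TestMeanIndividualMass:
    def test_cube_law_unit_case(self):
        c = LengthWeightCoeff("fish", a=0.01, b=3.0)
        assert mean_individual_mass([10.0], c) == pytest.approx(10.0)

    def test_mean_of_masses_not_mass_of_mean(self):
        c = LengthWeightCoeff("fish", a=0.01, b=3.0)
        # mean(10g, 80g) = 45g, whereas a*(15cm)^3 would be 33.75g
        assert mean_individual_mass([10.0, 20.0], c) == pytest.approx(45.0)

    def test_linear_degenerate_equals_mean_length(self):
        with pytest.warns(UserWarning, match="outside"):
            c = LengthWeightCoeff("eel", a=1.0, b=1.0)
        assert mean_individual_mass([3.0, 5.0, 7.0], c) == pytest.approx(5.0)

    def test_monotone_in_every_length(self):
        c = LengthWeightCoeff("fish", a=0.01, b=3.1)
        base = mean_individual_mass([10.0, 12.0, 14.0], c)
        assert mean_individual_mass([10.0, 12.0, 15.0], c) > base

    def test_empty_lengths_rejected(self):
        with pytest.raises(InsufficientDataError):
            mean_individual_mass([], LengthWeightCoeff("fish", 0.01, 3.0))


class TestTransectBiomass:
    COEFFS = {
        "ruffe": LengthWeightCoeff("ruffe", 0.012, 3.05),
        "bream": LengthWeightCoeff("bream", 0.009, 3.10),
    }

    def test_simple_product(self):
        coeffs = {"fish": LengthWeightCoeff("fish", 0.5, 3.0)}
        recs = [record("fish", 100, lengths=[10.0])]  # 0.5*1000 = 500 g each
        assert transect_biomass(recs, coeffs) == {"fish": pytest.approx(50.0)}

    def test_zero_counts(self):
        recs = [record("ruffe", 0)]
        biomass = transect_biomass(
            recs, self.COEFFS, fallback_mean_mass_g={"ruffe": 20.0}
        )
        assert biomass["ruffe"] == 0.0

    def test_matches_flat_per_record_sum_oracle(self):
        rng = np.random.default_rng(8)
        recs = []
        for i in range(12):
            for taxon in ("ruffe", "bream"):
                n = int(rng.integers(0, 15))
                lengths = rng.uniform(5, 30, size=min(n, 5))
                recs.append(record(taxon, n, lengths, transect=f"t{i}"))
        biomass = transect_biomass(recs, self.COEFFS)
        # oracle: pooled per-taxon mean mass applied record by record
        for taxon in ("ruffe", "bream"):
            pooled = np.concatenate(
                [r.lengths for r in recs if r.taxon == taxon and r.lengths]
            )
            c = self.COEFFS[taxon]
            mean_mass = np.mean(c.a * pooled ** c.b)
            expected = sum(
                r.count * mean_mass for r in recs if r.taxon == taxon
            ) / 1000.0
            assert biomass[taxon] == pytest.approx(expected)

    def test_additive_over_disjoint_subsets(self):
        recs = [
            record("ruffe", 5, [10.0, 12.0], transect="a"),
            record("ruffe", 7, [11.0], transect="b"),
        ]
        whole = transect_biomass(recs, self.COEFFS)["ruffe"]
        # the pooled mean mass is shared, so per-subset totals with that
        # mass must sum to the whole
        pooled = np.array([10.0, 12.0, 11.0])
        c = self.COEFFS["ruffe"]
        mean_mass = np.mean(c.a * pooled ** c.b)
        assert whole == pytest.approx((5 + 7) * mean_mass / 1000.0)

    def test_missing_coefficient_rejected(self):
        with pytest.raises(UnknownTaxonError):
            transect_biomass([record("pike", 3, [40.0])], self.COEFFS)

    def test_no_lengths_anywhere_needs_fallback(self):
        recs = [record("ruffe", 5)]
        with pytest.raises(InsufficientDataError):
            transect_biomass(recs, self.COEFFS)
        biomass = transect_biomass(
            recs, self.COEFFS, fallback_mean_mass_g={"ruffe": 20.0}
        )
        assert biomass["ruffe"] == pytest.approx(0.1)


class TestExtrapolation:
    def test_full_affected_reach(self):
        assert extrapolate_vertebrates(1.0, 561.0) == pytest.approx(112_200.0)

    def test_zero(self):
        assert extrapolate_vertebrates(0.0, 561.0) == 0.0

    def test_delegates_to_shore_extrapolation(self):
        for mean, L, banks in [(2.5, 150.0, 2), (0.7, 561.0, 1)]:
            assert extrapolate_vertebrates(mean, L, n_banks=banks) == (
                extrapolate_total(mean, L, n_banks=banks)
            )


def kruskal_brute_force(groups):
    """Independent rank-based oracle with tie correction."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank for ties
        i = j
    offsets = np.cumsum([0] + [len(g) for g in groups])
    h = 0.0
    for k, g in enumerate(groups):
        r_mean = ranks[offsets[k]:offsets[k + 1]].mean()
        h += len(g) * (r_mean - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    ties = 0.0
    for v in np.unique(sorted_vals):
        t = np.sum(sorted_vals == v)
        ties += t**3 - t
    return h / (1.0 - ties / (n**3 - n))


class TestHabitatEffect:
    def _records(self, multipliers, seed=0, n=40):
        cfg = ScenarioConfig(
            seed=seed, habitat_multipliers=tuple(multipliers.items())
        )
        return simulate_vertebrates(cfg, n_transects=n)

    def test_identical_habitats_give_null_kruskal(self):
        recs = [
            record("ruffe", 5, transect=f"t{i}", habitat=h)
            for i, h in enumerate(
                ["stony"] * 5 + ["gravel"] * 5 + ["reed"] * 5
            )
        ]
        report = habitat_effect(recs, "ruffe")
        assert report.kruskal_statistic == pytest.approx(0.0, abs=1e-9)
        assert report.kruskal_p > 0.99

    def test_strong_habitat_effect_detected(self):
        hits = 0
        for seed in range(20):
            recs = self._records(
                {"stony": 10.0, "gravel": 1.0, "reed": 1.0, "sandy": 1.0},
                seed=seed,
                n=40,
            )
            report = habitat_effect(recs, "ruffe")
            hits += report.kruskal_p < 0.05
        assert hits >= 19  # > 95% power at a 10x effect

    def test_kruskal_matches_brute_force_with_ties(self):
        from scipy import stats

        groups = [[1, 2, 2, 5], [2, 3, 3], [5, 5, 1]]
        expected = kruskal_brute_force([np.array(g, float) for g in groups])
        assert stats.kruskal(*groups).statistic == pytest.approx(expected)
        recs = []
        i = 0
        for hab, vals in zip(("stony", "gravel", "reed"), groups):
            for v in vals:
                recs.append(record("ruffe", v, transect=f"t{i}", habitat=hab))
                i += 1
        report = habitat_effect(recs, "ruffe")
        assert report.kruskal_statistic == pytest.approx(expected)

    def test_single_habitat_rejected(self):
        recs = [record("ruffe", 3, transect=f"t{i}") for i in range(6)]
        with pytest.raises(InsufficientDataError):
            habitat_effect(recs, "ruffe")
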