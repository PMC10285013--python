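import numpy as np
import pytest

from nirhsi.survey import (
    SizeDistribution,
    TowRecord,
    bin_size_distribution,
    concentration_range,
    default_size_bins,
    fit_power_law,
    fit_power_law_mle,
    load_raman_crosscheck,
    load_tow_table,
    polymer_proportions,
    raman_summary,
    round_half_up,
    tow_concentration,
)
from nirhsi.synth import sample_power_law


def exact_bin_masses(alpha, edges, lo=None, hi=None):
    """Closed-form bin integrals of l^-alpha: the analytic oracle."""
    lo = edges[0] if lo is None else lo
    hi = edges[-1] if hi is None else hi
    a1 = 1.0 - alpha
    starts = np.clip(edges[:-1], lo, hi)
    stops = np.clip(edges[1:], lo, hi)
    return (starts**a1 - stops**a1) / (alpha - 1.0)


class TestConcentrations:
    @pytest.mark.parametrize(
        "total,volume,expected",
        [(283, 196, 1.444), (41, 270, 0.152), (194, 27, 7.185), (293, 81, 3.617), (13, 206, 0.063)],
    )
    def test_count_over_volume_matches_printed_cells(self, total, volume, expected):
        rec = TowRecord("t", volume_m3=volume, total=total)
        assert round_half_up(tow_concentration(rec), 3) == expected

    def test_zero_particles_is_zero_concentration(self):
        assert tow_concentration(TowRecord("t", volume_m3=100, total=0)) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            TowRecord("t", volume_m3=0, total=5)

    def test_packaged_table_reproduces_every_printed_cell(self):
        df, records = load_tow_table()
        assert len(records) == 27
        for rec, printed in zip(records, df["mp_per_m3_printed"]):
            assert round_half_up(tow_concentration(rec), 3) == pytest.approx(printed)

    def test_range_excluding_clogged_tows(self):
        _, records = load_tow_table()
        lo, hi = concentration_range(records, exclude_clogged=True)
        assert round_half_up(lo, 3) == 0.063
        assert float(f"{hi:.2g}") == 3.6

    def test_including_clogged_tows_raises_the_maximum(self):
        _, records = load_tow_table()
        _, hi_excl = concentration_range(records, exclude_clogged=True)
        _, hi_incl = concentration_range(records, exclude_clogged=False)
        assert hi_incl > hi_excl
        assert round_half_up(hi_incl, 3) == 7.185

    def test_single_record_range_is_degenerate(self):
        rec = TowRecord("t", volume_m3=10, total=5)
        assert concentration_range([rec]) == (0.5, 0.5)

    def test_all_excluded_raises(self):
        rec = TowRecord("t", volume_m3=10, total=5, clogged=True)
        with pytest.raises(ValueError):
            concentration_range([rec])


class TestProportions:
    def test_simple_counts(self):
        recs = [TowRecord("t", 10, 4, counts={"PE": 3, "PP": 1})]
        assert polymer_proportions(recs) == {"PE": 0.75, "PP": 0.25}

    def test_fractions_sum_to_one_for_random_tables(self):
        rng = np.random.default_rng(0)
        recs = [
            TowRecord(
                f"t{i}", 50, 0,
                counts={c: int(rng.integers(0, 40)) for c in ("PE", "PP", "PS", "other")},
            )
            for i in range(6)
        ]
        assert sum(polymer_proportions(recs).values()) == pytest.approx(1.0)

    def test_single_class_table(self):
        recs = [TowRecord("t", 10, 7, counts={"PE": 7})]
        assert polymer_proportions(recs) == {"PE": 1.0}

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            polymer_proportions([TowRecord("t", 10, 0, counts={"PE": 0})])


class TestSizeBinning:
    def test_default_bins_span_mesh_to_forty_mm(self):
        edges = default_size_bins()
        assert len(edges) == 10
        assert edges[0] == pytest.approx(0.3)
        assert edges[-1] == pytest.approx(40.0)
        # log spacing: constant ratio
        ratios = edges[1:] / edges[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_single_length_lands_in_its_bin(self):
        dist = bin_size_distribution([1.0])
        edges = dist.bin_edges_mm
        target = np.searchsorted(edges, 1.0, side="right") - 1
        assert dist.counts.sum() == 1
        assert dist.counts[target] == 1

    def test_total_count_equals_in_range_lengths(self):
        rng = np.random.default_rng(1)
        lengths = rng.uniform(0.05, 50, 500)
        dist = bin_size_distribution(lengths)
        in_range = np.sum((lengths >= 0.3) & (lengths < 40.0))
        assert dist.counts.sum() == in_range
        assert dist.counts.sum() + dist.n_below + dist.n_above == 500

    def test_uniform_lengths_give_flat_normalized_abundance(self):
        rng = np.random.default_rng(2)
        n = 10_000
        lengths = rng.uniform(0.3, 40.0, n)
        dist = bin_size_distribution(lengths)
        density = n / (40.0 - 0.3)
        for count, width in zip(dist.counts, dist.widths):
            sd = np.sqrt(density * width)  # Poisson-like Monte-Carlo noise
            assert abs(count - density * width) < 3 * sd
        assert np.allclose(dist.normalized * dist.widths, dist.counts)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_size_distribution([1.0], edges=np.array([1.0, 0.5, 2.0]))


class TestPowerLawFit:
    def test_exact_bin_masses_recover_alpha_three(self):
        # Fill bins with analytic integrals of l^-3 (no sampling at all).
        edges = default_size_bins()
        masses = exact_bin_masses(3.0, edges)
        dist = SizeDistribution(edges, masses * 1e6)
        fit = fit_power_law(dist, l_min_fit=2.0)
        assert fit.alpha == pytest.approx(3.0, abs=0.02)

    @pytest.mark.parametrize("alpha", [3.41, 2.80])
    def test_sampled_lengths_recover_generator_exponent(self, alpha):
        lengths = sample_power_law(alpha, 2.0, 40.0, 20_000, rng=0)
        fit = fit_power_law(bin_size_distribution(lengths))
        assert abs(fit.alpha - alpha) <= 2 * fit.alpha_se

    def test_count_rescaling_moves_only_the_intercept(self):
        lengths = sample_power_law(3.0, 2.0, 40.0, 5_000, rng=3)
        dist = bin_size_distribution(lengths)
        scaled = SizeDistribution(dist.bin_edges_mm, dist.counts * 50.0)
        f1, f2 = fit_power_law(dist), fit_power_law(scaled)
        assert f2.alpha == pytest.approx(f1.alpha)
        assert f2.intercept != pytest.approx(f1.intercept)

    def test_all_mass_in_one_bin_is_insufficient(self):
        dist = bin_size_distribution([5.0, 5.1, 5.2])
        with pytest.raises(ValueError):
            fit_power_law(dist)

    def test_parameter_recovery_band_across_seeds(self):
        # Mean recovered alpha within 0.05 and ~2 se coverage >= 80%.
        for alpha in (2.80, 2.93, 3.41):
            estimates, covered = [], 0
            for seed in range(20):
                lengths = sample_power_law(alpha, 2.0, 40.0, 20_000, rng=seed)
                fit = fit_power_law(bin_size_distribution(lengths))
                estimates.append(fit.alpha)
                covered += abs(fit.alpha - alpha) <= 2 * fit.alpha_se
            assert abs(np.mean(estimates) - alpha) < 0.05
            assert covered >= 16

    def test_mle_cross_check_agrees_with_binned_ols(self):
        lengths = sample_power_law(3.2, 2.0, 40.0, 20_000, rng=4)
        ols = fit_power_law(bin_size_distribution(lengths)).alpha
        mle = fit_power_law_mle(lengths, 2.0, 40.0)
        assert ols == pytest.approx(mle, abs=0.15)

    def test_summary_mentions_alpha_and_range(self):
        lengths = sample_power_law(3.0, 2.0, 40.0, 5_000, rng=5)
        text = fit_power_law(bin_size_distribution(lengths)).summary()
        assert "alpha" in text and "mm" in text


class TestRamanArithmetic:
    def test_breakdown_totals_350(self):
        counts = load_raman_crosscheck()
        assert sum(counts.values()) == 350
        assert counts["PE"] == 250 and counts["PP"] == 31

    def test_not_evaluable_fraction_rounds_to_fifteen_percent(self):
        summary = raman_summary(load_raman_crosscheck())
        assert round(summary["pct_not_evaluable"]) == 15
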