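"""Two-neurite competition: outcomes, pooled/conditional fits, patterns, map."""

import math

import numpy as np
import pytest
from scipy import stats

from axonpolar import (
    FitError,
    SigmoidFit,
    SyntheticConfig,
    classify_pair_outcome,
    fit_conditional,
    fit_pair_pooled,
    fit_sigmoid,
    generate_pair_dataset,
    lc_shift,
    pair_bootstrap_se,
    pair_outcome_counts,
    probability_map,
    sigmoid_probability,
    stepwise_pattern,
)
from axonpolar.synthetic import IntensityModel


class TestPairOutcome:
    @pytest.mark.parametrize(
        "i1, i2, expected",
        [
            (0.7, 0.9, "none"),  # short-short: neither differentiates
            (2.1, 0.8, "single"),  # long-short: only the longer becomes an axon
            (1.9, 1.4, "dual"),  # long-long: both differentiate
        ],
    )
    def test_outcome_from_indices(self, i1, i2, expected):
        assert classify_pair_outcome(i1, i2) == expected

    def test_missing_index_rejected(self):
        with pytest.raises(ValueError):
            classify_pair_outcome(float("nan"), 1.2)

    def test_counts_conserve_pairs(self):
        df = generate_pair_dataset(SyntheticConfig(n_pairs=50, seed=2), "simultaneous")
        counts = pair_outcome_counts(df)
        assert sum(counts.values()) == 50

    def test_dual_fraction_above_definitive_length(self):
        """With no competition shift, pairs whose two neurites both exceed
        the definitive length are dual axons at close to p_definitive²."""
        cfg = SyntheticConfig(
            n_pairs=1000,
            seed=3,
            competition_shift=0.0,
            conditional_shift=0.0,
            intensity=IntensityModel(noise_sd=0.0),
        )
        df = generate_pair_dataset(cfg, "simultaneous")
        lt = cfg.true_Lt
        wide = df.pivot_table(
            index="pair_id", values=["length_um", "is_axon"], aggfunc=list
        )
        n_sel = n_dual = 0
        for _, row in wide.iterrows():
            if min(row["length_um"]) > lt:
                n_sel += 1
                n_dual += int(sum(row["is_axon"]) == 2)
        p0 = cfg.p_definitive**2
        test = stats.binomtest(n_dual, n_sel, p0)
        assert test.pvalue > 0.01


class TestPooledFit:
    def test_recovers_competition_truth(self):
        cfg = SyntheticConfig(n_pairs=1000, seed=4, conditional_shift=0.0)
        df = generate_pair_dataset(cfg, "simultaneous")
        fit = fit_pair_pooled(df)
        assert fit.Lc == pytest.approx(43.3 + 9.9, abs=2.5)

    def test_identical_to_flattened_fit(self):
        df = generate_pair_dataset(
            SyntheticConfig(n_pairs=100, seed=5, competition_shift=0.0), "simultaneous"
        )
        pooled = fit_pair_pooled(df)
        kept = df[~df["excluded"]]
        flat = fit_sigmoid(
            kept["length_um"].to_numpy(float), kept["is_axon"].to_numpy(float)
        )
        assert pooled.Lc == flat.Lc and pooled.sigma == flat.sigma

    def test_single_pair_rejected(self):
        df = generate_pair_dataset(SyntheticConfig(n_pairs=2, seed=6), "simultaneous")
        with pytest.raises(FitError):
            fit_pair_pooled(df[df.pair_id == "p000"])

    def test_pair_bootstrap_se_positive(self):
        df = generate_pair_dataset(SyntheticConfig(n_pairs=60, seed=7), "simultaneous")
        se = pair_bootstrap_se(df, n_boot=50, seed=1)
        assert se["Lc_se"] > 0 and se["n_successful"] > 10


class TestConditionalFit:
    def test_recovers_conditional_truth(self):
        cfg = SyntheticConfig(n_pairs=1500, seed=8)
        df = generate_pair_dataset(cfg, "simultaneous")
        fit = fit_conditional(df, Lt_ref=cfg.true_Lt)
        assert fit.Lc == pytest.approx(62.0, abs=3)

    def test_condition_never_satisfied_rejected(self):
        df = generate_pair_dataset(SyntheticConfig(n_pairs=20, seed=9), "simultaneous")
        with pytest.raises(FitError, match="partner"):
            fit_conditional(df, Lt_ref=1e6)

    def test_zero_conditional_shift_matches_pooled(self):
        cfg = SyntheticConfig(n_pairs=1500, seed=10, conditional_shift=0.0)
        df = generate_pair_dataset(cfg, "simultaneous")
        pooled = fit_pair_pooled(df)
        cond = fit_conditional(df, Lt_ref=cfg.true_Lt)
        se = math.sqrt(
            pooled.covariance[0, 0] + cond.covariance[0, 0]
        )
        assert abs(cond.Lc - pooled.Lc) < 4 * se + 1.0


class TestLcShift:
    def test_identical_fits_give_zero(self):
        fit = SigmoidFit(Lc=50.0, sigma=10.0)
        assert lc_shift(fit, fit)[0] == 0.0

    def test_printed_single_to_pair_shift(self):
        a = SigmoidFit(Lc=43.3, sigma=13.7)
        b = SigmoidFit(Lc=53.2, sigma=15.2)
        delta, _ = lc_shift(a, b)
        assert delta == pytest.approx(9.9)

    def test_shift_tracks_generator_increment(self):
        """Shifts between the short-partner and long-partner subsets center
        on the generator's conditional increment across replicates.

        The pooled fit mixes both shift levels, so the clean oracle splits
        neurites by whether the partner exceeds the definitive length: the
        two subsets have generating critical lengths exactly one
        conditional increment apart.
        """
        from axonpolar import pair_table

        deltas = []
        rng = np.random.default_rng(11)
        for _ in range(100):
            cfg = SyntheticConfig(n_pairs=400, seed=int(rng.integers(2**31)))
            df = generate_pair_dataset(cfg, "simultaneous")
            wide = pair_table(df)
            short_partner_L, short_partner_y = [], []
            for _, row in wide.iterrows():
                if row["length_2"] <= cfg.true_Lt:
                    short_partner_L.append(row["length_1"])
                    short_partner_y.append(row["is_axon_1"])
                if row["length_1"] <= cfg.true_Lt:
                    short_partner_L.append(row["length_2"])
                    short_partner_y.append(row["is_axon_2"])
            try:
                base = fit_sigmoid(
                    np.asarray(short_partner_L), np.asarray(short_partner_y)
                )
                cond = fit_conditional(df, Lt_ref=cfg.true_Lt)
            except FitError:
                continue
            deltas.append(lc_shift(base, cond)[0])
        mean_delta = np.mean(deltas)
        se_mean = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(mean_delta - 8.8) < 2 * se_mean + 0.2

    def test_unconverged_input_rejected(self):
        good = SigmoidFit(Lc=50.0, sigma=10.0)
        bad = SigmoidFit(Lc=50.0, sigma=10.0)
        bad.converged = False
        with pytest.raises(FitError):
            lc_shift(good, bad)


class TestStepwisePattern:
    @pytest.mark.parametrize(
        "l1, l2, a1, a2, expected",
        [
            (16.5, 316.0, 0, 1, "second_wins"),  # retracted first neurite
            (154.8, 63.7, 1, 0, "first_wins"),
            (165.0, 111.4, 1, 1, "dual"),
            (20.0, 30.0, 0, 0, "none"),
        ],
    )
    def test_pattern_assignment(self, l1, l2, a1, a2, expected):
        assert stepwise_pattern(l1, l2, a1, a2).pattern == expected

    def test_longest_is_axon_flag(self):
        assert stepwise_pattern(16.5, 316.0, 0, 1).longest_is_axon
        assert stepwise_pattern(154.8, 63.7, 1, 0).longest_is_axon
        assert not stepwise_pattern(100.0, 50.0, 0, 1).longest_is_axon

    def test_single_axon_above_definitive_length_is_longest(self):
        """When exactly one neurite clears the (competition-shifted)
        near-certainty length and the other stays far below threshold, the
        axon is the finally-longest neurite."""
        from axonpolar import pair_table

        cfg = SyntheticConfig(n_pairs=800, seed=12)
        df = generate_pair_dataset(cfg, "stepwise")
        lc_max = cfg.true_Lc + cfg.competition_shift + cfg.conditional_shift
        lt_eff = lc_max + cfg.true_sigma * math.atanh(2 * cfg.p_definitive - 1)
        lo_eff = cfg.true_Lc + cfg.competition_shift - 2 * cfg.true_sigma
        hits = total = 0
        for _, row in pair_table(df).iterrows():
            lengths = (row["length_1"], row["length_2"])
            if max(lengths) > lt_eff and min(lengths) < lo_eff:
                total += 1
                pat = stepwise_pattern(
                    row["length_1"], row["length_2"], row["is_axon_1"], row["is_axon_2"]
                )
                hits += pat.pattern in ("first_wins", "second_wins") and pat.longest_is_axon
        assert total > 30
        assert hits / total > 0.9


class TestProbabilityMap:
    def test_midpoint_cell(self):
        fit = SigmoidFit(Lc=43.3, sigma=13.7)
        pmap = probability_map(fit, [43.3], [43.3])
        assert pmap.p_x[0] == pytest.approx(0.5)
        assert pmap.p_y[0] == pytest.approx(0.5)

    def test_magenta_region_both_near_one(self):
        fit = SigmoidFit(Lc=43.3, sigma=13.7)
        pmap = probability_map(fit, [180.0], [150.0])
        assert pmap.p_x[0] > 0.999 and pmap.p_y[0] > 0.999
        rgb = pmap.to_rgb()
        assert rgb[0, 0, 0] == 255 and rgb[0, 0, 2] == 255

    def test_cells_equal_direct_sigmoid_evaluation(self):
        fit = SigmoidFit(Lc=50.0, sigma=12.0)
        x = np.linspace(0, 200, 11)
        y = np.linspace(0, 200, 7)
        pmap = probability_map(fit, x, y)
        grid = pmap.grid()
        np.testing.assert_allclose(
            grid["p_x"], sigmoid_probability(grid["x_um"].to_numpy(), 50.0, 12.0)
        )
        np.testing.assert_allclose(
            grid["p_y"], sigmoid_probability(grid["y_um"].to_numpy(), 50.0, 12.0)
        )
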