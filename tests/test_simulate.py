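"""Selection simulator: distributions, conservation laws, reproducibility."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dmscan
from dmscan.simulate import (
    SimulationConfig,
    assign_effect_noise,
    assign_jackpot_noise,
    binding_round,
    draw_true_effects,
    growth_round,
    initial_population,
    predicted_scores,
    sequence_population,
    simulate_dataset,
)


def rng(seed=0):
    return np.random.default_rng(seed)


class TestEffectDistribution:
    def test_binding_mean_places_wt_at_75th_percentile(self):
        config = SimulationConfig(assay="binding")
        assert config.effect_mean == pytest.approx(0.5 - 0.674490 * 0.1, abs=1e-6)

    def test_growth_mean(self):
        config = SimulationConfig(assay="growth")
        assert config.effect_mean == pytest.approx(1.0 - 0.674490 * 0.1, abs=1e-6)

    def test_wild_type_exact_and_bounds_respected(self):
        config = SimulationConfig(assay="binding", n_variants=5000)
        effects = draw_true_effects(config, rng())
        assert effects[0] == 0.5
        assert (effects[1:] > 0.05).all() and (effects[1:] < 0.99).all()

    def test_quantile_recovery_on_large_sample(self):
        """The wild-type effect sits at the 75th percentile of the draws."""
        config = SimulationConfig(assay="binding", n_variants=1_000_001)
        effects = draw_true_effects(config, rng(1))
        q75 = np.quantile(effects[1:], 0.75)
        # sample-quantile MC standard error is ~1.4e-4 at this n; the bounds
        # clip <0.01% of the mass, so any truncation bias is far smaller
        assert q75 == pytest.approx(config.wt_effect, abs=5e-4)

    def test_sd_zero_limit(self):
        config = SimulationConfig(assay="binding", effect_sd=1e-12)
        effects = draw_true_effects(config, rng())
        assert np.allclose(effects[1:], config.effect_mean)


class TestInitialPopulation:
    def test_wild_type_one_percent(self):
        config = SimulationConfig()
        pop = initial_population(config, rng())
        assert pop[0] == 100_000

    def test_total_population_after_rescaling(self):
        config = SimulationConfig()
        pop = initial_population(config, rng())
        # exact up to per-variant rounding
        assert abs(pop.sum() - config.population_size) < config.n_variants

    def test_lognormal_location_gives_stated_mean(self):
        # mean of LogNormal(mu, sd) is exp(mu + sd^2/2) = 990 by construction
        mu = np.log(990) - 0.4**2 / 2
        assert np.exp(mu + 0.4**2 / 2) == pytest.approx(990)
        draws = rng(3).lognormal(mu, 0.4, size=400_000)
        assert draws.mean() == pytest.approx(990, rel=5e-3)


class TestSelectionRounds:
    def test_binding_survival_mean(self):
        """Monte-Carlo check of E[k] = c' p on a 3-variant toy."""
        config = SimulationConfig(population_size=60_000, n_variants=3)
        c = np.array([10_000, 20_000, 30_000])
        p = np.array([0.9, 0.5, 0.1])
        g = rng(7)
        total = np.zeros(3)
        reps = 400
        for _ in range(reps):
            total += g.binomial(c, p)
        assert np.allclose(total / reps, c * p, rtol=5e-3)

    def test_binding_round_conserves_population(self):
        config = SimulationConfig(population_size=1_000_000, n_variants=100)
        pop = initial_population(config, rng())
        nxt = binding_round(pop, np.full(100, 0.5), config, rng())
        assert nxt.sum() == config.population_size

    def test_neutral_selection_preserves_frequencies(self):
        config = SimulationConfig(population_size=2_000_000, n_variants=50)
        pop = initial_population(config, rng(5))
        nxt = binding_round(pop, np.full(50, 0.5), config, rng(5))
        f0 = pop / pop.sum()
        f1 = nxt / nxt.sum()
        assert np.abs(f1 - f0).max() < 5e-4

    def test_growth_interval_length(self):
        config = SimulationConfig(assay="growth")
        assert config.dt == pytest.approx(2 * np.log(2))

    def test_growth_mean_matches_negative_binomial(self):
        """E[g] = c (1-p)/p with p = e^(-mu dt): Monte-Carlo on one variant."""
        config = SimulationConfig(assay="growth", population_size=10_000, n_variants=2)
        c = np.array([5_000, 5_000])
        mu = np.array([1.0, 1.0])
        p = np.exp(-mu[0] * config.dt)
        expected = c[0] * (1 - p) / p  # = c (e^{mu dt} - 1) = 3 c for delta=2
        assert expected == pytest.approx(3 * c[0])
        g = rng(11)
        draws = [growth_round(c, mu, config, g).sum() for _ in range(5)]
        assert all(d == config.population_size for d in draws)
        raw = g.negative_binomial(c[0], p, size=2000)
        assert raw.mean() == pytest.approx(expected, rel=2e-2)

    def test_extinct_variant_stays_extinct(self):
        config = SimulationConfig(assay="growth", population_size=1000, n_variants=3)
        nxt = growth_round(np.array([0, 500, 500]), np.ones(3), config, rng())
        assert nxt[0] == 0

    def test_total_extinction_is_error(self):
        config = SimulationConfig(population_size=100, n_variants=2)
        with pytest.raises(RuntimeError):
            binding_round(np.array([0, 0]), np.array([0.5, 0.5]), config, rng())


class TestSequencing:
    def test_total_depth(self):
        config = SimulationConfig(n_variants=100, reads_per_variant=200)
        reads = sequence_population(np.full(100, 1000), config, rng())
        assert reads.sum() == 20_000

    def test_single_variant_takes_all_reads(self):
        config = SimulationConfig(n_variants=3, reads_per_variant=10)
        pop = np.array([0, 500, 0])
        reads = sequence_population(pop, config, rng())
        assert reads.tolist() == [0, 30, 0]

    def test_frequencies_converge_with_depth(self):
        config = SimulationConfig(n_variants=4, reads_per_variant=250_000)
        pop = np.array([100, 200, 300, 400])
        reads = sequence_population(pop, config, rng())
        assert np.allclose(reads / reads.sum(), pop / pop.sum(), atol=2e-3)


class TestNoiseAssignment:
    def test_effect_noise_split(self):
        config = SimulationConfig(replicate_effect_noise=True)
        effects = draw_true_effects(config, rng())
        noise = assign_effect_noise(config, effects, rng(1))
        assert len(noise) == 1000  # 10% of 9,999 -> 1000 (rounded)
        counts = noise["replicate"].value_counts()
        assert sorted(counts) == [200] * 5
        assert noise["variant_idx"].is_unique
        assert (noise["variant_idx"] > 0).all()  # wild-type never noisy

    def test_jackpot_split(self):
        config = SimulationConfig(jackpot_noise=True)
        noise = assign_jackpot_noise(config, rng(2))
        assert (noise["direction"] == "amplified").sum() == 500
        assert (noise["direction"] == "depleted").sum() == 500
        assert noise["timepoint"].between(0, 5).all()  # input included

    def test_noise_disabled_empty(self):
        config = SimulationConfig()
        ds = simulate_dataset(
            SimulationConfig(n_variants=50, population_size=50_000, seed=1)
        )
        assert ds.truth.noise.empty


class TestPredictedScores:
    def test_binding_formula(self):
        config = SimulationConfig(assay="binding")
        out = predicted_scores(config, np.array([0.5, 0.25]))
        assert out["predicted_score"][0] == 0.0  # wild-type
        assert out["predicted_score"][1] == pytest.approx(5 * np.log(0.5), abs=1e-9)
        assert out["predicted_score"][1] == pytest.approx(-3.4657, abs=1e-4)

    def test_growth_formula_both_conventions(self):
        config = SimulationConfig(assay="growth")
        out = predicted_scores(config, np.array([1.0, 1.1]))
        assert out["predicted_score"][1] == pytest.approx(1.0)  # 5*2*0.1
        assert out["predicted_slope"][1] == pytest.approx(
            5 * 2 * np.log(2) * 0.1, rel=1e-9
        )


class TestEndToEnd:
    def test_seeded_runs_identical(self):
        config = SimulationConfig(
            n_variants=120, population_size=120_000, replicates=2, seed=42
        )
        a = simulate_dataset(config)
        b = simulate_dataset(config)
        for ta, tb in zip(a.tables, b.tables):
            pd.testing.assert_frame_equal(ta.counts, tb.counts)
        pd.testing.assert_frame_equal(a.truth.effects, b.truth.effects)

    def test_different_seeds_differ(self):
        base = dict(n_variants=120, population_size=120_000, replicates=2)
        a = simulate_dataset(SimulationConfig(seed=1, **base))
        b = simulate_dataset(SimulationConfig(seed=2, **base))
        assert not a.tables[0].counts.equals(b.tables[0].counts)

    def test_read_totals_exact(self, tiny_simulation):
        for table in tiny_simulation.tables:
            assert (
                table.counts.sum(axis=0)
                == tiny_simulation.config.reads_per_timepoint
            ).all()

    def test_neutral_simulation_centered_at_zero(self):
        """With every effect equal to wild-type's, scores center on 0.

        Wild-type sampling noise is shared across all variants within a run,
        so the per-run mean score does not shrink with the number of
        variants; the Monte-Carlo error is instead estimated from the
        between-run spread of mean scores over independent seeds.
        """
        means = []
        for seed in range(6):
            config = SimulationConfig(
                assay="binding",
                n_variants=200,
                population_size=200_000,
                replicates=3,
                effect_sd=1e-9,  # sd -> 0: every effect equals the wild-type's
                seed=seed,
            )
            ds = simulate_dataset(config)
            frames = [dmscan.score_selection(t) for t in ds.tables]
            comb = dmscan.combine_replicates(frames)
            means.append(comb["score"].drop("_wt").dropna().mean())
        means = np.asarray(means)
        mc_se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * mc_se

    def test_scores_track_true_effects(self, tiny_simulation):
        """Scores rise monotonically across true-effect quintiles."""
        frames = [dmscan.score_selection(t) for t in tiny_simulation.tables]
        comb = dmscan.combine_replicates(frames)
        j = comb.join(tiny_simulation.truth.effects).dropna(subset=["score"])
        r2 = stats.pearsonr(j["score"], j["predicted_score"]).statistic ** 2
        assert r2 > 0.9
        bins = pd.qcut(j["effect"], 5)
        means = j.groupby(bins, observed=True)["score"].mean()
        assert means.is_monotonic_increasing

    def test_dataset_write_roundtrip(self, tmp_path, tiny_simulation):
        tiny_simulation.write(tmp_path)
        back = dmscan.VariantCountTable.from_tsv(tmp_path / "rep1_counts.tsv")
        pd.testing.assert_frame_equal(
            back.counts,
            tiny_simulation.tables[0].counts,
            check_names=False,
        )
        truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t", index_col="variant")
        assert len(truth) == tiny_simulation.config.n_variants
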