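"""Simulation of binding and growth selections with known variant effects.

Each simulated library holds 10,000 unique variants (including wild-type).
A variant's true effect is its per-round probability of selection p_v
(binding assays: phage or yeast display panning) or its growth rate mu_v
(growth assays).  Effects are drawn from a normal distribution whose mean
places the wild-type effect (p_wt = 0.5, mu_wt = 1) at the 75th percentile,
with standard deviation 0.1; draws outside the plausible range
(0.05 < p < 0.99, 0.05 < mu < 5) are redrawn.

For each replicate, input population counts are log-normal (underlying
normal sd 0.4, mean count 990) rescaled so the population is 10 million
with wild-type at 1%.  Five rounds of selection follow.  Binding:
survivors k ~ Binomial(c', p_v), then weighted resampling with replacement
back to 10 million.  Growth: the grown population is drawn as
g ~ NegativeBinomial(r = c', p = e^(-mu_v dt)), the offspring count of a
linear birth process over one interval, with mean c' (e^(mu_v dt) - 1);
dt = delta ln2 / mu_wt gives delta wild-type doublings per sampled
timepoint (delta = 2); then the same resampling.  Sequencing draws 200
reads per variant on average (2 million reads per timepoint) multinomially
from the population.

Two noise modes emulate real artifacts: replicate-effect noise re-draws the
true effect of 10% of variants in exactly one replicate each (2% of
variants per replicate over 5 replicates), and jackpot noise multiplies or
divides one (replicate, timepoint) population count by 50 before sequencing
(5% of variants amplified, 5% depleted).

Analytic predicted scores under the regression scoring model:

    binding: beta' = maxT * ln(p_v / p_wt)
    growth:  beta'' = m * delta * (mu_v - mu_wt)

Under exact exponential growth the simulator's natural-log regression
slope is m * delta * ln2 * (mu_v - mu_wt) / mu_wt, proportional to beta'';
both conventions are emitted (columns ``predicted_score`` and, for growth,
``predicted_slope``) since score/prediction agreement is measured by the
scale-invariant r^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .counting import TimepointSchedule, VariantCountTable
from .refseq import WILD_TYPE_LABEL

Z_75 = float(stats.norm.ppf(0.75))  # 0.6744897501960817


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a simulated selection experiment (defaults = study scale)."""

    assay: str = "binding"  # "binding" | "growth"
    n_variants: int = 10_000  # including wild-type
    effect_sd: float = 0.1
    wt_percentile: float = 0.75
    p_wt: float = 0.5
    mu_wt: float = 1.0
    p_bounds: tuple[float, float] = (0.05, 0.99)
    mu_bounds: tuple[float, float] = (0.05, 5.0)
    population_size: int = 10_000_000
    wt_input_frequency: float = 0.01
    input_mean_count: float = 990.0
    input_log_sd: float = 0.4
    rounds: int = 5
    replicates: int = 5
    reads_per_variant: int = 200
    doublings_per_round: float = 2.0  # delta
    replicate_effect_noise: bool = False
    jackpot_noise: bool = False
    jackpot_factor: float = 50.0
    effect_noise_fraction: float = 0.10
    jackpot_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in {"binding", "growth"}:
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.n_variants < 2:
            raise ValueError("need at least wild-type plus one variant")
        lo, hi = self.bounds
        if not lo < self.wt_effect < hi:
            raise ValueError("effect bounds must bracket the wild-type effect")

    @property
    def wt_effect(self) -> float:
        return self.p_wt if self.assay == "binding" else self.mu_wt

    @property
    def bounds(self) -> tuple[float, float]:
        return self.p_bounds if self.assay == "binding" else self.mu_bounds

    @property
    def effect_mean(self) -> float:
        """Mean of the effect distribution placing wild-type at its percentile."""
        z = float(stats.norm.ppf(self.wt_percentile))
        return self.wt_effect - z * self.effect_sd

    @property
    def dt(self) -> float:
        """Growth interval between sampled timepoints (delta wt doublings)."""
        return self.doublings_per_round * np.log(2.0) / self.mu_wt

    @property
    def schedule(self) -> TimepointSchedule:
        return TimepointSchedule(tuple(float(t) for t in range(self.rounds + 1)))

    @property
    def reads_per_timepoint(self) -> int:
        return self.n_variants * self.reads_per_variant


@dataclass
class SimulationTruth:
    """Ground truth for one simulated experiment.

    ``effects`` has the base effect per variant plus, when replicate-effect
    noise is on, a ``rep<i>_effect`` column per replicate.  ``noise`` lists
    the affected variants with their annotations.
    """

    effects: pd.DataFrame  # index variant; columns effect, predicted_score, ...
    noise: pd.DataFrame  # effect- and jackpot-noise annotations
    config: SimulationConfig

    @property
    def variants(self) -> pd.Index:
        return self.effects.index

    def replicate_effects(self, rep: int) -> np.ndarray:
        col = f"rep{rep}_effect"
        if col in self.effects:
            return self.effects[col].to_numpy()
        return self.effects["effect"].to_numpy()


@dataclass
class SimulatedDataset:
    """Per-replicate count tables with paired ground truth."""

    tables: list[VariantCountTable]
    truth: SimulationTruth

    @property
    def config(self) -> SimulationConfig:
        return self.truth.config

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, table in enumerate(self.tables, 1):
            table.to_tsv(outdir / f"rep{i}_counts.tsv")
        self.truth.effects.to_csv(outdir / "truth.tsv", sep="\t", index_label="variant")
        self.truth.noise.to_csv(outdir / "noise.tsv", sep="\t", index=False)
        (outdir / "config.json").write_text(
            json.dumps(asdict(self.truth.config), indent=1) + "\n"
        )


def _variant_labels(n: int) -> pd.Index:
    width = len(str(n - 1))
    labels = [WILD_TYPE_LABEL] + [f"v{i:0{width}d}" for i in range(1, n)]
    return pd.Index(labels, name="variant")


def draw_true_effects(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw per-variant true effects; index 0 is the wild-type, set exactly.

    Out-of-bounds draws are rejected and redrawn, avoiding point masses at
    the bounds.
    """
    effects = np.empty(config.n_variants)
    effects[0] = config.wt_effect
    effects[1:] = _bounded_normal(
        config.n_variants - 1, config.effect_mean, config.effect_sd, config.bounds, rng
    )
    return effects


def _bounded_normal(n, mean, sd, bounds, rng):
    lo, hi = bounds
    out = rng.normal(mean, sd, size=n)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def initial_population(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal input population, wild-type fixed at 1% of the total.

    The underlying normal has sd ``input_log_sd`` and location
    ln(mean) - sd^2/2 so the log-normal mean equals ``input_mean_count``;
    non-wild-type draws are rescaled to fill the rest of the population.
    """
    wt_count = int(round(config.wt_input_frequency * config.population_size))
    mu = np.log(config.input_mean_count) - config.input_log_sd**2 / 2.0
    draws = rng.lognormal(mu, config.input_log_sd, size=config.n_variants - 1)
    remaining = config.population_size - wt_count
    scaled = np.round(draws / draws.sum() * remaining).astype(np.int64)
    counts = np.empty(config.n_variants, dtype=np.int64)
    counts[0] = wt_count
    counts[1:] = scaled
    return counts


def _resample_population(weights: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    total = weights.sum()
    if total <= 0:
        raise RuntimeError("selection drove the population extinct")
    return rng.multinomial(size, weights / total)


def binding_round(
    population: np.ndarray,
    p: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One round of binding selection: binomial survival, then regrowth.

    Survivors k ~ Binomial(c', p_v); the next population is a weighted
    resample (with replacement) of ``population_size`` individuals with
    weights proportional to k.
    """
    survivors = rng.binomial(population, p)
    return _resample_population(survivors.astype(float), config.population_size, rng)


def growth_round(
    population: np.ndarray,
    mu: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One interval of stochastic exponential growth, then dilution.

    The grown population of each lineage is drawn as
    g ~ NB(r = c', p = e^(-mu dt)) — the offspring produced by a linear
    birth process over dt, mean c' (e^(mu dt) - 1); variants at 0 stay
    extinct.  The grown population is resampled back to
    ``population_size``.
    """
    grown = np.zeros_like(population)
    alive = population > 0
    if alive.any():
        p_success = np.exp(-mu[alive] * config.dt)
        grown[alive] = rng.negative_binomial(population[alive], p_success)
    return _resample_population(grown.astype(float), config.population_size, rng)


def sequence_population(
    population: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial sequencing of the population at fixed total depth."""
    total = population.sum()
    if total <= 0:
        raise RuntimeError("cannot sequence an empty population")
    return rng.multinomial(config.reads_per_timepoint, population / total)


def assign_effect_noise(
    config: SimulationConfig, effects: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Pick noisy variants and resample their effect in one replicate each.

    A fraction ``effect_noise_fraction`` of non-wild-type variants (10% by
    default) is chosen at random and split uniformly over replicates, so 2%
    of variants are noisy in each of 5 replicates.  Returns annotations
    (variant index, replicate, original and resampled effect).
    """
    n_noisy = int(round(config.effect_noise_fraction * (config.n_variants - 1)))
    chosen = rng.choice(np.arange(1, config.n_variants), size=n_noisy, replace=False)
    reps = np.tile(np.arange(config.replicates), n_noisy // config.replicates + 1)[:n_noisy]
    new_effects = _bounded_normal(
        n_noisy, config.effect_mean, config.effect_sd, config.bounds, rng
    )
    return pd.DataFrame(
        {
            "variant_idx": chosen,
            "kind": "effect",
            "replicate": reps,
            "timepoint": -1,
            "original_effect": effects[chosen],
            "new_effect": new_effects,
            "direction": "",
        }
    )


def assign_jackpot_noise(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Pick jackpot-affected variants: half amplified x50, half depleted /50.

    Each affected variant gets one uniformly chosen (replicate, timepoint)
    cell, the input timepoint included.
    """
    n_noisy = int(round(config.jackpot_fraction * (config.n_variants - 1)))
    n_amp = n_noisy // 2
    chosen = rng.choice(np.arange(1, config.n_variants), size=n_noisy, replace=False)
    reps = np.tile(np.arange(config.replicates), n_noisy // config.replicates + 1)[:n_noisy]
    timepoints = rng.integers(0, config.rounds + 1, size=n_noisy)
    direction = np.array(["amplified"] * n_amp + ["depleted"] * (n_noisy - n_amp))
    return pd.DataFrame(
        {
            "variant_idx": chosen,
            "kind": "jackpot",
            "replicate": reps,
            "timepoint": timepoints,
            "original_effect": np.nan,
            "new_effect": np.nan,
            "direction": direction,
        }
    )


def predicted_scores(config: SimulationConfig, effects: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic expected scores under the regression model (wild-type = 0)."""
    max_t = float(config.rounds)
    if config.assay == "binding":
        beta = max_t * np.log(effects / config.p_wt)
        return {"predicted_score": beta}
    m = config.rounds
    delta = config.doublings_per_round
    beta = m * delta * (effects - config.mu_wt)
    slope = m * delta * np.log(2.0) * (effects - config.mu_wt) / config.mu_wt
    return {"predicted_score": beta, "predicted_slope": slope}


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full simulation: effects, replicates, selection, sequencing.

    All randomness derives from ``config.seed``; one master seed spawns
    independent per-replicate streams, so runs are bit-reproducible.
    """
    master = np.random.SeedSequence(config.seed)
    setup_seed, noise_seed, *rep_seeds = master.spawn(config.replicates + 2)
    rng = np.random.Generator(np.random.PCG64(setup_seed))
    noise_rng = np.random.Generator(np.random.PCG64(noise_seed))

    labels = _variant_labels(config.n_variants)
    effects = draw_true_effects(config, rng)

    noise_frames = []
    if config.replicate_effect_noise:
        noise_frames.append(assign_effect_noise(config, effects, noise_rng))
    if config.jackpot_noise:
        noise_frames.append(assign_jackpot_noise(config, noise_rng))
    noise = (
        pd.concat(noise_frames, ignore_index=True)
        if noise_frames
        else pd.DataFrame(
            columns=[
                "variant_idx", "kind", "replicate", "timepoint",
                "original_effect", "new_effect", "direction",
            ]
        )
    )

    effects_df = pd.DataFrame({"effect": effects}, index=labels)
    for name, values in predicted_scores(config, effects).items():
        effects_df[name] = values

    # per-replicate effect vectors (resampled for that replicate's noisy set)
    rep_effects = []
    for rep in range(config.replicates):
        e = effects.copy()
        if config.replicate_effect_noise:
            mask = (noise["kind"] == "effect") & (noise["replicate"] == rep)
            e[noise.loc[mask, "variant_idx"].to_numpy()] = noise.loc[
                mask, "new_effect"
            ].to_numpy()
            effects_df[f"rep{rep}_effect"] = e
        rep_effects.append(e)

    jackpot = noise[noise["kind"] == "jackpot"] if config.jackpot_noise else None

    tables = []
    for rep in range(config.replicates):
        rep_rng = np.random.Generator(np.random.PCG64(rep_seeds[rep]))
        population = initial_population(config, rep_rng)
        e = rep_effects[rep]
        reads = np.empty((config.n_variants, config.rounds + 1), dtype=np.int64)
        reads[:, 0] = sequence_population(
            _apply_jackpot(population, jackpot, rep, 0, config),
            config,
            rep_rng,
        )
        for t in range(1, config.rounds + 1):
            if config.assay == "binding":
                population = binding_round(population, e, config, rep_rng)
            else:
                population = growth_round(population, e, config, rep_rng)
            reads[:, t] = sequence_population(
                _apply_jackpot(population, jackpot, rep, t, config),
                config,
                rep_rng,
            )
        counts = pd.DataFrame(
            reads,
            index=labels,
            columns=[f"t{t}" for t in range(config.rounds + 1)],
        )
        tables.append(
            VariantCountTable(
                counts,
                config.schedule,
                read_totals=[config.reads_per_timepoint] * (config.rounds + 1),
                wild_type=WILD_TYPE_LABEL,
            )
        )

    truth = SimulationTruth(effects_df, noise, config)
    return SimulatedDataset(tables, truth)


def _apply_jackpot(population, jackpot, rep, timepoint, config):
    """Amplify/deplete affected population counts just before sequencing."""
    if jackpot is None:
        return population
    mask = (jackpot["replicate"] == rep) & (jackpot["timepoint"] == timepoint)
    if not mask.any():
        return population
    adjusted = population.copy()
    hit = jackpot.loc[mask]
    amp = hit.loc[hit["direction"] == "amplified", "variant_idx"].to_numpy()
    dep = hit.loc[hit["direction"] == "depleted", "variant_idx"].to_numpy()
    adjusted[amp] = adjusted[amp] * int(config.jackpot_factor)
    adjusted[dep] = adjusted[dep] // int(config.jackpot_factor)
    return adjusted
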