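"""The generation loop: seeded runs, metric accumulation, seed averaging.

A run is a pure function of (parameters, seed).  Headline metrics follow
the cumulative convention: *average cooperation* is the total number of
donations over all games played so far, and *average fusion* is the mean
fusion level over all generation-agent pairs so far, each recorded for the
parent population at the end of its games, before replacement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .params import ModelParams, s_policy_code

logger = logging.getLogger(__name__)

__all__ = ["Population", "MetricsAccumulator", "SimulationResult",
           "init_population", "run_games", "run_generation",
           "run_simulation", "run_experiment"]


@dataclass
class Population:
    """Flat-array population state consumed by the numeric kernels."""

    fusion: np.ndarray      # float64[N]
    rules: np.ndarray       # uint8[N, 3], columns (s, u, d)
    rep: np.ndarray         # int64[N]
    payoff: np.ndarray      # float64[N]
    n_pos: np.ndarray       # int64[N]
    n_neu: np.ndarray       # int64[N]
    n_neg: np.ndarray       # int64[N]
    group_rep: np.ndarray   # int64[1]

    @property
    def size(self) -> int:
        return int(self.fusion.shape[0])

    def reset_generation_state(self) -> None:
        """Zero payoff, both reputations and the contribution counters."""
        self.rep[:] = 0
        self.payoff[:] = 0.0
        self.n_pos[:] = 0
        self.n_neu[:] = 0
        self.n_neg[:] = 0
        self.group_rep[0] = 0


def init_population(params: ModelParams, rng: np.random.Generator) -> Population:
    """Random initial population: rule bits Bernoulli(1/2), fusion uniform
    over the fusion scale.

    Draw order per agent: three rule draws then one fusion draw; the fusion
    draw is skipped entirely under ``init_fusion="zero"``.
    """
    n = params.n_agents
    fusion = np.zeros(n)
    rules = np.zeros((n, 3), dtype=np.uint8)
    for i in range(n):
        for bit in range(3):
            rules[i, bit] = 1 if rng.random() < 0.5 else 0
        if params.init_fusion == "uniform":
            fusion[i] = K.draw_fusion(params.fusion_levels, rng)
    return Population(
        fusion=fusion, rules=rules,
        rep=np.zeros(n, dtype=np.int64), payoff=np.zeros(n),
        n_pos=np.zeros(n, dtype=np.int64), n_neu=np.zeros(n, dtype=np.int64),
        n_neg=np.zeros(n, dtype=np.int64),
        group_rep=np.zeros(1, dtype=np.int64))


@dataclass
class MetricsAccumulator:
    """Cumulative cooperation and fusion statistics across generations."""

    cum_donations: int = 0
    cum_games: int = 0
    cum_fusion_sum: float = 0.0
    gen_count: int = 0
    n_agents: int = 0

    def update(self, donations: int, games: int, fusion_sum: float,
               n_agents: int) -> None:
        self.cum_donations += donations
        self.cum_games += games
        self.cum_fusion_sum += fusion_sum
        self.gen_count += 1
        self.n_agents = n_agents

    @property
    def avg_cooperation(self) -> float:
        """Donations over all games played so far."""
        if self.cum_games == 0:
            return 0.0
        return self.cum_donations / self.cum_games

    @property
    def avg_fusion(self) -> float:
        """Mean fusion over all generation-agent pairs so far."""
        if self.gen_count == 0 or self.n_agents == 0:
            return 0.0
        return self.cum_fusion_sum / (self.gen_count * self.n_agents)


def run_games(pop: Population, params: ModelParams,
              rng: np.random.Generator) -> tuple[int, int]:
    """Play the generation's m games in place.

    Returns (donations, donations by agents with fusion >= T); the latter
    are the ones charged the differential cost.
    """
    s_mode, s_value = s_policy_code(params.s_policy)
    donations, gated = K.play_games(
        pop.fusion, pop.rules, pop.rep, pop.payoff,
        pop.n_pos, pop.n_neu, pop.n_neg, pop.group_rep,
        params.games_per_gen, s_mode, s_value,
        params.ostracism_type, params.threshold, params.delta,
        params.err_perception, params.err_execution,
        params.benefit, params.cost, params.extra_cost, rng)
    return int(donations), int(gated)


def run_generation(pop: Population, params: ModelParams,
                   metrics: MetricsAccumulator,
                   rng: np.random.Generator,
                   record=None) -> int:
    """One full generation: m games, metric update, selection, reset.

    Fusion enters the metrics as the parent population's sum at the end of
    its games, before replacement.  ``record(donations)``, when given, is
    called between the metric update and reproduction, while the parent
    population's end-of-games state is still observable.  Returns the
    generation's donation count.
    """
    donations, _ = run_games(pop, params, rng)
    metrics.update(donations, params.games_per_gen,
                   float(pop.fusion.sum()), pop.size)
    if record is not None:
        record(donations)
    parents = K.reproduce_select(
        pop.fusion, pop.payoff, pop.n_pos, pop.n_neu, pop.n_neg,
        params.ostracism_type, params.threshold,
        params.err_perception, params.err_execution, rng)
    pop.fusion[:] = pop.fusion[parents]
    pop.rules[:] = pop.rules[parents]
    K.mutate_population(pop.fusion, pop.rules, params.mutation_rate,
                        params.mutate_fusion, params.fusion_levels, rng)
    pop.reset_generation_state()
    return donations


@dataclass
class SimulationResult:
    """Outcome of one seeded run."""

    params: ModelParams
    seed: int
    metrics: MetricsAccumulator
    trajectory: pd.DataFrame = field(repr=False)
    final_population: Population = field(repr=False)

    @property
    def avg_cooperation(self) -> float:
        return self.metrics.avg_cooperation

    @property
    def avg_fusion(self) -> float:
        return self.metrics.avg_fusion


def run_simulation(params: ModelParams, seed: int | None = None,
                   record_every: int = 1,
                   log_every: int = 0) -> SimulationResult:
    """Run M generations from a fresh random population.

    ``record_every`` thins the per-generation trajectory records (the final
    generation is always recorded); ``log_every`` > 0 emits progress lines
    at that generation interval.
    """
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    pop = init_population(params, rng)
    metrics = MetricsAccumulator()
    rows = []
    m_gen = params.generations
    for gen in range(1, m_gen + 1):
        def record(donations, gen=gen):
            # records describe the parent population before replacement
            if gen % record_every == 0 or gen == m_gen:
                rows.append((gen, donations, metrics.avg_cooperation,
                             metrics.avg_fusion, float(pop.payoff.mean()),
                             int(pop.group_rep[0])))
            if log_every and gen % log_every == 0:
                logger.info("gen %d/%d coop=%.3f fusion=%.3f", gen, m_gen,
                            metrics.avg_cooperation, metrics.avg_fusion)

        run_generation(pop, params, metrics, rng, record=record)
    trajectory = pd.DataFrame(rows, columns=[
        "generation", "donations", "avg_cooperation", "avg_fusion",
        "mean_payoff", "group_rep"])
    return SimulationResult(params=params, seed=seed, metrics=metrics,
                            trajectory=trajectory, final_population=pop)


@dataclass
class ExperimentResult:
    """Seed-replicated runs of one condition plus their arithmetic means."""

    params: ModelParams
    seeds: list[int]
    runs: list[SimulationResult] = field(repr=False)
    avg_cooperation: float = 0.0
    avg_fusion: float = 0.0

    @property
    def mean_trajectory(self) -> pd.DataFrame:
        frames = [r.trajectory.set_index("generation") for r in self.runs]
        return sum(frames[1:], frames[0]) / len(frames)


def run_experiment(params: ModelParams, n_seeds: int = 1,
                   seeds: list[int] | None = None,
                   record_every: int = 1) -> ExperimentResult:
    """Run one condition over several seeds and average the final metrics.

    Seeds default to ``params.seed, params.seed + 1, ...``; averaging is
    the arithmetic mean over seeds.
    """
    if seeds is None:
        if n_seeds < 1:
            raise ValueError("n_seeds must be at least 1")
        seeds = [params.seed + k for k in range(n_seeds)]
    runs = [run_simulation(params, seed=s, record_every=record_every)
            for s in seeds]
    return ExperimentResult(
        params=params, seeds=list(seeds), runs=runs,
        avg_cooperation=float(np.mean([r.avg_cooperation for r in runs])),
        avg_fusion=float(np.mean([r.avg_fusion for r in runs])))
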