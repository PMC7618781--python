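"""Genetic-algorithm optimisation of the histogram-normalisation layout.

The five-segment histogram layout has seven free parameters — four
percentile boundaries P1..P4 and three segment bin counts n1..n3 — and the
quality of the resulting normalisation is judged by how well the
normalised spectra cluster into the two classes of interest (the
clustering ratio C_R).  A small generational GA searches that space:
tournament selection, uniform crossover, bounded per-gene mutation, and
elitism (so the best-so-far fitness is non-decreasing).  Genomes that
violate the layout constraints (percentiles out of order, bin counts < 1)
or that make the histogram degenerate on the data score -inf.

The initial population is seeded around the default layout
(P = 20/40/60/80, n = 30/30/30) plus random genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cluster import clustering_ratio
from .matrix import SpectrumMatrix
from .normalization import HistogramConfig, normalize_histogram

__all__ = ["GAConfig", "GAHistory", "fitness", "run_ga", "exhaustive_search"]

_N_GENES = 7  # P1..P4, n1..n3


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    generations: int = 50
    mutation_rate: float = 0.1
    crossover_rate: float = 0.8
    tournament_size: int = 3
    elitism: int = 2
    seed: int = 0
    p_bounds: tuple[float, float] = (1.0, 99.0)
    n_bounds: tuple[int, int] = (1, 60)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.generations < 1 or self.tournament_size < 1 or self.elitism < 0:
            raise ValueError("generations, tournament_size >= 1; elitism >= 0")
        if not (0.0 < self.p_bounds[0] < self.p_bounds[1] < 100.0):
            raise ValueError("p_bounds must lie strictly inside (0, 100)")
        if self.n_bounds[0] < 1 or self.n_bounds[0] > self.n_bounds[1]:
            raise ValueError("n_bounds must satisfy 1 <= lo <= hi")


@dataclass
class GAHistory:
    """Per-generation best/mean fitness and the best genome so far."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_genome: list[np.ndarray] = field(default_factory=list)


def _genome_to_config(genome: np.ndarray) -> HistogramConfig:
    return HistogramConfig(
        P1=float(genome[0]), P2=float(genome[1]),
        P3=float(genome[2]), P4=float(genome[3]),
        n1=int(genome[4]), n2=int(genome[5]), n3=int(genome[6]),
    )


def fitness(
    config: HistogramConfig | np.ndarray,
    matrix: SpectrumMatrix,
    variant: str = "histbin",
) -> float:
    """C_R of the matrix after histogram normalisation; -inf when invalid.

    Deterministic for fixed inputs: the histogram normalisation and the
    clustering ratio involve no randomness.
    """
    try:
        if not isinstance(config, HistogramConfig):
            config = _genome_to_config(np.asarray(config))
        ratio = clustering_ratio(normalize_histogram(matrix, variant, config)).C_R
    except (ValueError, OverflowError):
        return float("-inf")
    return ratio if np.isfinite(ratio) else float("-inf")


def _default_genome() -> np.ndarray:
    return np.array([20.0, 40.0, 60.0, 80.0, 30, 30, 30], dtype=np.float64)


def _random_genome(rng: np.random.Generator, cfg: GAConfig) -> np.ndarray:
    p = np.sort(rng.uniform(cfg.p_bounds[0], cfg.p_bounds[1], size=4))
    # nudge any coincident percentiles apart
    for i in range(1, 4):
        if p[i] <= p[i - 1]:
            p[i] = min(p[i - 1] + 0.5, cfg.p_bounds[1])
    n = rng.integers(cfg.n_bounds[0], cfg.n_bounds[1] + 1, size=3)
    return np.concatenate([p, n]).astype(np.float64)


def _mutate(genome: np.ndarray, rng: np.random.Generator, cfg: GAConfig) -> np.ndarray:
    out = genome.copy()
    for i in range(4):
        if rng.random() < cfg.mutation_rate:
            out[i] = np.clip(out[i] + rng.normal(0.0, 5.0),
                             cfg.p_bounds[0], cfg.p_bounds[1])
    for i in range(4, _N_GENES):
        if rng.random() < cfg.mutation_rate:
            out[i] = np.clip(round(out[i] + rng.integers(-5, 6)),
                             cfg.n_bounds[0], cfg.n_bounds[1])
    return out


def _tournament(
    rng: np.random.Generator, fits: np.ndarray, k: int
) -> int:
    contenders = rng.integers(0, fits.size, size=min(k, fits.size))
    return int(contenders[np.argmax(fits[contenders])])


def run_ga(
    matrix: SpectrumMatrix,
    variant: str = "histbin",
    ga_config: GAConfig | None = None,
) -> tuple[HistogramConfig, GAHistory]:
    """Optimise the histogram layout for one labelled matrix.

    Returns the best-ever layout and the per-generation history; fully
    reproducible from ``ga_config.seed``.
    """
    cfg = ga_config or GAConfig()
    rng = np.random.default_rng(cfg.seed)

    population = [_default_genome()]
    # jittered copies of the default, then fully random genomes
    while len(population) < max(2, cfg.population_size // 4):
        population.append(_mutate(_default_genome(), rng, cfg))
    while len(population) < cfg.population_size:
        population.append(_random_genome(rng, cfg))
    population = population[: cfg.population_size]

    history = GAHistory()
    best_genome = population[0].copy()
    best_fit = float("-inf")

    for _ in range(cfg.generations):
        fits = np.array([fitness(g, matrix, variant) for g in population])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genome = population[gen_best].copy()
        finite = fits[np.isfinite(fits)]
        history.best_fitness.append(best_fit)
        history.mean_fitness.append(float(finite.mean()) if finite.size else float("-inf"))
        history.best_genome.append(best_genome.copy())

        elite_idx = np.argsort(fits)[::-1][: cfg.elitism]
        next_pop = [population[i].copy() for i in elite_idx]
        while len(next_pop) < cfg.population_size:
            a = population[_tournament(rng, fits, cfg.tournament_size)]
            b = population[_tournament(rng, fits, cfg.tournament_size)]
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(_N_GENES) < 0.5
                child = np.where(mask, a, b)
            else:
                child = a.copy()
            next_pop.append(_mutate(child, rng, cfg))
        population = next_pop[: cfg.population_size]

    if not np.isfinite(best_fit):
        raise ValueError("no valid histogram layout found during the GA run")
    return _genome_to_config(best_genome), history


def exhaustive_search(
    matrix: SpectrumMatrix,
    variant: str,
    p_grid: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    n_grid: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> tuple[HistogramConfig | None, float]:
    """Brute-force sweep over a small grid of layouts (oracle for the GA)."""
    best_cfg, best_fit = None, float("-inf")
    for p1 in p_grid[0]:
        for p2 in p_grid[1]:
            for p3 in p_grid[2]:
                for p4 in p_grid[3]:
                    if not p1 < p2 < p3 < p4:
                        continue
                    for n1 in n_grid[0]:
                        for n2 in n_grid[1]:
                            for n3 in n_grid[2]:
                                genome = np.array(
                                    [p1, p2, p3, p4, n1, n2, n3], dtype=np.float64
                                )
                                fit = fitness(genome, matrix, variant)
                                if fit > best_fit:
                                    best_fit = fit
                                    best_cfg = _genome_to_config(genome)
    return best_cfg, best_fit
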