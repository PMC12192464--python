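"""Fuzzy-logic fusion of the four connectivity measures, GA-tuned.

Each measure value passes through a logistic membership function
sigma(k_m * (x - theta_m)) — "how edge-like is this score for measure m" —
and the memberships are combined by a convex weighted sum.  The membership
thresholds, slopes and fusion weights are tuned by a genetic algorithm
against simulated ground-truth networks, with edge-detection AUC as the
fitness, so no decision threshold has to be fixed during tuning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .fcmeasures import MEASURE_NAMES, MeasureMatrix, compute_measures
from .recording import Recording
from .simkit import GroundTruthNetwork, make_network, simulate_block

__all__ = ["FusionConfig", "FusedFC", "fuse", "edge_auc", "tune_ga",
           "GAResult", "default_config"]

logger = logging.getLogger(__name__)

UNDIRECTED = ("BCorrU", "COH1")

_SLOPE_BOUNDS = (0.5, 50.0)


@dataclass
class FusionConfig:
    """Membership parameters and fusion weights for the four measures."""

    thresholds: dict[str, float]
    slopes: dict[str, float]
    weights: dict[str, float]
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        for name in MEASURE_NAMES:
            for d, what in ((self.thresholds, "threshold"),
                            (self.slopes, "slope"), (self.weights, "weight")):
                if name not in d:
                    raise ValueError(f"missing {what} for measure {name}")
        if any(k <= 0 for k in self.slopes.values()):
            raise ValueError("slopes must be positive")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights sum to zero")
        self.weights = {m: w / total for m, w in self.weights.items()}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "FusionConfig":
        return cls(**json.loads(Path(path).read_text()))


def default_config() -> FusionConfig:
    """Untuned equal-weight config: midpoint thresholds, moderate slopes."""
    return FusionConfig(
        thresholds={m: 0.5 for m in MEASURE_NAMES},
        slopes={m: 10.0 for m in MEASURE_NAMES},
        weights={m: 0.25 for m in MEASURE_NAMES},
    )


@dataclass
class FusedFC:
    """Fused directed FC matrix (source row -> target column) in [0, 1]."""

    values: np.ndarray
    config_used: FusionConfig | None = None


def fuse(measures: dict[str, MeasureMatrix], config: FusionConfig) -> FusedFC:
    """Convex weighted sum of logistic memberships of the four measures."""
    missing = set(MEASURE_NAMES) - set(measures)
    if missing:
        raise ValueError(f"missing measure(s) {sorted(missing)}")
    shapes = {measures[m].values.shape for m in MEASURE_NAMES}
    if len(shapes) != 1:
        raise ValueError(f"measure shape mismatch: {shapes}")
    n = next(iter(shapes))[0]
    fused = np.zeros((n, n))
    for m in MEASURE_NAMES:
        x = measures[m].values
        membership = 1.0 / (1.0 + np.exp(-config.slopes[m] * (x - config.thresholds[m])))
        fused += config.weights[m] * membership
    fused = np.clip(fused, 0.0, 1.0)
    np.fill_diagonal(fused, 0.0)
    return FusedFC(fused, config)


def edge_auc(scores: np.ndarray, truth: GroundTruthNetwork) -> float:
    """AUC of off-diagonal scores against the true directed edge mask."""
    n = truth.n_nodes
    off = ~np.eye(n, dtype=bool)
    y = truth.edge_mask()[off].astype(int)
    if y.min() == y.max():
        raise ValueError("degenerate truth network: all edges present or absent")
    return float(roc_auc_score(y, scores[off]))


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

@dataclass
class GAResult:
    config: FusionConfig
    fitness_trace: list[float] = field(default_factory=list)
    best_fitness: float = float("nan")


def _genome_to_config(genome: np.ndarray) -> FusionConfig:
    g = np.asarray(genome, dtype=float)
    thresholds = {m: float(np.clip(g[i], 0.0, 1.0))
                  for i, m in enumerate(MEASURE_NAMES)}
    slopes = {m: float(np.clip(g[4 + i], *_SLOPE_BOUNDS))
              for i, m in enumerate(MEASURE_NAMES)}
    raw_w = np.clip(g[8:12], 0.0, None)
    if raw_w.sum() <= 0:
        raw_w = np.ones(4)
    weights = {m: float(raw_w[i]) for i, m in enumerate(MEASURE_NAMES)}
    return FusionConfig(thresholds, slopes, weights)


def _init_genome(rng: np.random.Generator) -> np.ndarray:
    return np.concatenate([
        rng.uniform(0.1, 0.9, 4),          # thresholds
        rng.uniform(2.0, 30.0, 4),         # slopes
        rng.uniform(0.05, 1.0, 4),         # weights
    ])


def _mutate(genome: np.ndarray, rng: np.random.Generator,
            rate: float, sd: float) -> np.ndarray:
    out = genome.copy()
    mask = rng.random(out.size) < rate
    scale = np.concatenate([np.full(4, sd), np.full(4, sd * 20), np.full(4, sd)])
    out[mask] += rng.normal(0.0, scale[mask])
    return out


def training_measures(n_networks: int, n_nodes: int, density: float,
                      n_samples: int, seed: int,
                      weight_range: tuple[float, float] = (0.3, 0.8),
                      noise_scale: float = 1.0,
                      order: int | str = 1,
                      ) -> list[tuple[GroundTruthNetwork, dict[str, MeasureMatrix]]]:
    """Simulate networks and precompute the four measures on each.

    Measure matrices are fixed per network, so GA fitness evaluation reduces
    to re-fusing cached matrices — the expensive signal processing happens
    once per network, not once per genome.
    """
    out = []
    fs = 1000.0
    for i in range(n_networks):
        net = make_network(n_nodes, density, weight_range, seed=seed + 1000 + i)
        rng = np.random.default_rng(seed + 2000 + i)
        data = simulate_block(net, n_samples / fs, fs, order=1,
                              noise_scale=noise_scale, rng=rng)
        rec = Recording(data, fs)
        out.append((net, compute_measures(rec, order=order)))
    return out


def tune_ga(training: list[tuple[GroundTruthNetwork, dict[str, MeasureMatrix]]],
            pop_size: int = 50, generations: int = 40,
            mutation_rate: float = 0.2, mutation_sd: float = 0.1,
            crossover_rate: float = 0.7, tournament_size: int = 3,
            seed: int = 0) -> GAResult:
    """Tune fusion parameters by a genetic algorithm.

    Fitness of a genome is the mean edge-detection AUC of its fused matrix
    across the training networks.  Tournament selection with one elite,
    uniform crossover, Gaussian mutation; the running-best fitness trace is
    non-decreasing by construction.
    """
    if pop_size < 10:
        raise ValueError("pop_size must be >= 10")
    if not training:
        raise ValueError("no training networks")
    rng = np.random.default_rng(seed)

    def fitness(genome: np.ndarray) -> float:
        cfg = _genome_to_config(genome)
        aucs = [edge_auc(fuse(meas, cfg).values, net) for net, meas in training]
        return float(np.mean(aucs))

    pop = [_init_genome(rng) for _ in range(pop_size)]
    fits = np.array([fitness(g) for g in pop])
    best_idx = int(np.argmax(fits))
    best_genome, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace = [best_fit]

    for gen in range(generations):
        if np.ptp([tuple(g) for g in pop], axis=0).max() < 1e-12:
            logger.warning("degenerate population at generation %d; early stop", gen)
            break
        new_pop = [best_genome.copy()]                 # elitism
        while len(new_pop) < pop_size:
            picks = rng.integers(0, pop_size, tournament_size)
            p1 = pop[picks[np.argmax(fits[picks])]]
            picks = rng.integers(0, pop_size, tournament_size)
            p2 = pop[picks[np.argmax(fits[picks])]]
            if rng.random() < crossover_rate:
                mask = rng.random(p1.size) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            new_pop.append(_mutate(child, rng, mutation_rate, mutation_sd))
        pop = new_pop
        fits = np.array([fitness(g) for g in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_genome = pop[gen_best].copy()
        trace.append(best_fit)

    return GAResult(_genome_to_config(best_genome), trace, best_fit)
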