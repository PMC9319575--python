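"""Genetic-algorithm wrapper feature selection with in-loop resampling.

Chromosomes are binary feature masks. The fitness of a mask is

    mean over holdout partitions of  F1 * (NFeat - NCFeat)

where F1 is the preterm-class F1 of an LDA trained on the (possibly
resampled) 64 % training fold and scored on the (possibly resampled) 16 %
validation fold, NFeat is the genome length and NCFeat the number of
selected features. The all-ones mask therefore scores exactly 0, and at
equal F1 smaller masks always win — the size term is the parsimony
pressure. The key design axis is *where* resampling happens inside the
loop: the training fold (FS_T*) or the validation fold (FS_V*), by
oversampling (O), NCL undersampling (U) or the hybrid (H).

The GA itself is a plain generational scheme: tournament selection of
size 2, arithmetic crossover (offspring re-binarised at 0.5, ties toward
the respective parent), uniform bit-flip mutation, two elites, and a
stall-based termination rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .evaluation import f1_score_binary, lda_fit, lda_posterior
from .features import FeatureTable, standardize
from .resampling import ResamplingSpec, resample

logger = logging.getLogger("ehgselect")

STRATEGY_CODES = ("FS_TO", "FS_TU", "FS_TH", "FS_VO", "FS_VU", "FS_VH")
_METHOD_BY_LETTER = {"O": "smote", "U": "ncl_undersample", "H": "hybrid"}


@dataclass
class FSStrategy:
    """One of the six named feature-selection resampling strategies."""

    resample_partition: str  # "training" | "validation"
    method: str              # resampling.METHODS entry
    target_ratio: float = 1.0

    def __post_init__(self):
        if self.resample_partition not in ("training", "validation"):
            raise ValueError("resample_partition must be 'training' or 'validation'")

    @classmethod
    def from_code(cls, code: str, target_ratio: float = 1.0) -> "FSStrategy":
        if code not in STRATEGY_CODES:
            raise ValueError(f"unknown strategy {code!r}; expected one of {STRATEGY_CODES}")
        partition = "training" if code[3] == "T" else "validation"
        return cls(partition, _METHOD_BY_LETTER[code[4]], target_ratio)

    @property
    def code(self) -> str:
        letter = {v: k for k, v in _METHOD_BY_LETTER.items()}[self.method]
        return f"FS_{'T' if self.resample_partition == 'training' else 'V'}{letter}"


@dataclass
class Chromosome:
    """Binary feature mask with its fitness."""

    mask: np.ndarray
    fitness: float = float("nan")
    trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class GAConfig:
    """GA hyperparameters; defaults are the full-scale configuration
    (population 222, 500 generations, stall after 150 flat generations)."""

    population_size: int = 222
    genome_length: int = 222
    generations: int = 500
    crossover_prob: float = 0.8
    mutation_prob: float = 0.01
    tournament_size: int = 2
    elite_count: int = 2
    stall_generations: int = 150
    stall_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.elite_count >= self.population_size:
            raise ValueError("elite_count must be smaller than population_size")


class FitnessEvaluator:
    """Size-weighted F1 fitness of a mask over a fixed partition scheme.

    The per-partition standardized matrices are precomputed once; the
    resampling RNG is re-seeded per partition from (seed, partition), so
    fitness is a deterministic function of the mask and results are
    cached by mask bytes.
    """

    def __init__(self, table: FeatureTable, scheme, strategy: FSStrategy,
                 seed: int = 0):
        self.table = table
        self.scheme = scheme
        self.strategy = strategy
        self.seed = seed
        self.n_feat = table.n_features
        self._cache: dict[bytes, float] = {}
        self._partitions = []
        for train_idx, val_idx, _test_idx in scheme.splits:
            Xs, _, _ = standardize(table.X, train_idx)
            self._partitions.append((Xs, train_idx, val_idx))
        self._labels = table.labels

    def _spec(self) -> ResamplingSpec:
        return ResamplingSpec(method=self.strategy.method,
                              target_ratio=self.strategy.target_ratio)

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        key = mask.tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if not mask.any():
            raise ValueError("cannot evaluate an empty feature mask")
        k = int(mask.sum())
        weight = self.n_feat - k
        if weight == 0:
            # all-ones mask: fitness is identically 0, skip the model fits
            self._cache[key] = 0.0
            return 0.0
        spec = self._spec()
        y = self._labels
        total = 0.0
        for p_idx, (Xs, train_idx, val_idx) in enumerate(self._partitions):
            Xm = Xs[:, mask]
            X_tr, y_tr = Xm[train_idx], y[train_idx]
            X_va, y_va = Xm[val_idx], y[val_idx]
            rng = np.random.default_rng(np.random.SeedSequence((self.seed, p_idx)))
            if self.strategy.resample_partition == "training":
                X_tr, y_tr = resample(X_tr, y_tr, spec, rng=rng)
            else:
                X_va, y_va = resample(X_va, y_va, spec, rng=rng)
            if (y_va == 1).sum() == 0:
                raise ValueError(
                    f"partition {p_idx}: validation fold lost all minority rows")
            model = lda_fit(X_tr, y_tr)
            pred = lda_posterior(model, X_va) >= 0.5
            total += f1_score_binary(pred, y_va) * weight
        value = total / len(self._partitions)
        self._cache[key] = value
        return value


def fitness(chromosome: Chromosome, table: FeatureTable, scheme,
            strategy: FSStrategy, seed: int = 0) -> float:
    """Convenience one-off fitness evaluation of a chromosome."""
    return FitnessEvaluator(table, scheme, strategy, seed=seed)(chromosome.mask)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, mask.size)] = True
    return mask


def _crossover(p1: np.ndarray, p2: np.ndarray,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic crossover with re-binarisation at 0.5.

    child = a*p1 + (1-a)*p2 with per-gene weights a ~ U(0,1); values
    > 0.5 become 1, exactly 0.5 falls back to the respective first
    parent's bit. (A single shared weight would degenerate on binary
    genomes: after thresholding every differing gene would follow the
    same parent, so no genes would ever mix.)
    """
    a = rng.random(p1.shape)
    c1f = a * p1 + (1 - a) * p2
    c2f = (1 - a) * p1 + a * p2
    c1 = np.where(c1f > 0.5, True, np.where(c1f < 0.5, False, p1))
    c2 = np.where(c2f > 0.5, True, np.where(c2f < 0.5, False, p2))
    return c1.astype(bool), c2.astype(bool)


def evolve(table: FeatureTable, scheme, strategy: FSStrategy,
           config: GAConfig | None = None,
           evaluator: FitnessEvaluator | None = None) -> Chromosome:
    """Run the GA and return the best-ever chromosome with its fitness trace.

    Deterministic under (config.seed, scheme): the same best mask is
    returned bit-for-bit across runs.
    """
    if config is None:
        config = GAConfig()
    if config.genome_length != table.n_features:
        config = replace(config, genome_length=table.n_features)
    if evaluator is None:
        evaluator = FitnessEvaluator(table, scheme, strategy, seed=config.seed)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    P, L = config.population_size, config.genome_length

    pop = rng.random((P, L)) < 0.5
    pop = np.array([_repair(m, rng) for m in pop])
    fits = np.array([evaluator(m) for m in pop])

    best_mask = pop[np.argmax(fits)].copy()
    best_fit = float(fits.max())
    trace = [best_fit]
    stall = 0

    for _gen in range(1, config.generations):
        order = np.argsort(fits)[::-1]
        elites = pop[order[:config.elite_count]].copy()
        children: list[np.ndarray] = []
        while len(children) < P - config.elite_count:
            idx1 = rng.integers(0, P, size=config.tournament_size)
            idx2 = rng.integers(0, P, size=config.tournament_size)
            p1 = pop[idx1[np.argmax(fits[idx1])]]
            p2 = pop[idx2[np.argmax(fits[idx2])]]
            if rng.random() < config.crossover_prob:
                c1, c2 = _crossover(p1, p2, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children.append(c1)
            if len(children) < P - config.elite_count:
                children.append(c2)
        child_arr = np.array(children)
        flip = rng.random(child_arr.shape) < config.mutation_prob
        child_arr ^= flip
        child_arr = np.array([_repair(m, rng) for m in child_arr])
        pop = np.vstack([elites, child_arr])
        fits = np.array([evaluator(m) for m in pop])

        gen_best = float(fits.max())
        if gen_best > best_fit + config.stall_tolerance:
            stall = 0
        else:
            stall += 1
        if gen_best > best_fit:
            best_fit = gen_best
            best_mask = pop[np.argmax(fits)].copy()
        trace.append(best_fit)
        if stall >= config.stall_generations:
            logger.info("GA stalled after %d generations (best %.4f)", _gen + 1, best_fit)
            break

    return Chromosome(mask=best_mask, fitness=best_fit, trace=trace)
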