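"""Orchestration of the three-step study design over a shared partition
scheme, plus the oversampling-leakage demonstration.

Step 1 runs the GA once per feature-selection strategy (FS_TO/TU/TH and
FS_VO/VU/VH) on a fixed scheme of stratified train(64 %)/validation(16 %)/
test(20 %) splits, with the all-features mask (AF) as baseline. Step 2
takes each selected mask, resamples the pooled 80 % training block with
each of RN/RO/RU/RH, fits LDA and scores the untouched test block,
collecting per-partition AUC and AP. Step 3 sweeps the post-resampling
minority:majority ratio of the validation fold from 20 % to 100 % under
FS_VU and re-evaluates with RN. Because every step reuses the same
scheme, all comparisons are paired across partitions.

The leakage demonstration contrasts SMOTE applied to the whole table
*before* splitting (synthetic minority rows correlated across train and
test, inflating test AUC) with SMOTE applied to the training block
*after* splitting — the honest protocol used everywhere else here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .evaluation import EvalResult, average_precision, auc, lda_fit, lda_posterior
from .features import FeatureTable, OBSTETRIC_NAMES, standardize
from .ga import Chromosome, FSStrategy, GAConfig, STRATEGY_CODES, evolve
from .resampling import ResamplingSpec, resample
from .synthetic import TableSpec, generate_feature_table

logger = logging.getLogger("ehgselect")

POST_METHODS = ("RN", "RO", "RU", "RH")


# ---------------------------------------------------------------------------
# partition scheme
# ---------------------------------------------------------------------------

@dataclass
class PartitionScheme:
    """Stratified train/validation/test index triples, reused everywhere."""

    splits: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    seed: int
    n_repeats: int

    def train80(self, i: int) -> np.ndarray:
        """Pooled 64 % + 16 % training block of repeat i."""
        tr, va, _ = self.splits[i]
        return np.concatenate([tr, va])


def build_scheme(labels: np.ndarray, n_repeats: int = 200, seed: int = 0,
                 fractions: tuple[float, float, float] = (0.64, 0.16, 0.20)
                 ) -> PartitionScheme:
    """Stratified random splits; repeat i depends on (seed, i) alone.

    Per class the test/validation counts are rounded from the fractions;
    every set must keep at least one row of each class, otherwise the
    minimum required class size is reported.
    """
    labels = np.asarray(labels, dtype=int)
    f_train, f_val, f_test = fractions
    if abs(f_train + f_val + f_test - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    splits = []
    class_idx = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    for c, idx in class_idx.items():
        n_test = round(f_test * idx.size)
        n_val = round(f_val * idx.size)
        n_train = idx.size - n_test - n_val
        if min(n_test, n_val, n_train) < 1:
            need = int(np.ceil(1.0 / min(f_test, f_val)))
            raise ValueError(
                f"class {c} has {idx.size} rows; at least {need} are needed "
                f"to guarantee one row per train/validation/test set")
    for i in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        tr, va, te = [], [], []
        for c, idx in class_idx.items():
            perm = rng.permutation(idx)
            n_test = round(f_test * idx.size)
            n_val = round(f_val * idx.size)
            te.append(perm[:n_test])
            va.append(perm[n_test:n_test + n_val])
            tr.append(perm[n_test + n_val:])
        splits.append((np.sort(np.concatenate(tr)),
                       np.sort(np.concatenate(va)),
                       np.sort(np.concatenate(te))))
    return PartitionScheme(splits=splits, seed=seed, n_repeats=n_repeats)


# ---------------------------------------------------------------------------
# genome restriction (Table-2 mode: GA over signal features only)
# ---------------------------------------------------------------------------

def restrict_genome_to_signals(table: FeatureTable, mask: np.ndarray) -> np.ndarray:
    """Force the obstetric covariates on, leaving the GA genome to the
    signal features only (the 222-gene reading of the configuration)."""
    mask = np.asarray(mask, bool).copy()
    for i, name in enumerate(table.feature_names):
        if name in OBSTETRIC_NAMES:
            mask[i] = True
    return mask


# ---------------------------------------------------------------------------
# step 1: feature selection per strategy
# ---------------------------------------------------------------------------

def step1(table: FeatureTable, scheme: PartitionScheme,
          strategies: tuple[str, ...] = STRATEGY_CODES,
          config: GAConfig | None = None,
          target_ratio: float = 1.0) -> dict[str, Chromosome]:
    """GA feature selection per strategy; 'AF' records the all-ones mask."""
    out: dict[str, Chromosome] = {}
    for code in strategies:
        strategy = FSStrategy.from_code(code, target_ratio=target_ratio)
        out[code] = evolve(table, scheme, strategy, config)
        logger.info("step1 %s: %d features, fitness %.3f",
                    code, out[code].n_selected, out[code].fitness)
    out["AF"] = Chromosome(mask=np.ones(table.n_features, dtype=bool), fitness=0.0)
    return out


# ---------------------------------------------------------------------------
# step 2: post-selection resampling of the training block
# ---------------------------------------------------------------------------

def evaluate_mask(table: FeatureTable, scheme: PartitionScheme,
                  mask: np.ndarray, method: str = "RN",
                  target_ratio: float = 1.0, seed: int = 0) -> EvalResult:
    """Train on the resampled 80 % block, score the untouched test block.

    Per repeat: standardize by the 80 % block, mask columns, resample the
    block as one unit (RN/RO/RU/RH), fit LDA and collect test AUC/AP.
    Test rows never enter the resampler.
    """
    mask = np.asarray(mask, bool)
    spec = ResamplingSpec(method=method, target_ratio=target_ratio)
    y = table.labels
    aucs, aps = [], []
    for i, (_tr, _va, test_idx) in enumerate(scheme.splits):
        train80 = scheme.train80(i)
        if np.intersect1d(train80, test_idx).size:
            raise AssertionError("test rows leaked into the training block")
        Xs, _, _ = standardize(table.X, train80)
        Xm = Xs[:, mask]
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        X_tr, y_tr = resample(Xm[train80], y[train80], spec, rng=rng)
        model = lda_fit(X_tr, y_tr)
        scores = lda_posterior(model, Xm[test_idx])
        aucs.append(auc(scores, y[test_idx]))
        aps.append(average_precision(scores, y[test_idx]))
    return EvalResult(auc=np.array(aucs), ap=np.array(aps))


def step2(table: FeatureTable, scheme: PartitionScheme,
          masks: dict[str, Chromosome | np.ndarray],
          post_methods: tuple[str, ...] = POST_METHODS,
          seed: int = 0) -> dict[tuple[str, str], EvalResult]:
    """AUC/AP grid over (feature subset, post-selection resampling)."""
    grid: dict[tuple[str, str], EvalResult] = {}
    for name, chrom in masks.items():
        mask = chrom.mask if isinstance(chrom, Chromosome) else np.asarray(chrom, bool)
        for method in post_methods:
            grid[(name, method)] = evaluate_mask(
                table, scheme, mask, method=method, seed=seed)
            s = grid[(name, method)].summary()
            logger.info("step2 %s/%s: AUC %.1f%% AP %.1f%%", name, method,
                        100 * s["auc_mean"], 100 * s["ap_mean"])
    return grid


# ---------------------------------------------------------------------------
# step 3: validation imbalance-ratio sweep
# ---------------------------------------------------------------------------

def step3(table: FeatureTable, scheme: PartitionScheme,
          ratios: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
          config: GAConfig | None = None,
          strategy_code: str = "FS_VU",
          seed: int = 0) -> dict[float, dict]:
    """Rerun selection under FS_VU at each validation target ratio, then
    evaluate the selected mask with RN; returns chromosome and EvalResult
    per ratio."""
    out: dict[float, dict] = {}
    for r in ratios:
        strategy = FSStrategy.from_code(strategy_code, target_ratio=r)
        chrom = evolve(table, scheme, strategy, config)
        result = evaluate_mask(table, scheme, chrom.mask, method="RN", seed=seed)
        out[r] = {"chromosome": chrom, "result": result}
        s = result.summary()
        logger.info("step3 ratio %.0f%%: %d features, (AUC+AP)/2 %.1f%%",
                    100 * r, chrom.n_selected, 100 * s["combined_mean"])
    return out


def sweep_trend(results: dict[float, dict]) -> tuple[float, float]:
    """Spearman correlation between ratio and mean (AUC+AP)/2."""
    ratios = sorted(results)
    means = [results[r]["result"].summary()["combined_mean"] for r in ratios]
    rho, p = stats.spearmanr(ratios, means)
    return float(rho), float(p)


def ratio_sweep_experiment(seed: int = 0, n_replicates: int = 2,
                           n_repeats: int = 20,
                           config: GAConfig | None = None) -> dict:
    """Validation imbalance-ratio sweep in the heavy-overlap regime.

    The study's structure is emulated with a 227-column Gaussian table
    (30 weakly informative columns among 197 noise, 51:275 rows) whose
    all-features LDA baseline sits near chance — the regime where the
    quality of the fitness signal, and hence the validation balance,
    decides what the GA finds. Each replicate draws a fresh table and
    partition scheme and reruns selection at every ratio; the trend is the
    Spearman correlation between ratio and test (AUC+AP)/2 over all
    (replicate, ratio) points.
    """
    if config is None:
        config = GAConfig(population_size=40, generations=60,
                          stall_generations=150)
    ratios = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
    points: list[tuple[float, float]] = []
    per_ratio: dict[float, list[float]] = {r: [] for r in ratios}
    sizes: dict[float, list[int]] = {r: [] for r in ratios}
    for rep in range(n_replicates):
        s_table, s_scheme, s_ga = (
            int(s % 2**31)
            for s in np.random.SeedSequence((seed, rep)).generate_state(3))
        table = generate_feature_table(TableSpec(
            n_minority=51, n_majority=275, n_informative=30, n_noise=197,
            separation=1.0, seed=s_table))
        scheme = build_scheme(table.labels, n_repeats=n_repeats, seed=s_scheme)
        cfg = replace(config, seed=s_ga, genome_length=table.n_features)
        results = step3(table, scheme, ratios=ratios, config=cfg, seed=s_ga)
        for r in ratios:
            combined = results[r]["result"].summary()["combined_mean"]
            points.append((r, combined))
            per_ratio[r].append(combined)
            sizes[r].append(results[r]["chromosome"].n_selected)
    xs, ys = zip(*points)
    rho, p = stats.spearmanr(xs, ys)
    return {
        "points": points,
        "per_ratio_mean": {r: float(np.mean(v)) for r, v in per_ratio.items()},
        "selected_sizes": sizes,
        "rho": float(rho),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# planted-subset recovery experiment
# ---------------------------------------------------------------------------

def recovery_experiment(n_runs: int = 20, seed: int = 0,
                        n_informative: int = 5, n_noise: int = 45,
                        separation: float = 3.0,
                        n_repeats: int = 20,
                        config: GAConfig | None = None,
                        strategy_code: str = "FS_VU",
                        min_recovered: int = 4) -> dict:
    """Can the GA find a planted informative subset among noise columns?

    Each run draws a fresh 51:275 Gaussian table with ``n_informative``
    informative and ``n_noise`` noise columns, evolves a mask under the
    scaled configuration (population 40, 60 generations unless overridden)
    and counts how many informative columns the best mask retains. A run
    succeeds when at least ``min_recovered`` are recovered.
    """
    from .synthetic import informative_indices

    if config is None:
        config = GAConfig(population_size=40, generations=60,
                          stall_generations=150)
    recovered, selected_sizes = [], []
    for r in range(n_runs):
        s_table, s_scheme, s_ga = (
            int(s % 2**31)
            for s in np.random.SeedSequence((seed, r)).generate_state(3))
        table = generate_feature_table(TableSpec(
            n_minority=51, n_majority=275, n_informative=n_informative,
            n_noise=n_noise, separation=separation, seed=s_table))
        scheme = build_scheme(table.labels, n_repeats=n_repeats, seed=s_scheme)
        cfg = replace(config, seed=s_ga, genome_length=table.n_features)
        best = evolve(table, scheme, FSStrategy.from_code(strategy_code), cfg)
        inf = informative_indices(table)
        recovered.append(int(best.mask[inf].sum()))
        selected_sizes.append(best.n_selected)
    successes = sum(k >= min_recovered for k in recovered)
    return {"recovered": recovered, "selected_sizes": selected_sizes,
            "successes": successes, "n_runs": n_runs,
            "success_rate": successes / n_runs}


# ---------------------------------------------------------------------------
# leakage demonstration
# ---------------------------------------------------------------------------

def _split_two(labels: np.ndarray, test_frac: float,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    tr, te = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        n_test = max(1, round(test_frac * idx.size))
        te.append(idx[:n_test])
        tr.append(idx[n_test:])
    return np.sort(np.concatenate(tr)), np.sort(np.concatenate(te))


def leakage_demo(table_spec: TableSpec, n_repeats: int = 50, seed: int = 0,
                 test_frac: float = 0.2) -> dict:
    """Paired contrast of SMOTE before vs after the train/test split.

    Arm A balances the whole table first and then splits, so synthetic
    minority rows interpolated from the same originals land on both sides
    of the split; arm B splits first and balances only the training side.
    Returns per-repeat test AUCs of both arms and the one-sided paired
    t-test p-value for mean AUC(A) > mean AUC(B).
    """
    table = generate_feature_table(table_spec)
    spec = ResamplingSpec(method="smote", target_ratio=1.0)
    auc_before, auc_after = [], []
    for i in range(n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))

        # arm A: resample the full table, then split the augmented table
        Xs_full, _, _ = standardize(table.X, np.arange(table.X.shape[0]))
        Xa, ya = resample(Xs_full, table.labels, spec, rng=rng)
        tr, te = _split_two(ya, test_frac, rng)
        model = lda_fit(Xa[tr], ya[tr])
        auc_before.append(auc(lda_posterior(model, Xa[te]), ya[te]))

        # arm B: split the original table, resample the training side only
        tr, te = _split_two(table.labels, test_frac, rng)
        Xs, _, _ = standardize(table.X, tr)
        Xb, yb = resample(Xs[tr], table.labels[tr], spec, rng=rng)
        model = lda_fit(Xb, yb)
        auc_after.append(auc(lda_posterior(model, Xs[te]), table.labels[te]))

    a = np.array(auc_before)
    b = np.array(auc_after)
    t, p = stats.ttest_rel(a, b, alternative="greater")
    return {"auc_before_split": a, "auc_after_split": b,
            "mean_difference": float(a.mean() - b.mean()),
            "t": float(t), "p": float(p)}
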