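"""Self-contained benchmark experiments for the selection pipeline.

Every experiment regenerates its inputs from a seed and recomputes its
quantity from scratch, so the same functions back both the test suite and
the reproduction script.  Problem sizes are chosen so the whole battery
runs on a single core in minutes; swarm budgets are therefore smaller than
the library defaults.
"""

from __future__ import annotations

import itertools

import numpy as np
from sklearn.svm import SVC

from .features import Standardizer, extract_features, zscore_normalize
from .mrmr import mrmr_rank
from .pipeline import PipelineConfig, _split_indices, mrmr_pso_svm
from .pso import SwarmConfig, _make_folds, fitness, run_pso
from .synthetic import (
    PlantedTableSpec,
    SyntheticSpec,
    generate_eeg,
    generate_table,
    signal_recovery,
)

__all__ = [
    "extracted_feature_count",
    "mrmr_oracle_agreement",
    "pso_exhaustive_gap",
    "recovery_experiment",
    "null_experiment",
]

#: Swarm budget used by the simulation experiments below.
SIM_SWARM = dict(n_particles=20, n_generations=40, patience=12)


def extracted_feature_count(n_channels: int, seed: int = 0) -> int:
    """Fused dimensionality measured by actually extracting features from a
    freshly generated recording with ``n_channels`` channels."""
    epochs = generate_eeg(
        SyntheticSpec(
            n_channels=n_channels, fs=128.0, window_s=3.0,
            n_epochs_per_class=1, coupling_pairs=(), seed=seed,
        )
    )
    return extract_features(epochs).n_features


def _brute_force_fcq_order(X: np.ndarray, y: np.ndarray, k: int) -> list[int]:
    """Direct per-step evaluation of the F-test correlation quotient."""
    from .mrmr import _f_statistics

    F = _f_statistics(X, y)
    R = np.abs(np.nan_to_num(np.corrcoef(X, rowvar=False)))
    order = [int(np.argmax(F))]
    while len(order) < k:
        best, best_v = None, -np.inf
        for c in range(X.shape[1]):
            if c in order:
                continue
            v = F[c] / max(np.mean([R[c, j] for j in order]), 1e-12)
            if v > best_v:
                best, best_v = c, v
        order.append(best)
    return order


def mrmr_oracle_agreement(n_tables: int = 50, seed: int = 0) -> float:
    """Fraction of greedy mRMR picks that match exhaustive per-step
    evaluation, over ``n_tables`` random small tables (m <= 10)."""
    matches = total = 0
    for s in range(n_tables):
        rng = np.random.default_rng(seed * 1009 + s)
        m = int(rng.integers(4, 11))
        n = 60
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        X = rng.standard_normal((n, m))
        X[:, : max(1, m // 4)] += (y - 0.5)[:, None]
        from .features import FeatureTable

        ranking = mrmr_rank(FeatureTable(X, [f"f{i}" for i in range(m)], y), pool_size=m)
        oracle = _brute_force_fcq_order(X, y, m)
        matches += sum(int(a == b) for a, b in zip(ranking.order, oracle))
        total += m
    return matches / total


def pso_exhaustive_gap(
    n_tables: int = 3, pool_size: int = 10, seed: int = 0
) -> float:
    """Worst-case percent gap between the swarm optimum and exhaustive
    enumeration of all 2^pool masks at fixed (C, gamma)."""
    from .features import FeatureTable

    worst = 0.0
    for s in range(n_tables):
        table, _ = generate_table(
            PlantedTableSpec(
                n_rows=80, n_informative=3, n_redundant=0, n_noise=pool_size - 1,
                effect_size=1.2, seed=seed * 777 + s,
            )
        )
        table, _ = zscore_normalize(table)
        ranking = mrmr_rank(table, pool_size=pool_size)
        cfg = SwarmConfig(
            n_particles=30, n_generations=60, patience=25,
            optimize_hyperparams=False, fixed_C=1.0, fixed_gamma=0.125,
            seed=seed * 31 + s,
        )
        res = run_pso(table, ranking, cfg)

        pool = ranking.order[:pool_size]
        pool_table = FeatureTable(
            table.X[:, pool], [table.feature_names[i] for i in pool], table.y
        )
        folds = _make_folds(table.y, cfg.n_folds, cfg.seed)
        best = 0.0
        for bits in itertools.product([0, 1], repeat=pool_size):
            mask = np.array(bits, bool)
            if not mask.any():
                continue
            best = max(best, fitness(mask, 1.0, 0.125, pool_table, cfg, folds))
        worst = max(worst, 100.0 * (best - res.fitness) / best)
    return worst


def _baseline_accuracy(table, split_seed: int, train_fraction: float = 0.8) -> float:
    """Held-out accuracy of an RBF-SVM on *all* features (C=1, gamma=scale),
    with z-scoring fitted on the same training partition."""
    tr, te = _split_indices(table.y, train_fraction, split_seed)
    std = Standardizer().fit(table.subset_rows(tr))
    trn = std.transform(table.subset_rows(tr))
    ten = std.transform(table.subset_rows(te))
    clf = SVC(kernel="rbf", C=1.0, gamma="scale").fit(trn.X, trn.y)
    return float((clf.predict(ten.X) == ten.y).mean())


def recovery_experiment(n_runs: int = 20, seed: int = 0) -> dict:
    """Planted-signal benchmark: 5 informative, 20 redundant copies, 75
    noise columns, n = 400.  For each run the full pipeline is compared
    head-to-head with an all-features SVM on the same split."""
    recoveries = wins = 0
    sel_fracs, accs = [], []
    for s in range(n_runs):
        table, truth = generate_table(PlantedTableSpec(seed=seed * 10_007 + s))
        cfg = PipelineConfig(swarm=SwarmConfig(**SIM_SWARM), seed=seed * 613 + s)
        res = mrmr_pso_svm(table, cfg)
        _, n_groups = signal_recovery(res.mask, truth)
        recoveries += n_groups >= 4

        ss = np.random.SeedSequence(cfg.seed)
        split_seed = int(ss.generate_state(2)[0]) % 2**31
        wins += res.metrics.accuracy >= _baseline_accuracy(table, split_seed)
        sel_fracs.append(res.selected_count / table.n_features)
        accs.append(res.metrics.accuracy)
    return {
        "n_runs": n_runs,
        "recovery_rate": recoveries / n_runs,
        "accuracy_win_rate": wins / n_runs,
        "mean_selected_fraction": float(np.mean(sel_fracs)),
        "mean_accuracy": float(np.mean(accs)),
    }


def null_experiment(n_runs: int = 8, seed: int = 0) -> dict:
    """Zero-signal tables: held-out accuracy must stay at chance (leakage
    guard).  Returns the pooled accuracy and its 3-sigma Monte-Carlo band."""
    accs, n_test = [], 0
    for s in range(n_runs):
        table, _ = generate_table(
            PlantedTableSpec(
                n_rows=200, n_informative=0, n_redundant=0, n_noise=30,
                effect_size=0.0, seed=seed * 4099 + s,
            )
        )
        cfg = PipelineConfig(
            swarm=SwarmConfig(n_particles=12, n_generations=15, patience=6),
            seed=seed * 211 + s,
        )
        res = mrmr_pso_svm(table, cfg)
        accs.append(res.metrics.accuracy)
        n_test += res.metrics.total
    mean = float(np.mean(accs))
    # binomial SE of the pooled test predictions at p = 0.5
    se = float(np.sqrt(0.25 / n_test))
    return {"n_runs": n_runs, "mean_accuracy": mean, "mc_se": se, "n_test": n_test}
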