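"""Binary particle swarm optimization over a feature mask + SVM hyperparameters.

Each particle lives in a mixed space of dimension ``pool_size + 2``: one
latent coordinate per pooled feature (binarized stochastically through a
sigmoid transfer function of the velocity) and two continuous coordinates,
``log2 C`` and ``log2 gamma``, for the RBF-SVM trained on the masked
columns.  Fitness is the mean F-measure of the stress class under
stratified K-fold cross-validation on the training partition.

Velocity and position follow the canonical update

    V' = w V + c1 r1 (pbest - X) + c2 r2 (gbest - X),  X' = X + V'

with the velocity clamped to ``±v_max``.  The inertia weight ``w`` is, by
default, data-adaptive: the mean mutual information between each pooled
feature (10 equal-frequency bins) and the class label, clipped to
[0.4, 0.9].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import f1_score, mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, DegenerateLabelsError
from .features import FeatureTable
from .mrmr import MRMRRanking

__all__ = [
    "SwarmConfig",
    "Particle",
    "SelectionResult",
    "initialize_swarm",
    "update_velocity",
    "update_position",
    "fitness",
    "run_pso",
    "adaptive_inertia",
]


@dataclass
class SwarmConfig:
    """Tunable swarm parameters.

    Defaults follow the standard large-budget setting for this optimizer
    (50 particles, 200 generations, c1 = c2 = 2); simulations in the test
    suite use smaller, explicitly passed budgets.
    """

    n_particles: int = 50
    n_generations: int = 200
    c1: float = 2.0
    c2: float = 2.0
    w: float | None = None  # None -> data-adaptive mutual-information inertia
    v_max: float = 6.0
    c_range: tuple[float, float] = (-5.0, 15.0)  # log2 C
    gamma_range: tuple[float, float] = (-15.0, 3.0)  # log2 gamma
    optimize_hyperparams: bool = True
    fixed_C: float = 1.0
    fixed_gamma: float = 0.125
    n_folds: int = 3
    patience: int = 30
    tol: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_particles < 2:
            problems.append(f"n_particles must be >= 2, got {self.n_particles}")
        if self.n_generations < 1:
            problems.append(f"n_generations must be >= 1, got {self.n_generations}")
        if self.c1 <= 0 or self.c2 <= 0:
            problems.append(f"c1, c2 must be > 0, got ({self.c1}, {self.c2})")
        if self.w is not None and not 0.0 < self.w < 1.5:
            problems.append(f"w must lie in (0, 1.5), got {self.w}")
        if self.v_max <= 0:
            problems.append(f"v_max must be > 0, got {self.v_max}")
        for name, rng in (("c_range", self.c_range), ("gamma_range", self.gamma_range)):
            if rng[0] >= rng[1]:
                problems.append(f"{name} must be non-empty, got {rng}")
        if self.n_folds < 2:
            problems.append(f"n_folds must be >= 2, got {self.n_folds}")
        if problems:
            raise ConfigError("; ".join(problems))


@dataclass
class Particle:
    """One candidate solution: latent position, velocity, realized mask, pbest."""

    position: np.ndarray
    velocity: np.ndarray
    mask: np.ndarray  # realized bits for the mask dimensions
    pbest_position: np.ndarray
    pbest_mask: np.ndarray
    pbest_fitness: float


@dataclass
class SelectionResult:
    """Outcome of a swarm run (optionally with held-out metrics attached)."""

    mask: np.ndarray  # boolean over the *original* m features
    C: float
    gamma: float
    fitness_history: list[float]
    pool_indices: np.ndarray
    w: float
    metrics: "object | None" = None  # pipeline.Metrics, attached downstream
    ranking: MRMRRanking | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.selected_count < 1:
            raise ValueError("a selection result must keep at least one feature")
        hist = np.asarray(self.fitness_history, dtype=float)
        if np.any(np.diff(hist) < 0):
            raise ValueError("gbest fitness history must be non-decreasing")

    @property
    def selected_count(self) -> int:
        return int(self.mask.sum())

    @property
    def fitness(self) -> float:
        return float(self.fitness_history[-1])


def _sigmoid(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def adaptive_inertia(X_pool: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Mean mutual information (nats) between binned features and the label,
    clipped to the stable inertia range [0.4, 0.9]."""
    mis = []
    for j in range(X_pool.shape[1]):
        col = X_pool[:, j]
        edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
        binned = np.digitize(col, np.unique(edges))
        mis.append(mutual_info_score(binned, y))
    return float(np.clip(np.mean(mis), 0.4, 0.9))


def initialize_swarm(
    config: SwarmConfig, dimension: int, rng: np.random.Generator | None = None
) -> list[Particle]:
    """Seed-reproducible swarm: mask latents uniform in [0, 1], hyperparameter
    coordinates uniform in their log2 ranges, velocities uniform in ±v_max.

    Initial mask bits are realized with probability equal to the latent
    coordinate (so ~half the pool starts selected)."""
    config.validate()
    if dimension < 3:
        raise ConfigError(f"search dimension must be >= 3, got {dimension}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_mask = dimension - 2 if config.optimize_hyperparams else dimension
    swarm = []
    for _ in range(config.n_particles):
        pos = np.empty(dimension)
        pos[:n_mask] = rng.uniform(0.0, 1.0, n_mask)
        if config.optimize_hyperparams:
            pos[n_mask] = rng.uniform(*config.c_range)
            pos[n_mask + 1] = rng.uniform(*config.gamma_range)
        vel = rng.uniform(-config.v_max, config.v_max, dimension)
        mask = rng.random(n_mask) < pos[:n_mask]
        swarm.append(
            Particle(
                position=pos,
                velocity=vel,
                mask=mask,
                pbest_position=pos.copy(),
                pbest_mask=mask.copy(),
                pbest_fitness=-np.inf,
            )
        )
    return swarm


def update_velocity(
    p: Particle,
    gbest_position: np.ndarray,
    config: SwarmConfig,
    r1: float,
    r2: float,
) -> np.ndarray:
    """Canonical velocity update, clamped to ±v_max."""
    gbest_position = np.asarray(gbest_position, dtype=float)
    if gbest_position.shape != p.position.shape:
        raise ValueError("gbest/position dimension mismatch")
    v = (
        (config.w if config.w is not None else 1.0) * p.velocity
        + config.c1 * r1 * (p.pbest_position - p.position)
        + config.c2 * r2 * (gbest_position - p.position)
    )
    return np.clip(v, -config.v_max, config.v_max)


def update_position(
    p: Particle, config: SwarmConfig, r: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Move the particle along its (already updated) velocity.

    Continuous hyperparameter coordinates are clamped to their ranges; the
    mask latents are clamped to [0, 1] and the realized bit of mask
    dimension d is 1 iff ``r[d] < sigmoid(velocity[d])`` (sigmoid transfer
    binarization).  Returns ``(new_position, new_mask_bits)``.
    """
    n_mask = p.mask.size
    pos = p.position + p.velocity
    pos[:n_mask] = np.clip(pos[:n_mask], 0.0, 1.0)
    if config.optimize_hyperparams:
        pos[n_mask] = np.clip(pos[n_mask], *config.c_range)
        pos[n_mask + 1] = np.clip(pos[n_mask + 1], *config.gamma_range)
    bits = np.asarray(r)[:n_mask] < _sigmoid(p.velocity[:n_mask])
    return pos, bits


def _make_folds(y: np.ndarray, n_folds: int, seed: int):
    """Stratified CV folds, resampled once if a training fold is single-class."""
    for attempt in range(2):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed + attempt) % 2**31)
        folds = list(skf.split(np.zeros_like(y), y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in folds):
            return folds
    return None  # degenerate: callers score fitness 0


def fitness(
    mask: np.ndarray,
    C: float,
    gamma: float,
    train_table: FeatureTable,
    config: SwarmConfig,
    folds=None,
) -> float:
    """Mean stress-class F-measure of an RBF-SVM on the masked columns under
    stratified K-fold CV.  An empty mask scores 0 without training."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        return 0.0
    if train_table.y is None:
        raise DegenerateLabelsError("fitness needs a labeled table")
    if folds is None:
        folds = _make_folds(train_table.y, config.n_folds, config.seed)
    if folds is None:
        return 0.0
    X = train_table.X[:, mask]
    y = train_table.y
    scores = []
    for tr, te in folds:
        clf = SVC(kernel="rbf", C=C, gamma=gamma)
        clf.fit(X[tr], y[tr])
        scores.append(f1_score(y[te], clf.predict(X[te]), pos_label=1, zero_division=0))
    return float(np.mean(scores))


def _decode_hyperparams(position: np.ndarray, n_mask: int, config: SwarmConfig):
    if config.optimize_hyperparams:
        return 2.0 ** position[n_mask], 2.0 ** position[n_mask + 1]
    return config.fixed_C, config.fixed_gamma


def run_pso(
    table: FeatureTable,
    ranking: MRMRRanking,
    config: SwarmConfig,
) -> SelectionResult:
    """Optimize the feature mask (within the mRMR pool) and, optionally, the
    SVM hyperparameters, maximizing cross-validated F-measure.

    The returned mask is lifted from pool coordinates back to the original
    feature indices.  The gbest fitness trace is monotone non-decreasing;
    the run stops after ``n_generations`` or once the trace improves by less
    than ``tol`` for ``patience`` consecutive generations.
    """
    config.validate()
    if table.y is None:
        raise DegenerateLabelsError("run_pso needs a labeled table")
    pool = ranking.order[: ranking.pool_size]
    n_mask = pool.size
    dimension = n_mask + 2 if config.optimize_hyperparams else n_mask
    if dimension < 3:
        raise ConfigError("search dimension must be >= 3")

    pool_table = FeatureTable(
        table.X[:, pool], [table.feature_names[i] for i in pool], table.y
    )
    rng = np.random.default_rng(config.seed)
    w = config.w if config.w is not None else adaptive_inertia(pool_table.X, table.y)
    run_cfg = SwarmConfig(**{**config.__dict__, "w": w})
    folds = _make_folds(table.y, config.n_folds, config.seed)

    swarm = initialize_swarm(run_cfg, dimension, rng)
    gbest_position = None
    gbest_mask = None
    gbest_fit = -np.inf
    for p in swarm:
        C, gamma = _decode_hyperparams(p.position, n_mask, run_cfg)
        fit = fitness(p.mask, C, gamma, pool_table, run_cfg, folds)
        p.pbest_fitness = fit
        if fit > gbest_fit:
            gbest_fit = fit
            gbest_position = p.position.copy()
            gbest_mask = p.mask.copy()
    history = [gbest_fit]

    stall = 0
    for _gen in range(1, run_cfg.n_generations):
        for p in swarm:
            r1, r2 = rng.random(2)
            p.velocity = update_velocity(p, gbest_position, run_cfg, r1, r2)
            p.position, p.mask = update_position(p, run_cfg, rng.random(n_mask))
            C, gamma = _decode_hyperparams(p.position, n_mask, run_cfg)
            fit = fitness(p.mask, C, gamma, pool_table, run_cfg, folds)
            if fit > p.pbest_fitness:
                p.pbest_fitness = fit
                p.pbest_position = p.position.copy()
                p.pbest_mask = p.mask.copy()
            if fit > gbest_fit:
                gbest_fit = fit
                gbest_position = p.position.copy()
                gbest_mask = p.mask.copy()
        improvement = gbest_fit - history[-1]
        history.append(gbest_fit)
        stall = stall + 1 if improvement <= run_cfg.tol else 0
        if stall >= run_cfg.patience:
            break

    if gbest_mask.sum() == 0:
        # Degenerate swarm: fall back to the single top-ranked feature.
        gbest_mask = np.zeros(n_mask, dtype=bool)
        gbest_mask[0] = True
    full_mask = np.zeros(table.n_features, dtype=bool)
    full_mask[pool[gbest_mask]] = True
    C, gamma = _decode_hyperparams(gbest_position, n_mask, run_cfg)
    return SelectionResult(
        mask=full_mask,
        C=float(C),
        gamma=float(gamma),
        fitness_history=[float(h) for h in history],
        pool_indices=pool.copy(),
        w=float(w),
        ranking=ranking,
    )
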