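"""Intelligent Water Drops (IWD) wrapper feature selection.

Drops traverse a fully connected graph whose nodes are feature columns (plus
a virtual start node). Each edge carries "soil"; drops preferentially follow
low-soil edges, gain velocity on each move, and erode soil from the edges
they traverse — fast moves over low-undesirability edges erode more. After
every iteration the soils along the iteration-best tour (by wrapper fitness)
are reinforced globally, so good feature subsets become progressively more
probable while an elitist archive keeps the best subset ever seen.

Dynamics per move from node i to feature j:

    vel ← vel + a_v / (b_v + c_v · soil(i,j)²)
    time(i,j)  = HUD(j) / vel
    Δsoil      = a_s / (b_s + c_s · time(i,j)²)
    soil(i,j) ← (1 − ρ_n) · soil(i,j) − ρ_n · Δsoil        (local update)

and per iteration, along the iteration-best tour:

    soil(i,j) ← (1 + ρ_iwd) · soil(i,j) − ρ_iwd · carried_soil / (m − 1)

HUD (heuristic undesirability) of a feature is one minus its normalized
absolute point-biserial association with the class label, so label-informative
features are "easy riverbed". Transition probabilities depend only on soil:
p(j) ∝ 1 / (ε + g(soil(i,j))) where g shifts soils so the minimum over the
candidate edges is never negative.

The wrapper fitness of a subset is the pooled stratified k-fold accuracy of a
nearest-centroid classifier restricted to the subset's columns, minus an
optional subset-size penalty. Fitness is deterministic given the seed and is
memoized across tours.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .vectorize import FeatureMatrix

__all__ = [
    "IWDParams",
    "IWDState",
    "Drop",
    "FeatureSubset",
    "FitnessConfig",
    "init_state",
    "transition_probabilities",
    "update_velocity",
    "soil_delta",
    "local_soil_update",
    "global_soil_update",
    "construct_solution",
    "fitness",
    "hud_scores",
    "select_features",
    "run_iwd",
]


@dataclass(frozen=True)
class IWDParams:
    """Static constants and run budget of the IWD search.

    ``a/b/c`` triples parameterize the velocity (``_v``) and soil (``_s``)
    updates; ``rho_n`` / ``rho_iwd`` are the local and global soil-update
    rates. Defaults are scale-consistent with heuristic-undesirability values
    in [0, 1] and near-unit initial soils, which keeps transition
    probabilities smooth early (exploration) while repeated reinforcement
    progressively sharpens them (exploitation).
    """

    a_v: float = 1.0
    b_v: float = 1.0
    c_v: float = 1.0
    a_s: float = 1.0
    b_s: float = 1.0
    c_s: float = 1.0
    rho_n: float = 0.1
    rho_iwd: float = 0.1
    init_soil: float = 1.0
    init_vel: float = 1.0
    epsilon_p: float = 1.0
    n_drops: int = 10
    n_iterations: int = 100
    subset_size: int | None = None  # None → max(5, round(0.1 · n_features))
    lambda_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.b_v <= 0 or self.b_s <= 0:
            raise ValueError("b_v and b_s must be positive")
        if self.epsilon_p <= 0:
            raise ValueError("epsilon_p must be positive")
        if not (0.0 < self.rho_n < 1.0):
            raise ValueError("rho_n must be in (0, 1)")
        if not (0.0 < self.rho_iwd < 1.0):
            raise ValueError("rho_iwd must be in (0, 1)")
        if self.subset_size is not None and self.subset_size < 1:
            raise ValueError("subset_size must be >= 1")
        if self.n_drops < 1:
            raise ValueError("n_drops must be >= 1")

    def resolve_subset_size(self, n_features: int) -> int:
        m = self.subset_size
        if m is None:
            m = max(5, int(round(0.1 * n_features)))
            m = min(m, n_features)
        if m > n_features:
            raise ValueError(f"subset_size {m} exceeds feature count {n_features}")
        return m


@dataclass(frozen=True)
class FeatureSubset:
    """Sorted distinct feature columns plus the wrapper fitness (if scored)."""

    indices: tuple[int, ...]
    fitness: float | None = None

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(set(idx)) != len(idx):
            raise ValueError("subset indices must be distinct")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class Drop:
    """One water drop: its tour so far, velocity, and eroded soil carried."""

    visited: list[int] = field(default_factory=list)
    velocity: float = 1.0
    carried_soil: float = 0.0


@dataclass
class IWDState:
    """Soil table over feature nodes + virtual start node, and the archive."""

    soil: np.ndarray  # (n+1, n+1) symmetric; node n is the start node
    n_features: int
    best_subset: FeatureSubset | None = None
    iteration: int = 0

    @property
    def start_node(self) -> int:
        return self.n_features


def init_state(n_features: int, params: IWDParams) -> IWDState:
    """Fresh state: every edge (including start-node edges) at ``init_soil``."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    m = params.resolve_subset_size(n_features)
    if n_features < m:
        raise ValueError("n_features must be >= subset_size")
    soil = np.full((n_features + 1, n_features + 1), float(params.init_soil))
    np.fill_diagonal(soil, 0.0)
    return IWDState(soil=soil, n_features=n_features)


def transition_probabilities(
    drop: Drop,
    current_node: int,
    state: IWDState,
    params: IWDParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Probability of moving to each unvisited feature from ``current_node``.

    Returns ``(candidates, probabilities)``. p(j) ∝ 1/(ε + g(soil)) with g
    shifting by the (negative part of the) minimum candidate soil, so lower
    soil means higher probability and negative soils are handled.
    """
    visited = set(drop.visited)
    candidates = np.array(
        [j for j in range(state.n_features) if j not in visited], dtype=np.int64
    )
    if candidates.size == 0:
        raise ValueError("no unvisited features to move to")
    soils = state.soil[current_node, candidates]
    g = soils - min(0.0, float(soils.min()))
    f = 1.0 / (params.epsilon_p + g)
    return candidates, f / f.sum()


def update_velocity(drop: Drop, soil_edge: float, params: IWDParams) -> float:
    """vel(t+1) = vel(t) + a_v / (b_v + c_v · soil²); increasing for a_v > 0."""
    return drop.velocity + params.a_v / (params.b_v + params.c_v * soil_edge * soil_edge)


def soil_delta(drop: Drop, heuristic_undesirability: float, params: IWDParams) -> float:
    """Soil eroded on a move: a_s / (b_s + c_s · (HUD/vel)²).

    Faster drops and more desirable (lower-HUD) edges erode more soil.
    """
    if drop.velocity <= 0:
        raise ValueError("drop velocity must be positive")
    t = heuristic_undesirability / drop.velocity
    return params.a_s / (params.b_s + params.c_s * t * t)


def local_soil_update(
    state: IWDState,
    edge: tuple[int, int],
    delta_soil: float,
    params: IWDParams,
    drop: Drop | None = None,
) -> None:
    """Erode one edge: soil ← (1 − ρ_n)·soil − ρ_n·Δ; the drop carries Δ."""
    i, j = edge
    new = (1.0 - params.rho_n) * state.soil[i, j] - params.rho_n * delta_soil
    state.soil[i, j] = new
    state.soil[j, i] = new
    if drop is not None:
        drop.carried_soil += delta_soil


def _run_drop(
    state: IWDState,
    params: IWDParams,
    rng: np.random.Generator,
    hud: np.ndarray,
    m: int,
) -> Drop:
    drop = Drop(velocity=float(params.init_vel))
    current = state.start_node
    for _ in range(m):
        candidates, probs = transition_probabilities(drop, current, state, params)
        j = int(rng.choice(candidates, p=probs))
        drop.velocity = update_velocity(drop, float(state.soil[current, j]), params)
        delta = soil_delta(drop, float(hud[j]), params)
        local_soil_update(state, (current, j), delta, params, drop)
        drop.visited.append(j)
        current = j
    return drop


def construct_solution(
    state: IWDState,
    params: IWDParams,
    rng: np.random.Generator,
    hud: np.ndarray | None = None,
) -> FeatureSubset:
    """One drop's tour of ``m`` probabilistic moves from the start node.

    Local soil updates are applied as the drop moves (state is mutated).
    """
    m = params.resolve_subset_size(state.n_features)
    if hud is None:
        hud = np.ones(state.n_features)
    drop = _run_drop(state, params, rng, np.asarray(hud, dtype=np.float64), m)
    return FeatureSubset(indices=tuple(drop.visited))


@dataclass(frozen=True)
class FitnessConfig:
    """Wrapper-fitness settings: inner CV folds and size penalty."""

    k_folds: int = 3
    lambda_penalty: float = 0.0
    seed: int = 0


def _stratified_folds(
    labels: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment per row: within-class shuffle, then round-robin."""
    fold = np.empty(labels.shape[0], dtype=np.int64)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def _nearest_centroid_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    n_classes: int,
) -> np.ndarray:
    """Euclidean nearest-centroid; absent classes are never predicted; ties
    break toward the lowest class index (argmin picks the first minimum)."""
    present = np.unique(y_train)
    centroids = np.vstack([X_train[y_train == c].mean(axis=0) for c in present])
    d2 = ((X_test[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return present[np.argmin(d2, axis=1)]


def fitness(
    subset: FeatureSubset,
    matrix: FeatureMatrix,
    eval_config: FitnessConfig | None = None,
) -> float:
    """Pooled stratified k-fold nearest-centroid accuracy minus size penalty.

    Deterministic given ``eval_config.seed``; all-zero columns are handled
    (centroid ties resolve to the lowest class index).
    """
    if eval_config is None:
        eval_config = FitnessConfig()
    if len(subset) == 0:
        raise ValueError("fitness requires a non-empty subset")
    X = matrix.values[:, list(subset.indices)]
    y = matrix.labels
    rng = np.random.default_rng(eval_config.seed)
    k = min(eval_config.k_folds, matrix.n_docs)
    folds = _stratified_folds(y, k, rng)
    correct = 0
    for f in range(k):
        test_mask = folds == f
        if not test_mask.any() or test_mask.all():
            continue
        pred = _nearest_centroid_predict(
            X[~test_mask], y[~test_mask], X[test_mask], matrix.n_classes
        )
        correct += int((pred == y[test_mask]).sum())
    accuracy = correct / matrix.n_docs
    penalty = eval_config.lambda_penalty * len(subset) / matrix.n_features
    return accuracy - penalty


def global_soil_update(
    state: IWDState,
    best_drop: Drop,
    best_subset: FeatureSubset,
    params: IWDParams,
) -> None:
    """Reinforce the iteration-best tour and maintain the elitist archive.

    Every edge on the tour gets soil ← (1 + ρ_iwd)·soil − ρ_iwd·carried/(m−1)
    (divisor guarded at 1 for m = 1); the best-so-far subset is replaced only
    on a strict fitness improvement, so ties keep the incumbent.
    """
    if best_subset.fitness is None:
        raise ValueError("iteration-best subset must carry a fitness")
    m = len(best_drop.visited)
    divisor = max(m - 1, 1)
    share = best_drop.carried_soil / divisor
    path = [state.start_node] + best_drop.visited
    for i, j in zip(path, path[1:]):
        new = (1.0 + params.rho_iwd) * state.soil[i, j] - params.rho_iwd * share
        state.soil[i, j] = new
        state.soil[j, i] = new
    if state.best_subset is None or (
        state.best_subset.fitness is not None
        and best_subset.fitness > state.best_subset.fitness
    ):
        state.best_subset = best_subset


def hud_scores(matrix: FeatureMatrix) -> np.ndarray:
    """Per-feature heuristic undesirability in [0, 1].

    1 − normalized max-over-classes absolute point-biserial correlation
    between the feature column and the one-vs-rest class indicator; the most
    label-associated feature has HUD 0. Zero-variance columns score 0
    association (HUD 1).
    """
    X = matrix.values
    y = matrix.labels
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    x_sd = X.std(axis=0)
    best = np.zeros(X.shape[1])
    for c in range(matrix.n_classes):
        ind = (y == c).astype(np.float64)
        ic = ind - ind.mean()
        i_sd = ind.std()
        if i_sd == 0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ ic) / (n * x_sd * i_sd)
        r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
        best = np.maximum(best, np.abs(r))
    top = best.max()
    if top <= 0:
        return np.ones(X.shape[1])
    return 1.0 - best / top


def run_iwd(
    matrix: FeatureMatrix,
    params: IWDParams,
    fitness_fn: Callable[[FeatureSubset], float] | None = None,
) -> tuple[FeatureSubset, list[dict], IWDState]:
    """Full IWD search; returns (best subset, per-iteration trace, state).

    ``fitness_fn`` overrides the default wrapper fitness (used, e.g., with a
    BPNN-in-the-loop wrapper or a deterministic benchmark landscape); it must
    be deterministic for the memoization to be sound.
    """
    if params.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1 (no solution constructed otherwise)")
    n_features = matrix.n_features
    m = params.resolve_subset_size(n_features)
    state = init_state(n_features, params)
    rng = np.random.default_rng(params.seed)
    hud = hud_scores(matrix)
    if fitness_fn is None:
        cfg = FitnessConfig(lambda_penalty=params.lambda_penalty, seed=params.seed)

        def fitness_fn(subset: FeatureSubset) -> float:
            return fitness(subset, matrix, cfg)

    cache: dict[tuple[int, ...], float] = {}
    trace: list[dict] = []
    for it in range(params.n_iterations):
        state.iteration = it
        best_drop: Drop | None = None
        best_sub: FeatureSubset | None = None
        for _ in range(params.n_drops):
            drop = _run_drop(state, params, rng, hud, m)
            key = tuple(sorted(drop.visited))
            fit = cache.get(key)
            if fit is None:
                fit = fitness_fn(FeatureSubset(indices=key))
                cache[key] = fit
            if best_sub is None or fit > best_sub.fitness:  # type: ignore[operator]
                best_sub = FeatureSubset(indices=key, fitness=fit)
                best_drop = drop
        assert best_drop is not None and best_sub is not None
        global_soil_update(state, best_drop, best_sub, params)
        trace.append(
            {
                "iteration": it,
                "iteration_best_fitness": best_sub.fitness,
                "best_fitness": state.best_subset.fitness,  # type: ignore[union-attr]
            }
        )
    assert state.best_subset is not None
    return state.best_subset, trace, state


def select_features(matrix: FeatureMatrix, params: IWDParams) -> FeatureSubset:
    """Run the IWD search and return the best feature subset found."""
    best, _, _ = run_iwd(matrix, params)
    return best
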