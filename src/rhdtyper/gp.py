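"""Symbolic classification by genetic programming with offspring selection.

Trees are one-vs-rest discriminants over the feature vector; an offspring is
accepted into the next generation only when its fitness beats a
comparison-factor-weighted blend of its parents' fitnesses.  Prediction is
the argmax of the per-class tree outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["GPConfig", "GPClassifier", "evolve_gp_classifier"]

log = logging.getLogger(__name__)

# node encodings: ("f", index) feature, ("c", value) constant,
# (op_name, left, right) binary operator
_BINARY_OPS = ("add", "sub", "mul", "div")


def _apply(op: str, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if op == "add":
        return a + b
    if op == "sub":
        return a - b
    if op == "mul":
        return a * b
    # protected division
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(b) < 1e-9, 1.0, a / b)
    return out


def eval_tree(node: tuple, X: np.ndarray) -> np.ndarray:
    kind = node[0]
    if kind == "f":
        return X[:, node[1]]
    if kind == "c":
        return np.full(X.shape[0], node[1], dtype=float)
    return _apply(kind, eval_tree(node[1], X), eval_tree(node[2], X))


def tree_depth(node: tuple) -> int:
    if node[0] in ("f", "c"):
        return 1
    return 1 + max(tree_depth(node[1]), tree_depth(node[2]))


def _linear_scaling(out: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, intercept) mapping tree output onto the target."""
    var = float(out.var())
    if var < 1e-12:
        return 0.0, float(target.mean())
    a = float(np.cov(out, target, bias=True)[0, 1] / var)
    return a, float(target.mean() - a * out.mean())


@dataclass
class GPConfig:
    population_size: int = 100
    max_tree_depth: int = 7
    max_generations: int = 50
    success_ratio: float = 1.0
    comparison_factor: float = 1.0
    tournament_size: int = 3
    mutation_prob: float = 0.15
    constant_range: float = 3.0
    max_selection_pressure: float = 10.0

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")
        if self.max_tree_depth < 2:
            raise ValueError("max_tree_depth must be >= 2")


class _Evolver:
    def __init__(self, cfg: GPConfig, n_features: int, rng: np.random.Generator):
        self.cfg = cfg
        self.n_features = n_features
        self.rng = rng

    def random_terminal(self) -> tuple:
        if self.rng.random() < 0.7:
            return ("f", int(self.rng.integers(self.n_features)))
        return ("c", float(self.rng.uniform(-self.cfg.constant_range, self.cfg.constant_range)))

    def random_tree(self, depth: int, full: bool) -> tuple:
        if depth <= 1 or (not full and self.rng.random() < 0.3):
            return self.random_terminal()
        op = _BINARY_OPS[int(self.rng.integers(len(_BINARY_OPS)))]
        return (op, self.random_tree(depth - 1, full), self.random_tree(depth - 1, full))

    def init_population(self) -> list[tuple]:
        # ramped half-and-half over depths 2..min(5, max depth)
        pop = []
        depths = list(range(2, min(5, self.cfg.max_tree_depth) + 1))
        for i in range(self.cfg.population_size):
            pop.append(self.random_tree(depths[i % len(depths)], full=i % 2 == 0))
        return pop

    def _subtrees(self, node: tuple, path: tuple = ()) -> list[tuple]:
        out = [(path, node)]
        if node[0] not in ("f", "c"):
            out += self._subtrees(node[1], path + (1,))
            out += self._subtrees(node[2], path + (2,))
        return out

    def _replace(self, node: tuple, path: tuple, sub: tuple) -> tuple:
        if not path:
            return sub
        branch = path[0]
        left = self._replace(node[1], path[1:], sub) if branch == 1 else node[1]
        right = self._replace(node[2], path[1:], sub) if branch == 2 else node[2]
        return (node[0], left, right)

    def crossover(self, a: tuple, b: tuple) -> tuple:
        nodes_a = self._subtrees(a)
        nodes_b = self._subtrees(b)
        path, _ = nodes_a[int(self.rng.integers(len(nodes_a)))]
        _, sub = nodes_b[int(self.rng.integers(len(nodes_b)))]
        child = self._replace(a, path, sub)
        return child if tree_depth(child) <= self.cfg.max_tree_depth else a

    def mutate(self, node: tuple) -> tuple:
        nodes = self._subtrees(node)
        path, _ = nodes[int(self.rng.integers(len(nodes)))]
        child = self._replace(node, path, self.random_tree(2, full=False))
        return child if tree_depth(child) <= self.cfg.max_tree_depth else node

    def tournament(self, pop: list[tuple], fit: np.ndarray) -> int:
        idx = self.rng.integers(len(pop), size=self.cfg.tournament_size)
        return int(idx[np.argmax(fit[idx])])

    def evolve(self, X: np.ndarray, y_signed: np.ndarray) -> tuple:
        """Evolve one discriminant tree towards targets in {-1, +1}
        (fitness is negative mean squared error after linear output scaling)."""
        cfg = self.cfg

        def fitness(tree: tuple) -> float:
            out = eval_tree(tree, X)
            if not np.all(np.isfinite(out)):
                return -np.inf
            a, b = _linear_scaling(out, y_signed)
            return -float(np.mean((a * out + b - y_signed) ** 2))

        pop = self.init_population()
        fit = np.array([fitness(t) for t in pop])
        best_i = int(np.argmax(fit))
        best, best_fit = pop[best_i], float(fit[best_i])

        for _gen in range(cfg.max_generations):
            if best_fit >= -1e-9:
                break
            required = max(1, int(round(cfg.success_ratio * (cfg.population_size - 1))))
            successes: list[tuple[tuple, float]] = []
            pool: list[tuple[tuple, float]] = []
            trials = 0
            max_trials = int(cfg.max_selection_pressure * cfg.population_size)
            while len(successes) < required and trials < max_trials:
                i1 = self.tournament(pop, fit)
                i2 = self.tournament(pop, fit)
                child = self.crossover(pop[i1], pop[i2])
                if self.rng.random() < cfg.mutation_prob:
                    child = self.mutate(child)
                f = fitness(child)
                f_lo, f_hi = sorted((float(fit[i1]), float(fit[i2])))
                threshold = f_lo + cfg.comparison_factor * (f_hi - f_lo)
                if f >= threshold:
                    successes.append((child, f))
                else:
                    pool.append((child, f))
                trials += 1
            nxt = [(best, best_fit)] + successes
            pool.sort(key=lambda tf: -tf[1])
            nxt += pool[: cfg.population_size - len(nxt)]
            while len(nxt) < cfg.population_size:
                i = self.tournament(pop, fit)
                nxt.append((pop[i], float(fit[i])))
            nxt = nxt[: cfg.population_size]
            pop = [t for t, _ in nxt]
            fit = np.array([f for _, f in nxt])
            gen_best = int(np.argmax(fit))
            if fit[gen_best] > best_fit:
                best, best_fit = pop[gen_best], float(fit[gen_best])
            if trials >= max_trials and not successes:
                log.debug("offspring selection stagnated; returning best so far")
                break
        return best


class GPClassifier:
    """Scikit-learn-style wrapper around one-vs-rest evolved trees."""

    def __init__(self, config: GPConfig | None = None, random_state: int = 0):
        self.config = config or GPConfig()
        self.random_state = random_state
        self.classes_: list | None = None
        self.trees_: list[tuple] = []
        self.scalings_: list[tuple[float, float]] = []

    def fit(self, X: np.ndarray, y) -> "GPClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = sorted(set(y.tolist()), key=str)
        rng = np.random.default_rng(self.random_state)
        evolver = _Evolver(self.config, X.shape[1], rng)
        self.trees_ = []
        self.scalings_ = []
        for cls in self.classes_:
            signed = np.where(y == cls, 1.0, -1.0)
            tree = evolver.evolve(X, signed)
            self.trees_.append(tree)
            out = eval_tree(tree, X)
            if np.all(np.isfinite(out)):
                self.scalings_.append(_linear_scaling(out, signed))
            else:
                self.scalings_.append((0.0, float(signed.mean())))
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.column_stack(
            [
                a * eval_tree(t, X) + b
                for t, (a, b) in zip(self.trees_, self.scalings_)
            ]
        )
        return np.nan_to_num(out, nan=-np.inf, posinf=np.inf, neginf=-np.inf)

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        idx = np.argmax(scores, axis=1)
        return np.array([self.classes_[i] for i in idx])


def evolve_gp_classifier(
    X: np.ndarray, y, cfg: GPConfig | None = None, rng_seed: int = 0
) -> GPClassifier:
    """Evolve a one-vs-rest symbolic classifier over the feature matrix."""
    y = np.asarray(y)
    if len(set(y.tolist())) < 1:
        raise ValueError("need at least one class")
    return GPClassifier(cfg, random_state=rng_seed).fit(X, y)
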