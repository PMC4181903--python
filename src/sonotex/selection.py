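"""Feature-subset selection by genetic or random search over a
correlation-based merit.

The evaluator is the CFS (correlation-based feature selection) merit

    M_S = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where k is the subset size, r_cf the mean feature-class association of the
subset's features and r_ff the mean pairwise association between subset
features.  The merit rewards subsets that track the class while being
mutually non-redundant; zero-variance features contribute association 0.

Two association measures are provided.  ``measure="su"`` (the pipeline
default) is symmetrical uncertainty, 2*I(a;b)/(H(a)+H(b)), computed on
features discretized by the Fayyad-Irani MDL criterion — the
information-based evaluator of classical CFS, which detects two-sided
relations such as a disease group that is alternately brighter (fatty) and
darker (cirrhosis) than normal, and which scores a feature relevant to only
a minority subgroup (liver length for hepatomegaly) on the strength of its
best cut rather than on an arbitrary bin count.
``measure="pearson"`` is the absolute Pearson correlation on standardized
features; it is cheaper and easier to reason about analytically (for a
single feature the merit reduces to |r_cf|) but is blind to exactly those
non-monotone contrasts.

The searches mirror the two WEKA attribute searches the workflow is
modelled on: a simple genetic algorithm (roulette selection, single-point
crossover, per-bit mutation, elitism of one) and uniform random subset
sampling.  Ties in merit break toward the smaller subset, then the
lexicographically smaller bitmask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "SearchConfig",
    "SubsetCandidate",
    "MeritEvaluator",
    "subset_merit",
    "genetic_search",
    "random_search",
    "select_features",
    "table_to_arrays",
]


def table_to_arrays(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y01, feature_names); the positive
    class (abnormal) maps to 1."""
    feature_cols = [c for c in table.columns if c not in ("case_id", "class")]
    X = table[feature_cols].to_numpy(dtype=float)
    y = (table["class"].to_numpy() == "abnormal").astype(float)
    return X, y, feature_cols


@dataclass
class SearchConfig:
    method: str = "genetic"          # "genetic" | "random"
    population_size: int = 20        # WEKA GeneticSearch defaults
    generations: int = 20
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    random_budget: int = 500
    measure: str = "su"              # "su" | "pearson"
    seed: int = 0

    def validate(self) -> None:
        if self.method not in ("genetic", "random"):
            raise ValueError("method must be 'genetic' or 'random'")
        if self.measure not in ("su", "pearson"):
            raise ValueError("measure must be 'su' or 'pearson'")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if min(self.population_size, self.generations, self.random_budget) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SubsetCandidate:
    mask: np.ndarray               # boolean over feature indices
    merit: float
    names: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return int(self.mask.sum())


def _class_entropy(labels: np.ndarray) -> float:
    counts = np.bincount(labels)
    p = counts[counts > 0] / labels.size
    return float(-np.sum(p * np.log2(p)))


def _mdl_discretize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fayyad-Irani entropy-based (MDL) discretization of one feature.

    Recursively places the class-information-maximizing cut point and keeps
    it only when the information gain clears the MDL acceptance threshold.
    A feature with no informative cut collapses to a single bin (entropy 0,
    hence symmetrical uncertainty 0) — the classical behaviour that lets
    CFS zero out irrelevant attributes.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        seg_y = ys[lo:hi]
        k = len(np.unique(seg_y))
        if n < 4 or k == 1:
            return
        base = _class_entropy(seg_y)
        xv = xs[lo:hi]
        change = np.flatnonzero(np.diff(xv) != 0) + 1
        best_gain, best_i, best_parts = 0.0, None, None
        for i in change:
            left, right = seg_y[:i], seg_y[i:]
            e1, e2 = _class_entropy(left), _class_entropy(right)
            gain = base - (i / n) * e1 - ((n - i) / n) * e2
            if gain > best_gain:
                best_gain, best_i, best_parts = gain, int(i), (e1, e2, left, right)
        if best_i is None:
            return
        e1, e2, left, right = best_parts
        k1, k2 = len(np.unique(left)), len(np.unique(right))
        delta = np.log2(3.0**k - 2.0) - (k * base - k1 * e1 - k2 * e2)
        if best_gain > (np.log2(n - 1.0) + delta) / n:
            cuts.append(0.5 * (xs[lo + best_i - 1] + xs[lo + best_i]))
            recurse(lo, lo + best_i)
            recurse(lo + best_i, hi)

    recurse(0, len(xs))
    return np.searchsorted(np.sort(cuts), x, side="right")


def _discretize(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Supervised MDL discretization of each column to integer codes."""
    codes = np.empty(X.shape, dtype=np.int64)
    for j in range(X.shape[1]):
        codes[:, j] = _mdl_discretize(X[:, j], y)
    return codes


def _entropy_codes(a: np.ndarray) -> float:
    counts = np.bincount(a)
    p = counts[counts > 0] / a.size
    return float(-np.sum(p * np.log2(p)))


def _symmetrical_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ha = _entropy_codes(a)
    hb = _entropy_codes(b)
    if ha + hb == 0:
        return 0.0
    joint = a * (b.max() + 1) + b
    hab = _entropy_codes(joint)
    return 2.0 * max(ha + hb - hab, 0.0) / (ha + hb)


class MeritEvaluator:
    """CFS merit over a fixed table, with the association structure
    precomputed once so that search loops stay cheap."""

    def __init__(self, X: np.ndarray, y: np.ndarray, measure: str = "su"):
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_cases, n_features) aligned with y")
        n, self.n_features = X.shape
        if len(np.unique(y)) < 2 or min(np.sum(y == 0), np.sum(y == 1)) < 2:
            raise ValueError("need at least 2 cases of each class")
        if measure == "pearson":
            Xs = X - X.mean(axis=0)
            sd = Xs.std(axis=0)
            nonzero = sd > 0
            Xs[:, nonzero] /= sd[nonzero]
            Xs[:, ~nonzero] = 0.0  # zero-variance features correlate with nothing
            ys = (y - y.mean()) / y.std()
            self.r_cf = np.abs(Xs.T @ ys) / n
            self.r_ff = np.abs(Xs.T @ Xs) / n
            np.fill_diagonal(self.r_ff, 1.0)
        elif measure == "su":
            ycodes = y.astype(np.int64)
            codes = _discretize(X, ycodes)
            m = self.n_features
            self.r_cf = np.array(
                [_symmetrical_uncertainty(codes[:, j], ycodes) for j in range(m)]
            )
            self.r_ff = np.ones((m, m))
            for a in range(m):
                for b in range(a + 1, m):
                    su = _symmetrical_uncertainty(codes[:, a], codes[:, b])
                    self.r_ff[a, b] = self.r_ff[b, a] = su
        else:
            raise ValueError("measure must be 'su' or 'pearson'")

    def __call__(self, mask: np.ndarray) -> float:
        idx = np.flatnonzero(mask)
        k = idx.size
        if k == 0:
            raise ValueError("empty subset has no merit")
        rcf = self.r_cf[idx].mean()
        if k == 1:
            return float(rcf)
        sub = self.r_ff[np.ix_(idx, idx)]
        rff = (sub.sum() - k) / (k * (k - 1))
        return float(k * rcf / np.sqrt(k + k * (k - 1) * rff))


def subset_merit(table: pd.DataFrame, subset: np.ndarray,
                 measure: str = "su") -> float:
    """CFS merit of one subset (bitmask over the table's feature columns)."""
    X, y, _ = table_to_arrays(table)
    return MeritEvaluator(X, y, measure=measure)(np.asarray(subset, dtype=bool))


def _better(merit_a: float, mask_a: np.ndarray, merit_b: float, mask_b: np.ndarray) -> bool:
    """True when candidate a beats b: higher merit, then fewer features,
    then lexicographically smaller bitmask."""
    if merit_a != merit_b:
        return merit_a > merit_b
    ka, kb = int(mask_a.sum()), int(mask_b.sum())
    if ka != kb:
        return ka < kb
    return tuple(mask_a.astype(int)) < tuple(mask_b.astype(int))


def _ensure_nonempty(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(0, mask.size)] = True
    return mask


def genetic_search(table: pd.DataFrame, config: SearchConfig | None = None) -> SubsetCandidate:
    """Simple GA over attribute subsets; returns the best-ever candidate.
    Deterministic for a fixed seed."""
    config = config or SearchConfig(method="genetic")
    config.validate()
    if config.method != "genetic":
        raise ValueError("config.method must be 'genetic'")
    X, y, names = table_to_arrays(table)
    evaluate = MeritEvaluator(X, y, measure=config.measure)
    n_f = len(names)
    rng = np.random.default_rng(config.seed)

    pop = [_ensure_nonempty(rng.random(n_f) < 0.5, rng)
           for _ in range(config.population_size)]
    fitness = np.array([evaluate(m) for m in pop])
    best_mask, best_merit = pop[0].copy(), fitness[0]
    for m, f in zip(pop[1:], fitness[1:]):
        if _better(f, m, best_merit, best_mask):
            best_mask, best_merit = m.copy(), f

    for _ in range(config.generations):
        # roulette selection on shifted fitness (merit can be near zero)
        w = fitness - fitness.min() + 1e-9
        probs = w / w.sum()
        elite = best_mask.copy()
        children = [elite]
        while len(children) < config.population_size:
            ia, ib = rng.choice(len(pop), size=2, p=probs)
            a, b = pop[ia].copy(), pop[ib].copy()
            if rng.random() < config.crossover_prob and n_f > 1:
                cut = int(rng.integers(1, n_f))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flips = rng.random(n_f) < config.mutation_prob
                child ^= flips
                children.append(_ensure_nonempty(child, rng))
        pop = children[: config.population_size]
        fitness = np.array([evaluate(m) for m in pop])
        for m, f in zip(pop, fitness):
            if _better(f, m, best_merit, best_mask):
                best_mask, best_merit = m.copy(), f
    return SubsetCandidate(mask=best_mask, merit=float(best_merit),
                           names=[names[i] for i in np.flatnonzero(best_mask)])


def random_search(table: pd.DataFrame, config: SearchConfig | None = None) -> SubsetCandidate:
    """Uniform random search over non-empty subsets; exhaustive when the
    budget covers the whole subset lattice.  Seeded and budget-monotone
    (a larger budget extends the same sample stream)."""
    config = config or SearchConfig(method="random")
    config.validate()
    if config.method != "random":
        raise ValueError("config.method must be 'random'")
    X, y, names = table_to_arrays(table)
    evaluate = MeritEvaluator(X, y, measure=config.measure)
    n_f = len(names)
    rng = np.random.default_rng(config.seed)

    best_mask = None
    best_merit = -np.inf

    def consider(mask: np.ndarray) -> None:
        nonlocal best_mask, best_merit
        merit = evaluate(mask)
        if best_mask is None or _better(merit, mask, best_merit, best_mask):
            best_mask, best_merit = mask.copy(), merit

    if 2**n_f - 1 <= config.random_budget:
        for k in range(1, n_f + 1):
            for idx in combinations(range(n_f), k):
                mask = np.zeros(n_f, dtype=bool)
                mask[list(idx)] = True
                consider(mask)
    else:
        for _ in range(config.random_budget):
            consider(_ensure_nonempty(rng.random(n_f) < 0.5, rng))
    return SubsetCandidate(mask=best_mask, merit=float(best_merit),
                           names=[names[i] for i in np.flatnonzero(best_mask)])


def select_features(table: pd.DataFrame, config: SearchConfig) -> SubsetCandidate:
    """Dispatch on ``config.method``."""
    if config.method == "genetic":
        return genetic_search(table, config)
    return random_search(table, config)
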