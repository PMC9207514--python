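"""Hybrid neuroevolution: GP over tree structures, swarm over parameters.

Structure search and parameter search are interleaved: grammar-guided
genetic programming proposes flexible-neural-tree topologies, and every
candidate topology receives a short, warm-started salp-swarm polish of its
continuous parameters before its fitness is recorded. Selection is
tournament-based with one elite copied unchanged per generation; after the
last generation the best structure gets a deeper swarm run. Fitness is the
root-mean-square error of the continuous tree output against the 0/1 class
labels, so a perfect classifier scores 0 and the all-0.5 constant scores
0.5 on balanced labels.

Features are min-max scaled to [0, 1] (fitted on the training data only)
before they reach the tree, keeping the Gaussian activations
well-conditioned; the scaling parameters travel with the trained model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import fnt_core, grammar_gp, ssa
from .errors import InputError, TrainingError

__all__ = ["TrainConfig", "TrainedModel", "fitness", "train", "predict"]


@dataclass
class TrainConfig:
    """Knobs of the hybrid evolutionary run.

    Defaults follow the screening study's stated settings (population 30,
    maximum tree depth 5, operator arities 2-5, decision threshold 0.5);
    iteration budgets for the two optimization phases are deliberately
    modest and config-exposed.
    """

    population_size: int = 30
    max_depth: int = 5
    arities: tuple[int, ...] = (2, 3, 4, 5)
    gp_generations: int = 10
    ssa_iterations_screen: int = 20
    ssa_population_screen: int = 10
    ssa_iterations_final: int = 100
    weight_bounds: tuple[float, float] = (-1.0, 1.0)
    a_bounds: tuple[float, float] = (0.0, 1.0)
    b_bounds: tuple[float, float] = (0.01, 1.0)
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    tournament_size: int = 3
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise InputError("population_size must be >= 2")
        if self.max_depth < 2:
            raise InputError("max_depth must be >= 2")
        for low, high in (self.weight_bounds, self.a_bounds, self.b_bounds):
            if not low < high:
                raise InputError("parameter bounds must satisfy low < high")


@dataclass
class TrainedModel:
    """A fitted tree plus the feature scaling fitted on its training data."""

    model: fnt_core.FNTModel
    col_min: np.ndarray
    col_max: np.ndarray
    fitness_trace: list[float]
    threshold: float
    config: TrainConfig | None = None
    structure: str = ""

    def to_json(self) -> str:
        doc = {
            "format": "fntscreen-trained/1",
            "model": json.loads(fnt_core.model_to_json(self.model)),
            "col_min": self.col_min.tolist(),
            "col_max": self.col_max.tolist(),
            "fitness_trace": list(map(float, self.fitness_trace)),
            "threshold": self.threshold,
            "structure": self.structure,
            "config": asdict(self.config) if self.config is not None else None,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        doc = json.loads(text)
        if doc.get("format") != "fntscreen-trained/1":
            raise InputError(f"unrecognized format tag {doc.get('format')!r}")
        cfg = None
        if doc.get("config"):
            c = dict(doc["config"])
            c["arities"] = tuple(c["arities"])
            for key in ("weight_bounds", "a_bounds", "b_bounds"):
                c[key] = tuple(c[key])
            cfg = TrainConfig(**c)
        model = fnt_core.model_from_json(json.dumps(doc["model"]))
        return cls(
            model=model,
            col_min=np.asarray(doc["col_min"], float),
            col_max=np.asarray(doc["col_max"], float),
            fitness_trace=list(doc["fitness_trace"]),
            threshold=float(doc["threshold"]),
            config=cfg,
            structure=doc.get("structure", ""),
        )


def fitness(model: fnt_core.FNTModel, X: np.ndarray, y: np.ndarray) -> float:
    """RMSE between the tree's continuous output and the 0/1 labels."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] == 0:
        raise InputError("cannot compute fitness on empty data")
    if X.shape[0] != y.shape[0]:
        raise InputError("X and y lengths differ")
    scores = fnt_core.evaluate_batch(model, X)
    return float(np.sqrt(np.mean((scores - y) ** 2)))


def _scale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return X.min(axis=0), X.max(axis=0)


def _scale_apply(X: np.ndarray, col_min: np.ndarray, col_max: np.ndarray) -> np.ndarray:
    span = col_max - col_min
    safe = np.where(span > 0, span, 1.0)
    out = (X - col_min) / safe
    out = np.where(span > 0, out, 0.0)  # constant columns map to 0
    return np.clip(out, 0.0, 1.0)


def _parameter_bounds(
    model: fnt_core.FNTModel, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-parameter box in the flat pre-order layout (weights, a, b)."""
    lows: list[float] = []
    highs: list[float] = []
    for op in fnt_core._operator_nodes(model.root):
        lows.extend([cfg.weight_bounds[0]] * op.arity)
        highs.extend([cfg.weight_bounds[1]] * op.arity)
        lows.extend([cfg.a_bounds[0], cfg.b_bounds[0]])
        highs.extend([cfg.a_bounds[1], cfg.b_bounds[1]])
    return np.asarray(lows), np.asarray(highs)


def _polish(
    model: fnt_core.FNTModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    m: int,
    iterations: int,
    rng: np.random.Generator,
) -> tuple[fnt_core.FNTModel, float]:
    """Swarm-polish a tree's parameters, warm-started from its current ones.

    The current parameter vector seeds the swarm, so the returned fitness is
    never worse than the tree's incoming fitness.
    """
    xmin, xmax = _parameter_bounds(model, cfg)
    current = fnt_core.extract_parameters(model)
    scratch = model.copy()

    def fn(v: np.ndarray) -> float:
        fnt_core.inject_parameters(scratch, v, inplace=True)
        return fitness(scratch, X, y)

    ssa_cfg = ssa.SSAConfig(m=m, n=len(current), xmin=xmin, xmax=xmax, T=iterations)
    result = ssa.run_ssa(fn, ssa_cfg, rng=rng, initial_positions=current)
    best_model = fnt_core.inject_parameters(model, result.best)
    return best_model, result.best_fitness


def train(X: np.ndarray, y: np.ndarray, cfg: TrainConfig | None = None) -> TrainedModel:
    """Fit a flexible neural tree to binary-labeled feature rows.

    Deterministic given ``cfg.seed``: structure search, parameter polish and
    the returned model are all reproducible.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InputError("X must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    if counts.min() < 2:
        raise TrainingError("need at least 2 samples per class")

    col_min, col_max = _scale_fit(X)
    Xs = _scale_apply(X, col_min, col_max)
    rng = np.random.default_rng(cfg.seed)
    grammar = grammar_gp.build_default_grammar(set(cfg.arities), X.shape[1])

    # individuals: (derivation tree, fitted model, fitness)
    population: list[tuple[grammar_gp.DerivationNode, fnt_core.FNTModel, float]] = []
    for _ in range(cfg.population_size):
        tree = grammar_gp.random_derivation(grammar, cfg.max_depth, rng)
        model = grammar_gp.derivation_to_fnt(
            tree, X.shape[1], cfg.weight_bounds, rng
        )
        model, fit = _polish(
            model, Xs, y, cfg, cfg.ssa_population_screen,
            cfg.ssa_iterations_screen, rng,
        )
        population.append((tree, model, fit))

    trace: list[float] = []
    best = min(population, key=lambda ind: ind[2])
    trace.append(best[2])

    for _ in range(cfg.gp_generations):
        fitness_pairs = [(t, f) for t, _, f in population]
        new_pop = [best]  # elite copied unchanged (replication)
        while len(new_pop) < cfg.population_size:
            if rng.random() < cfg.crossover_rate:
                p1 = grammar_gp.select_parent(fitness_pairs, rng, cfg.tournament_size)
                p2 = grammar_gp.select_parent(fitness_pairs, rng, cfg.tournament_size)
                children = grammar_gp.crossover(p1, p2, grammar, cfg.max_depth, rng)
            else:
                p = grammar_gp.select_parent(fitness_pairs, rng, cfg.tournament_size)
                children = (p,)
            for child in children:
                if len(new_pop) >= cfg.population_size:
                    break
                if rng.random() < cfg.mutation_rate:
                    child = grammar_gp.mutate(child, grammar, cfg.max_depth, rng)
                model = grammar_gp.derivation_to_fnt(
                    child, X.shape[1], cfg.weight_bounds, rng
                )
                model, fit = _polish(
                    model, Xs, y, cfg, cfg.ssa_population_screen,
                    cfg.ssa_iterations_screen, rng,
                )
                new_pop.append((child, model, fit))
        population = new_pop
        best = min(population, key=lambda ind: ind[2])
        trace.append(best[2])

    # deep parameter run on the winning structure
    final_model, final_fit = _polish(
        best[1], Xs, y, cfg, cfg.population_size, cfg.ssa_iterations_final, rng
    )
    trace.append(final_fit)

    return TrainedModel(
        model=final_model,
        col_min=col_min,
        col_max=col_max,
        fitness_trace=trace,
        threshold=cfg.threshold,
        config=cfg,
        structure=grammar_gp.to_sexpr(best[0]),
    )


def predict(tm: TrainedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores in (0, 1] and hard labels (score strictly above threshold)."""
    X = np.asarray(X, float)
    if X.size == 0:
        return np.empty(0), np.empty(0, dtype=int)
    if X.ndim != 2 or X.shape[1] != tm.model.input_dim:
        raise InputError(
            f"expected {tm.model.input_dim} feature columns, got shape {X.shape}"
        )
    Xs = _scale_apply(X, tm.col_min, tm.col_max)
    scores = fnt_core.evaluate_batch(tm.model, Xs)
    labels = (scores > tm.threshold).astype(int)
    return scores, labels
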