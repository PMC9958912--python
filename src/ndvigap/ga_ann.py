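"""The core regression method: a 1-H-1 neural network trained by a genetic
algorithm, with optional gradient refinement.

The network maps one coarse-sensor NDVI value to one fine-sensor NDVI value:

    y = b2 + sum_j w2_j * tanh(w1_j * (2x - 1) + b1_j),   j = 1..H

so a chromosome holds 3H + 1 genes (input weights, hidden biases, output
weights, output bias); for the default H = 5 that is 16 genes.  Inputs in
[0, 1] are affinely mapped to [-1, 1] before the saturating hidden layer and
predictions are clamped back to [0, 1] at inference only — fitness and
gradient refinement see the unclamped linear output so the search never
stalls on a flat clipped region.

The genetic algorithm follows the classical recipe: a small real-coded
population, roulette-wheel (fitness-proportional) selection, two-point
crossover, per-gene Gaussian mutation, and heavy elitism.  Fitness is
1 / (MSE + eps), which is strictly positive (required by roulette selection)
and preserves the MSE ordering.  Elitism makes the best-fitness trace
non-decreasing, which is asserted on every run.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pairing import PixelPairSet, split_train_validation

__all__ = [
    "NetworkSpec",
    "GAConfig",
    "GAANNModel",
    "TrainResult",
    "forward",
    "fitness",
    "roulette_select",
    "crossover",
    "mutate",
    "evolve",
    "refine",
    "train",
    "save_model",
    "load_model",
]

_FITNESS_EPS = 1e-12


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the 1-H-1 network (tanh hidden layer, linear output)."""

    n_hidden: int = 5
    hidden_activation: str = "tanh"

    n_input: int = 1
    n_output: int = 1

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.hidden_activation != "tanh":
            raise ValueError("only the tanh hidden activation is implemented")

    @property
    def weight_count(self) -> int:
        # input->hidden weights + hidden biases + hidden->output weights + bias
        return 3 * self.n_hidden + 1


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults are the classical small-population setup used for this method:
    population 10 with 9 elites, roulette-wheel selection, two-point
    crossover at probability 0.4, Gaussian mutation at probability 0.2, at
    most 50 generations, and termination when the best fitness improves
    relatively by less than 1e-5 over a 10-generation stall window.
    ``migration_direction``/``migration_interval`` are recorded for
    provenance but inert: there is a single population.
    """

    population_size: int = 10
    elite_count: int = 9
    crossover_probability: float = 0.4
    crossover_type: str = "two-point"
    mutation_probability: float = 0.2
    mutation_sigma: float | None = None  # default: 0.1 * gene range
    max_generations: int = 50
    termination_tolerance: float = 1e-5
    stall_window: int = 10
    gene_low: float = -5.0
    gene_high: float = 5.0
    migration_direction: str = "forward"
    migration_interval: int = 11

    def __post_init__(self) -> None:
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("need 0 <= elite_count < population_size")
        for p in (self.crossover_probability, self.mutation_probability):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_generations < 1 or self.termination_tolerance <= 0:
            raise ValueError("max_generations >= 1 and tolerance > 0 required")
        if not self.gene_high > self.gene_low:
            raise ValueError("gene bounds must satisfy high > low")

    @property
    def sigma(self) -> float:
        if self.mutation_sigma is not None:
            return self.mutation_sigma
        return 0.1 * (self.gene_high - self.gene_low)


@dataclass
class GAANNModel:
    """Trained network: weights plus the fixed input/output affine scalings.

    ``predict``/:func:`forward` is a pure deterministic function of
    (weights, scaling, input).
    """

    spec: NetworkSpec
    weights: np.ndarray
    input_scaling: tuple[float, float] = (-1.0, 2.0)  # x -> offset + scale * x
    output_scaling: tuple[float, float] = (0.0, 1.0)
    training_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.spec.weight_count,):
            raise ValueError(
                f"expected {self.spec.weight_count} weights, got {self.weights.shape}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return forward(self, x)


def _unpack(genes: np.ndarray, h: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    return genes[:h], genes[h : 2 * h], genes[2 * h : 3 * h], genes[3 * h]


def _raw_output(
    genes: np.ndarray, h: int, x: np.ndarray, input_scaling: tuple[float, float]
) -> np.ndarray:
    off, scale = input_scaling
    t = off + scale * x
    w1, b1, w2, b2 = _unpack(genes, h)
    hidden = np.tanh(np.multiply.outer(t, w1) + b1)
    return hidden @ w2 + b2


def forward(model: GAANNModel, x: np.ndarray | float) -> np.ndarray | float:
    """Predict fine NDVI from coarse NDVI; output clamped to [0, 1].

    Accepts scalars or arrays of any shape; shape and order are preserved.
    """
    scalar = np.isscalar(x) or (isinstance(x, np.ndarray) and x.ndim == 0)
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("forward requires finite inputs")
    o_off, o_scale = model.output_scaling
    y = o_off + o_scale * _raw_output(
        model.weights, model.spec.n_hidden, arr.ravel(), model.input_scaling
    )
    y = np.clip(y, 0.0, 1.0).reshape(arr.shape)
    return float(y) if scalar else y


def _mse(genes: np.ndarray, spec: NetworkSpec, x: np.ndarray, y: np.ndarray) -> float:
    pred = _raw_output(genes, spec.n_hidden, x, (-1.0, 2.0))
    return float(np.mean((pred - y) ** 2))


def fitness(chromosome: np.ndarray, pairs: PixelPairSet, spec: NetworkSpec) -> float:
    """1 / (training MSE + eps): strictly positive, higher is better."""
    if len(pairs) == 0:
        raise ValueError("fitness requires a non-empty pair set")
    genes = np.asarray(chromosome, dtype=float)
    return 1.0 / (_mse(genes, spec, pairs.coarse, pairs.fine) + _FITNESS_EPS)


def roulette_select(
    population: np.ndarray,
    fitnesses: np.ndarray,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Fitness-proportional sampling with replacement."""
    fitnesses = np.asarray(fitnesses, dtype=float)
    if np.any(fitnesses <= 0):
        raise ValueError("roulette selection requires strictly positive fitnesses")
    rng = _rng(seed)
    cum = np.cumsum(fitnesses)
    idx = np.searchsorted(cum / cum[-1], rng.random(n), side="right")
    return np.asarray(population)[np.minimum(idx, len(fitnesses) - 1)]


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    probability: float = 0.4,
    seed: int | np.random.Generator = 0,
    crossover_type: str = "two-point",
    cut_points: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recombine two chromosomes; with probability ``1 - probability`` the
    parents are returned unchanged.

    Two-point crossover swaps the gene segment [i, j); ``cut_points`` pins
    the cuts (used in tests), otherwise they are drawn uniformly.
    """
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("parents must have equal gene length")
    rng = _rng(seed)
    if rng.random() >= probability:
        return a.copy(), b.copy()
    n = len(a)
    c, d = a.copy(), b.copy()
    if crossover_type == "two-point":
        if cut_points is None:
            i, j = np.sort(rng.choice(n + 1, size=2, replace=False))
        else:
            i, j = cut_points
        c[i:j], d[i:j] = b[i:j], a[i:j]
    elif crossover_type == "single-point":
        i = int(rng.integers(1, n)) if cut_points is None else cut_points[0]
        c[i:], d[i:] = b[i:], a[i:]
    elif crossover_type == "uniform":
        swap = rng.random(n) < 0.5
        c[swap], d[swap] = b[swap], a[swap]
    else:
        raise ValueError(f"unknown crossover type {crossover_type!r}")
    return c, d


def mutate(
    chromosome: np.ndarray,
    probability: float = 0.2,
    sigma: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-gene Gaussian perturbation: each gene moves by N(0, sigma^2) with
    the given probability, independently."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    genes = np.asarray(chromosome, dtype=float)
    rng = _rng(seed)
    hit = rng.random(len(genes)) < probability
    noise = rng.normal(0.0, sigma, len(genes))
    return genes + hit * noise


def evolve(
    pairs: PixelPairSet,
    spec: NetworkSpec | None = None,
    config: GAConfig | None = None,
    seed: int = 0,
) -> "TrainResult":
    """Run the genetic algorithm and return the best network found.

    Each generation carries the ``elite_count`` best chromosomes over
    unchanged and fills the remaining slots with mutated crossover offspring
    of roulette-selected parents.  Stops at ``max_generations`` or when the
    best fitness has improved relatively by less than the termination
    tolerance over the stall window.
    """
    spec = spec or NetworkSpec()
    config = config or GAConfig()
    if len(pairs) < 2 * config.population_size:
        raise ValueError(
            f"need at least {2 * config.population_size} pairs, got {len(pairs)}"
        )
    if config.elite_count >= config.population_size - 1:
        warnings.warn(
            "elite_count leaves at most one non-elite slot per generation; "
            "exploration is driven almost entirely by that single offspring",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    pop = rng.uniform(
        config.gene_low, config.gene_high, (config.population_size, spec.weight_count)
    )
    fits = np.array([fitness(c, pairs, spec) for c in pop])
    trace: list[float] = []
    for gen in range(config.max_generations):
        order = np.argsort(fits)[::-1]
        pop, fits = pop[order], fits[order]
        trace.append(float(fits[0]))
        if (
            len(trace) > config.stall_window
            and (trace[-1] - trace[-1 - config.stall_window])
            < config.termination_tolerance * abs(trace[-1 - config.stall_window])
        ):
            break
        if gen == config.max_generations - 1:
            break
        children = []
        while len(children) < config.population_size - config.elite_count:
            pa, pb = roulette_select(pop, fits, 2, rng)
            ca, cb = crossover(
                pa, pb, config.crossover_probability, rng, config.crossover_type
            )
            for child in (ca, cb):
                if len(children) < config.population_size - config.elite_count:
                    children.append(
                        mutate(child, config.mutation_probability, config.sigma, rng)
                    )
        elite = pop[: config.elite_count]
        elite_fit = fits[: config.elite_count]
        child_fit = np.array([fitness(c, pairs, spec) for c in children])
        pop = np.vstack([elite, children])
        fits = np.concatenate([elite_fit, child_fit])
    best = int(np.argmax(fits))
    model = GAANNModel(
        spec=spec,
        weights=pop[best].copy(),
        training_summary={
            "generations_run": len(trace),
            "final_fitness": float(fits[best]),
            "refined": False,
            "seed": seed,
        },
    )
    return TrainResult(model=model, validation_metrics={}, fitness_trace=trace)


def _gradient(
    genes: np.ndarray, h: int, x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Analytic gradient of the training MSE for the 1-H-1 tanh network."""
    w1, b1, w2, _ = _unpack(genes, h)
    t = -1.0 + 2.0 * x
    a = np.multiply.outer(t, w1) + b1  # (n, h)
    hid = np.tanh(a)
    pred = hid @ w2 + genes[3 * h]
    dl = 2.0 * (pred - y) / len(y)  # (n,)
    grad = np.empty_like(genes)
    dhid = np.multiply.outer(dl, w2) * (1.0 - hid**2)  # (n, h)
    grad[:h] = dhid.T @ t  # d/dw1
    grad[h : 2 * h] = dhid.sum(axis=0)  # d/db1
    grad[2 * h : 3 * h] = hid.T @ dl  # d/dw2
    grad[3 * h] = dl.sum()  # d/db2
    return grad


def refine(
    model: GAANNModel,
    pairs: PixelPairSet,
    steps: int = 500,
    learning_rate: float = 0.1,
    method: str = "lbfgs",
) -> GAANNModel:
    """Polish the GA solution by gradient-based descent on training MSE.

    ``lbfgs`` (default) runs L-BFGS with the analytic gradient for up to
    ``steps`` iterations; its line search only accepts decreasing iterates
    and the result is additionally safeguarded against the starting loss, so
    the training MSE never increases.  ``gd`` is plain full-batch gradient
    descent with backtracking (the step size halves on rejection and grows
    gently on acceptance); slower but dependency-light.  ``steps=0`` is the
    identity.
    """
    x, y = pairs.coarse, pairs.fine
    h = model.spec.n_hidden
    genes = model.weights.copy()
    loss = _mse(genes, model.spec, x, y)
    if steps > 0 and method == "lbfgs":
        from scipy.optimize import minimize

        out = minimize(
            lambda g: _mse(g, model.spec, x, y),
            genes,
            jac=lambda g: _gradient(g, h, x, y),
            method="L-BFGS-B",
            options={"maxiter": steps, "ftol": 1e-15, "gtol": 1e-12},
        )
        if out.fun <= loss:
            genes, loss = out.x.copy(), float(out.fun)
    elif steps > 0 and method == "gd":
        lr = learning_rate
        for _ in range(steps):
            g = _gradient(genes, h, x, y)
            cand = genes - lr * g
            cand_loss = _mse(cand, model.spec, x, y)
            if cand_loss <= loss:
                genes, loss = cand, cand_loss
                lr *= 1.2
            else:
                lr *= 0.5
                if lr < 1e-12:
                    break
    elif steps > 0:
        raise ValueError(f"unknown refinement method {method!r}")
    summary = dict(model.training_summary)
    summary.update({"refined": steps > 0 or summary.get("refined", False),
                    "refine_steps": steps, "final_training_mse": loss})
    if steps == 0:
        summary["refined"] = model.training_summary.get("refined", False)
    return GAANNModel(
        spec=model.spec,
        weights=genes,
        input_scaling=model.input_scaling,
        output_scaling=model.output_scaling,
        training_summary=summary,
    )


@dataclass
class TrainResult:
    """Outcome of a training run: the model, held-out metrics, and the
    per-generation best-fitness trace (non-decreasing under elitism)."""

    model: GAANNModel
    validation_metrics: dict
    fitness_trace: list[float]


def train(
    pairs: PixelPairSet,
    spec: NetworkSpec | None = None,
    config: GAConfig | None = None,
    seed: int = 0,
    refine_flag: bool = True,
    refine_steps: int = 500,
    train_fraction: float = 0.8,
) -> TrainResult:
    """Full training protocol: split, evolve, optionally refine, validate.

    The pair set is split ``train_fraction``/(1 - ``train_fraction``); the
    genetic algorithm (and the optional gradient refinement) sees only the
    training part, and RMSE/MAE/Pearson r are reported on the held-out part
    using clamped predictions.
    """
    from . import metrics as _metrics

    train_set, val_set = split_train_validation(pairs, train_fraction, seed)
    result = evolve(train_set, spec, config, seed)
    model = result.model
    if refine_flag:
        model = refine(model, train_set, steps=refine_steps)
    pred = forward(model, val_set.coarse)
    vm = {
        "rmse": _metrics.rmse(pred, val_set.fine),
        "mae": _metrics.mae(pred, val_set.fine),
        "n": len(val_set),
    }
    if len(val_set) >= 2 and np.std(val_set.fine) > 0 and np.std(pred) > 0:
        vm["r"] = _metrics.pearson_r(pred, val_set.fine)
    model.training_summary["validation"] = vm
    return TrainResult(model=model, validation_metrics=vm, fitness_trace=result.fitness_trace)


# ---------------------------------------------------------------------------
# Serialization — a small JSON document sufficient to reproduce any
# prediction bit-exactly.


def save_model(model: GAANNModel, path: str | Path) -> None:
    doc = {
        "format": "ndvigap-ga-ann-model",
        "version": 1,
        "spec": {
            "n_hidden": model.spec.n_hidden,
            "hidden_activation": model.spec.hidden_activation,
        },
        "weights": [w.hex() for w in model.weights.astype(float)],
        "weights_readable": model.weights.tolist(),
        "input_scaling": list(model.input_scaling),
        "output_scaling": list(model.output_scaling),
        "training_summary": _jsonable(model.training_summary),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def load_model(path: str | Path) -> GAANNModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ndvigap-ga-ann-model":
        raise ValueError(f"{path} is not a ndvigap model file")
    return GAANNModel(
        spec=NetworkSpec(
            n_hidden=doc["spec"]["n_hidden"],
            hidden_activation=doc["spec"]["hidden_activation"],
        ),
        weights=np.array([float.fromhex(w) for w in doc["weights"]]),
        input_scaling=tuple(doc["input_scaling"]),
        output_scaling=tuple(doc["output_scaling"]),
        training_summary=doc.get("training_summary", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
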