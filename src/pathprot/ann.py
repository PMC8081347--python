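"""Multilayer perceptron with resilient-backpropagation training rules.

The perceptron is fully connected with logistic activations on every hidden
unit and on the single binomial output unit, trained against the summed
squared error E = 1/2 * sum (y - yhat)^2.  Five update rules are provided:

``backprop``
    Plain gradient descent, delta_w = -lr * dE/dw with lr = 0.001.
``rprop_plus``
    Resilient backpropagation *with* weight backtracking.  Each weight owns
    a step size Delta_ij adapted multiplicatively: grown by eta+ when the
    partial derivative keeps its sign, shrunk by eta- when it flips
    (0 < eta- < 1 < eta+).  On a sign flip the previous weight update is
    reverted (delta_w = -prev_dw) and the stored derivative zeroed so the
    same flip is not punished twice.
``rprop_minus``
    The same step-size adaptation without the backtracking branch: the
    update is always -sign(grad) * Delta.
``sag`` / ``slr``
    Globally convergent variants: weights whose derivative flipped sign
    step with a shared conservative magnitude instead of their own shrunken
    step -- the smallest Delta among the weights with smallest absolute
    derivative (``sag``) or the smallest Delta over all weights (``slr``).

Defaults eta+ = 1.2, eta- = 0.5, Delta0 = 0.1, Delta in [1e-6, 50] are the
canonical resilient-backpropagation settings.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .architecture import MLPTopology
from .features import ReducedFeatures

__all__ = [
    "MLP",
    "RpropState",
    "TrainingConfig",
    "TrainingTrace",
    "EvaluationReport",
    "ALGORITHMS",
    "init_mlp",
    "forward",
    "gradient",
    "backprop_update",
    "rprop_plus_update",
    "rprop_minus_update",
    "grprop_update",
    "train",
    "evaluate_protocol",
    "predict_labels",
]

ALGORITHMS = ("backprop", "rprop_plus", "rprop_minus", "sag", "slr")


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class MLP:
    topology: MLPTopology
    #: per-layer weight matrices of shape (fan_in + 1, fan_out); the last
    #: input row is the bias weight
    weights: list[np.ndarray]

    def copy(self) -> "MLP":
        return MLP(self.topology, [w.copy() for w in self.weights])

    def to_json(self) -> dict:
        return {
            "input_dim": self.topology.input_dim,
            "hidden_sizes": list(self.topology.hidden_sizes),
            "weights": [w.tolist() for w in self.weights],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "MLP":
        topo = MLPTopology(obj["input_dim"], tuple(obj["hidden_sizes"]))
        return cls(topo, [np.asarray(w, dtype=float) for w in obj["weights"]])


@dataclass
class TrainingConfig:
    algorithm: str = "rprop_plus"
    lr: float = 0.001
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    stop_threshold: float = 0.01   # on max |dE/dw|
    #: steps before the stop criterion is first tested; near-zero gradients
    #: at initialization signal the predict-the-mean saddle of the SSE, not
    #: a minimum, and sign-driven rules walk out of it within a few dozen
    #: steps when given the chance
    min_steps: int = 50
    max_steps: int = 100_000
    seed: int | None = None

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if not (0.0 < self.eta_minus < 1.0 < self.eta_plus):
            raise ValueError("require 0 < eta_minus < 1 < eta_plus")
        if not (0.0 < self.delta_min <= self.delta0 <= self.delta_max):
            raise ValueError("require 0 < delta_min <= delta0 <= delta_max")


@dataclass
class RpropState:
    delta: list[np.ndarray]
    prev_grad: list[np.ndarray]
    prev_dw: list[np.ndarray]

    @classmethod
    def initial(cls, mlp: MLP, config: TrainingConfig) -> "RpropState":
        return cls(
            delta=[np.full_like(w, config.delta0) for w in mlp.weights],
            prev_grad=[np.zeros_like(w) for w in mlp.weights],
            prev_dw=[np.zeros_like(w) for w in mlp.weights],
        )


def init_mlp(topology: MLPTopology, seed: int | None = None) -> MLP:
    """Seed-reproducible uniform(-0.5, 0.5) weight initialization."""
    rng = np.random.default_rng(seed)
    sizes = topology.layer_sizes
    weights = [rng.uniform(-0.5, 0.5, size=(fan_in + 1, fan_out))
               for fan_in, fan_out in zip(sizes[:-1], sizes[1:])]
    return MLP(topology, weights)


def _forward_activations(mlp: MLP, X: np.ndarray) -> list[np.ndarray]:
    a = np.atleast_2d(np.asarray(X, dtype=float))
    if a.shape[1] != mlp.topology.input_dim:
        raise ValueError(
            f"input dimension {a.shape[1]} != topology input_dim {mlp.topology.input_dim}")
    activations = [a]
    for w in mlp.weights:
        a_bias = np.hstack([a, np.ones((a.shape[0], 1))])
        a = _logistic(a_bias @ w)
        activations.append(a)
    return activations


def forward(mlp: MLP, x: np.ndarray) -> np.ndarray | float:
    """Feed-forward output in (0, 1); scalar for a single input vector."""
    x = np.asarray(x, dtype=float)
    out = _forward_activations(mlp, x)[-1]
    if x.ndim == 1:
        return float(out[0, 0])
    return out[:, 0]


def sse(mlp: MLP, X: np.ndarray, Y: np.ndarray) -> float:
    yhat = _forward_activations(mlp, X)[-1][:, 0]
    return 0.5 * float(((np.asarray(Y, dtype=float) - yhat) ** 2).sum())


def gradient(mlp: MLP, X: np.ndarray, Y: np.ndarray) -> list[np.ndarray]:
    """Exact backpropagated gradient of E = 1/2 sum (y - yhat)^2."""
    Y = np.atleast_1d(np.asarray(Y, dtype=float))
    if Y.size == 0:
        raise ValueError("batch is empty")
    acts = _forward_activations(mlp, X)
    yhat = acts[-1]
    # dE/da at the output, then propagate through logistic units
    delta = (yhat - Y.reshape(-1, 1)) * yhat * (1.0 - yhat)
    grads: list[np.ndarray] = [None] * len(mlp.weights)
    for l in range(len(mlp.weights) - 1, -1, -1):
        a_bias = np.hstack([acts[l], np.ones((acts[l].shape[0], 1))])
        grads[l] = a_bias.T @ delta
        if l > 0:
            back = delta @ mlp.weights[l][:-1].T  # drop bias row
            delta = back * acts[l] * (1.0 - acts[l])
    return grads


# --------------------------------------------------------------------------
# update rules (operate elementwise on matching lists of weight arrays)
# --------------------------------------------------------------------------

def backprop_update(grad: list[np.ndarray], config: TrainingConfig) -> list[np.ndarray]:
    return [-config.lr * g for g in grad]


def _adapt_deltas(state: RpropState, grad: list[np.ndarray], config: TrainingConfig):
    """Per-weight step-size adaptation shared by all resilient variants."""
    new_delta, grow, shrink = [], [], []
    for d, pg, g in zip(state.delta, state.prev_grad, grad):
        s = pg * g
        up = s > 0
        dn = s < 0
        nd = d.copy()
        nd[up] = np.minimum(d[up] * config.eta_plus, config.delta_max)
        nd[dn] = np.maximum(d[dn] * config.eta_minus, config.delta_min)
        new_delta.append(nd)
        grow.append(up)
        shrink.append(dn)
    return new_delta, grow, shrink


def rprop_plus_update(state: RpropState, grad: list[np.ndarray],
                      config: TrainingConfig) -> tuple[list[np.ndarray], RpropState]:
    """Resilient backpropagation with weight backtracking.

    Sign agreement grows Delta by eta+ and steps -sign(grad)*Delta; a sign
    flip shrinks Delta by eta-, reverts the previous update and zeroes the
    stored derivative; a zero product leaves Delta unchanged.
    """
    new_delta, _, shrink = _adapt_deltas(state, grad, config)
    dw, new_pg = [], []
    for nd, dn, g, pdw in zip(new_delta, shrink, grad, state.prev_dw):
        step = -np.sign(g) * nd
        step[dn] = -pdw[dn]
        pg = g.copy()
        pg[dn] = 0.0
        dw.append(step)
        new_pg.append(pg)
    return dw, RpropState(new_delta, new_pg, [d.copy() for d in dw])


def rprop_minus_update(state: RpropState, grad: list[np.ndarray],
                       config: TrainingConfig) -> tuple[list[np.ndarray], RpropState]:
    """Resilient backpropagation without backtracking."""
    new_delta, _, _ = _adapt_deltas(state, grad, config)
    dw = [-np.sign(g) * nd for g, nd in zip(grad, new_delta)]
    return dw, RpropState(new_delta, [g.copy() for g in grad], [d.copy() for d in dw])


def grprop_update(state: RpropState, grad: list[np.ndarray], config: TrainingConfig,
                  variant: str) -> tuple[list[np.ndarray], RpropState]:
    """Globally convergent variants ('sag' and 'slr').

    Behaves as rprop_minus except that sign-flipped weights step with a
    shared magnitude: the smallest Delta among weights of smallest absolute
    derivative (sag) or the smallest Delta over all weights (slr).
    """
    if variant not in ("sag", "slr"):
        raise ValueError("variant must be 'sag' or 'slr'")
    new_delta, _, shrink = _adapt_deltas(state, grad, config)
    all_delta = np.concatenate([d.ravel() for d in new_delta])
    if variant == "slr":
        shared = float(all_delta.min())
    else:
        all_grad = np.abs(np.concatenate([g.ravel() for g in grad]))
        gmin = all_grad.min()
        mask = all_grad <= gmin + 1e-15
        shared = float(all_delta[mask].min())
    dw = []
    for g, nd, dn in zip(grad, new_delta, shrink):
        step = -np.sign(g) * nd
        step[dn] = -np.sign(g[dn]) * shared
        dw.append(step)
    return dw, RpropState(new_delta, [g.copy() for g in grad], [d.copy() for d in dw])


def _apply_rule(state: RpropState, grad: list[np.ndarray], config: TrainingConfig):
    alg = config.algorithm
    if alg == "backprop":
        return backprop_update(grad, config), state
    if alg == "rprop_plus":
        return rprop_plus_update(state, grad, config)
    if alg == "rprop_minus":
        return rprop_minus_update(state, grad, config)
    return grprop_update(state, grad, config, alg)


@dataclass
class TrainingTrace:
    errors: list[float]
    steps: int
    converged: bool


class DivergenceError(RuntimeError):
    pass


def train(topology: MLPTopology, X: np.ndarray, Y: np.ndarray,
          config: TrainingConfig) -> tuple[MLP, TrainingTrace]:
    """Full-batch training until max |dE/dw| < stop_threshold or max_steps."""
    Y = np.asarray(Y, dtype=float)
    if len(set(Y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    mlp = init_mlp(topology, config.seed)
    state = RpropState.initial(mlp, config)
    errors: list[float] = []
    converged = False
    step = 0
    for step in range(1, config.max_steps + 1):
        grad = gradient(mlp, X, Y)
        err = sse(mlp, X, Y)
        errors.append(err)
        if err > 1e6:
            raise DivergenceError(
                f"training error diverged ({err:.3g}); try a smaller eta_plus")
        gmax = max(float(np.abs(g).max()) for g in grad)
        if gmax < config.stop_threshold and step > config.min_steps:
            converged = True
            break
        dw, state = _apply_rule(state, grad, config)
        for w, d in zip(mlp.weights, dw):
            w += d
    return mlp, TrainingTrace(errors=errors, steps=step, converged=converged)


# --------------------------------------------------------------------------
# randomized evaluation protocol
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Misclassification / consistency per (algorithm, reduction) cell."""

    misclassification: dict[tuple[str, str], float]
    consistency: dict[tuple[str, str], float]
    modal_predictions: dict[tuple[str, str], tuple[bool, ...]]
    query_ids: list[str]
    n_iter: int

    def to_json(self) -> dict:
        def keyed(d):
            return {f"{alg}|{red}": (list(v) if isinstance(v, tuple) else v)
                    for (alg, red), v in sorted(d.items())}
        return {
            "n_iter": self.n_iter,
            "query_ids": list(self.query_ids),
            "misclassification": keyed(self.misclassification),
            "consistency": keyed(self.consistency),
            "modal_predictions": keyed(self.modal_predictions),
        }

    def best_cell(self) -> tuple[str, str]:
        """Lowest misclassification; ties broken by highest consistency."""
        return min(self.misclassification,
                   key=lambda k: (self.misclassification[k], -self.consistency[k], k))


def _labeled_arrays(red: ReducedFeatures) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    labels = np.array(red.labels)
    labeled = labels != "query"
    y = (labels[labeled] == "agonist").astype(float)
    return red.coordinates[labeled], y, red.coordinates[~labeled]


def evaluate_protocol(features: dict[str, ReducedFeatures], topology: MLPTopology,
                      config: TrainingConfig | None = None,
                      algorithms: tuple[str, ...] = ALGORITHMS,
                      n_iter: int = 1000, test_size: int = 4,
                      seed: int | None = None, n_restarts: int = 5) -> EvaluationReport:
    """Randomized train/test protocol over the algorithm x reduction grid.

    For every cell, ``n_iter`` random splits hold out ``test_size`` labeled
    compounds; misclassification is the mean fraction of held-out compounds
    mislabeled at the 0.5 threshold, and consistency is the fraction of
    iterations whose query-prediction vector equals the modal vector.
    Splits that leave a class empty in training are resampled.

    Training within an iteration is repeated with fresh seeded
    initializations (up to ``n_restarts`` extra attempts) until the
    training set is fit without error, keeping the best attempt otherwise;
    this discards optimization accidents (local minima of the SSE surface)
    so that each iteration scores a classifier that actually learned its
    training data.
    """
    base = config or TrainingConfig()
    query_ids = None
    for red in features.values():
        qids = [c for c, l in zip(red.compound_ids, red.labels) if l == "query"]
        query_ids = qids if query_ids is None else query_ids
    ss = np.random.SeedSequence(seed)
    mis: dict[tuple[str, str], float] = {}
    cons: dict[tuple[str, str], float] = {}
    modal: dict[tuple[str, str], tuple[bool, ...]] = {}

    for red_name in sorted(features):
        red = features[red_name]
        Xl, yl, Xq = _labeled_arrays(red)
        if min((yl == 1).sum(), (yl == 0).sum()) < 2:
            raise ValueError("need at least 2 compounds per class")
        if test_size >= len(yl):
            raise ValueError("test_size must leave at least one training compound")
        topo = replace(topology, input_dim=Xl.shape[1]) if \
            topology.input_dim != Xl.shape[1] else topology
        for alg in algorithms:
            rng = np.random.default_rng(ss.spawn(1)[0])
            errs = np.empty(n_iter)
            preds: Counter[tuple[bool, ...]] = Counter()
            for it in range(n_iter):
                for _ in range(1000):
                    test_idx = rng.choice(len(yl), size=test_size, replace=False)
                    train_mask = np.ones(len(yl), dtype=bool)
                    train_mask[test_idx] = False
                    if len(set(yl[train_mask].tolist())) == 2:
                        break
                else:
                    raise RuntimeError("could not draw a split with both classes in training")
                best = None
                for _ in range(n_restarts + 1):
                    cfg = replace(base, algorithm=alg,
                                  seed=int(rng.integers(2 ** 31 - 1)))
                    cand, _ = train(topo, Xl[train_mask], yl[train_mask], cfg)
                    fit_err = float(((forward(cand, Xl[train_mask]) >= 0.5)
                                     != (yl[train_mask] == 1)).mean())
                    if best is None or fit_err < best[0]:
                        best = (fit_err, cand)
                    if fit_err == 0.0:
                        break
                mlp = best[1]
                yhat = forward(mlp, Xl[~train_mask]) >= 0.5
                errs[it] = float((yhat != (yl[~train_mask] == 1)).mean())
                qv = tuple(bool(b) for b in (forward(mlp, Xq) >= 0.5)) if len(Xq) else ()
                preds[qv] += 1
            cell = (alg, red_name)
            mis[cell] = float(errs.mean())
            mode, count = preds.most_common(1)[0]
            cons[cell] = count / n_iter
            modal[cell] = mode
    return EvaluationReport(mis, cons, modal, query_ids or [], n_iter)


def predict_labels(mlp: MLP, coordinates: np.ndarray,
                   compound_ids: list[str] | None = None) -> list[dict]:
    """Binomial neuroprotection call per query compound.

    A score >= 0.5 (ties inclusive) labels the compound neuroprotective.
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    scores = forward(mlp, coords)
    scores = np.atleast_1d(scores)
    ids = compound_ids or [f"Q{i + 1}" for i in range(len(scores))]
    return [{"compound": c, "score": float(s), "neuroprotective": bool(s >= 0.5)}
            for c, s in zip(ids, scores)]


def save_model(mlp: MLP, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(mlp.to_json(), indent=2))
    return path


def load_model(path: str | Path) -> MLP:
    return MLP.from_json(json.loads(Path(path).read_text()))
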