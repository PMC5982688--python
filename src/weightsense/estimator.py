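"""Feed-forward weight regression trained by resilient propagation.

A three-layer network (inputs -> one tanh hidden layer -> one linear output
neuron, the weight in kilograms) is trained full-batch with the iRPROP-
variant of resilient propagation on a squared-error loss with optional L2
weight decay.  Inputs and the target are standardized on the training rows.
A validation split held out at subject granularity drives early stopping:
training aborts once the validation error has not improved for ``patience``
epochs and the best-validation weights are returned.

Evaluation metrics follow the field's conventions: per-subject relative
error ``eps_i = (truth_i - estimate_i) / truth_i`` (positive = the system
underestimates), mean absolute error ``MAE = mean |truth - estimate|`` in
kg, mean squared error in kg^2, and the share of subjects within the
±5/10/20 % relative-error bands (±10 % being the clinical rtPA dosing
tolerance).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NetworkConfig",
    "TrainedModel",
    "Metrics",
    "split_by_subject",
    "train",
    "predict",
    "evaluate",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Topology and training hyper-parameters.

    The RPROP step-size schedule uses the standard published constants
    (eta+ = 1.2, eta- = 0.5, initial step 0.1, clipped to [1e-6, 50]).
    """

    n_hidden: int = 16
    weight_decay: float = 1e-4
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.1
    delta_min: float = 1e-6
    delta_max: float = 50.0
    max_epochs: int = 2000
    patience: int = 50
    seed: int = 0
    train_fraction: float = 0.70
    validation_fraction: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if not (self.eta_minus < 1.0 < self.eta_plus):
            raise ValueError("need eta_minus < 1 < eta_plus")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")


@dataclass
class TrainedModel:
    """Weights, topology and feature scaling of a trained network."""

    w1: np.ndarray  # (n_hidden, n_features)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    feature_names: Tuple[str, ...]
    config: NetworkConfig = field(default_factory=NetworkConfig)

    def to_json(self) -> str:
        payload = {
            "topology": {
                "n_inputs": int(self.w1.shape[1]),
                "n_hidden": int(self.w1.shape[0]),
                "activation": "tanh",
                "output": "linear",
            },
            "weights": {
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2,
            },
            "scaling": {
                "x_mean": self.x_mean.tolist(),
                "x_sd": self.x_sd.tolist(),
                "y_mean": self.y_mean,
                "y_sd": self.y_sd,
            },
            "feature_names": list(self.feature_names),
            "config": asdict(self.config),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        p = json.loads(text)
        return cls(
            w1=np.asarray(p["weights"]["w1"], dtype=np.float64),
            b1=np.asarray(p["weights"]["b1"], dtype=np.float64),
            w2=np.asarray(p["weights"]["w2"], dtype=np.float64),
            b2=float(p["weights"]["b2"]),
            x_mean=np.asarray(p["scaling"]["x_mean"], dtype=np.float64),
            x_sd=np.asarray(p["scaling"]["x_sd"], dtype=np.float64),
            y_mean=float(p["scaling"]["y_mean"]),
            y_sd=float(p["scaling"]["y_sd"]),
            feature_names=tuple(p["feature_names"]),
            config=NetworkConfig(**p["config"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def split_by_subject(
    person_ids: Sequence[int], fraction: float = 0.70, seed: int = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Partition frames into train/test boolean masks at SUBJECT granularity.

    ``round(fraction * n_subjects)`` subjects (clamped so both sides stay
    non-empty) are assigned to training; every frame of a subject lands on
    the same side.  Deterministic given the seed.
    """
    ids = np.asarray(person_ids)
    subjects = np.unique(ids)
    n = len(subjects)
    if n < 2:
        raise ValueError(f"need >= 2 subjects to split, got {n}")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    shuffled = subjects[rng.permutation(n)]
    train_subjects = set(shuffled[:n_train].tolist())
    train_mask = np.array([i in train_subjects for i in ids])
    return train_mask, ~train_mask


def _forward(model_w, x):
    w1, b1, w2, b2 = model_w
    h = np.tanh(x @ w1.T + b1)
    return h @ w2 + b2, h


def _loss_and_grads(params, x, y, lam):
    w1, b1, w2, b2 = params
    n = len(x)
    out, h = _forward(params, x)
    err = out - y
    loss = 0.5 * np.mean(err**2)
    if lam > 0:
        loss += lam * (np.sum(w1**2) + np.sum(w2**2))
    g_out = err / n  # d loss / d out
    g_w2 = h.T @ g_out + 2.0 * lam * w2
    g_b2 = np.array([g_out.sum()])
    g_h = np.outer(g_out, w2)
    g_pre = g_h * (1.0 - h**2)
    g_w1 = g_pre.T @ x + 2.0 * lam * w1
    g_b1 = g_pre.sum(axis=0)
    return loss, (g_w1, g_b1, g_w2, g_b2)


def _rprop_step(params, grads, prev_grads, deltas, cfg: NetworkConfig):
    """One iRPROP- update in place; returns updated prev_grads."""
    new_prev = []
    for p, g, pg, d in zip(params, grads, prev_grads, deltas):
        sign_change = g * pg
        grow = sign_change > 0
        shrink = sign_change < 0
        d[grow] = np.minimum(d[grow] * cfg.eta_plus, cfg.delta_max)
        d[shrink] = np.maximum(d[shrink] * cfg.eta_minus, cfg.delta_min)
        g = g.copy()
        g[shrink] = 0.0  # iRPROP-: forget the gradient after a sign flip
        p -= np.sign(g) * d
        new_prev.append(g)
    return new_prev


def train(
    features: np.ndarray,
    weights_kg: np.ndarray,
    cfg: NetworkConfig = NetworkConfig(),
    person_ids: Optional[Sequence[int]] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> TrainedModel:
    """Train the three-layer network on a (rows x features) matrix.

    ``person_ids``, when given, make the internal early-stopping validation
    split subject-disjoint; otherwise rows are held out at random.  The
    returned model carries the weights of the best validation epoch.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("features must be a 2D matrix")
    y = np.asarray(weights_kg, dtype=np.float64).reshape(-1)
    if len(x) != len(y):
        raise ValueError("features and targets disagree in length")
    if len(x) < 2:
        raise ValueError("need >= 2 training rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values; mask or impute first")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite target values")

    rng = np.random.default_rng(cfg.seed)
    n, d = x.shape

    # validation split for early stopping
    val_mask = np.zeros(n, dtype=bool)
    if cfg.validation_fraction > 0:
        if person_ids is not None and len(np.unique(person_ids)) >= 3:
            tr_mask, va_mask = split_by_subject(
                person_ids, 1.0 - cfg.validation_fraction, seed=cfg.seed + 1
            )
            val_mask = va_mask
        elif n >= 10:
            n_val = max(1, int(round(cfg.validation_fraction * n)))
            val_mask[rng.permutation(n)[:n_val]] = True
    fit_mask = ~val_mask

    x_mean = x[fit_mask].mean(axis=0)
    x_sd = x[fit_mask].std(axis=0)
    x_sd[x_sd == 0] = 1.0
    y_mean = float(y[fit_mask].mean())
    y_sd = float(y[fit_mask].std())
    if y_sd == 0:
        y_sd = 1.0
    xs = (x - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    nh = cfg.n_hidden
    limit1 = 1.0 / np.sqrt(d)
    limit2 = 1.0 / np.sqrt(nh)
    params = [
        rng.uniform(-limit1, limit1, size=(nh, d)),
        np.zeros(nh),
        rng.uniform(-limit2, limit2, size=nh),
        np.zeros(1),
    ]
    deltas = [np.full_like(p, cfg.delta0, dtype=np.float64) for p in params]
    prev_grads = [np.zeros_like(p, dtype=np.float64) for p in params]

    x_fit, y_fit = xs[fit_mask], ys[fit_mask]
    x_val, y_val = xs[val_mask], ys[val_mask]
    use_val = len(x_val) > 0

    best = [p.copy() for p in params]
    best_err = np.inf
    stall = 0
    for _ in range(cfg.max_epochs):
        _, grads = _loss_and_grads(params, x_fit, y_fit, cfg.weight_decay)
        prev_grads = _rprop_step(params, grads, prev_grads, deltas, cfg)
        if use_val:
            out, _ = _forward(params, x_val)
            err = float(np.mean((out - y_val) ** 2))
        else:
            out, _ = _forward(params, x_fit)
            err = float(np.mean((out - y_fit) ** 2))
        if err < best_err - 1e-12:
            best_err = err
            best = [p.copy() for p in params]
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break

    w1, b1, w2, b2 = best
    return TrainedModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2[0]),
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        feature_names=tuple(feature_names) if feature_names is not None else tuple(),
        config=cfg,
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Forward pass: features (rows x inputs, or a single row) -> kg."""
    x = np.asarray(features, dtype=np.float64)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != model.w1.shape[1]:
        raise ValueError(
            f"model expects {model.w1.shape[1]} features, got {x.shape[1]}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    xs = (x - model.x_mean) / model.x_sd
    out, _ = _forward((model.w1, model.b1, model.w2, model.b2), xs)
    kg = out * model.y_sd + model.y_mean
    return float(kg[0]) if single else kg


@dataclass
class Metrics:
    """Per-subject relative errors and the derived summary statistics."""

    relative_errors: np.ndarray
    mean_rel: float
    sd_rel: float
    min_rel: float
    max_rel: float
    mae: float
    mse: float
    pct_within_5: float
    pct_within_10: float
    pct_within_20: float

    def as_dict(self) -> dict:
        return {
            "relative_error_min_pct": 100 * self.min_rel,
            "relative_error_max_pct": 100 * self.max_rel,
            "relative_error_mean_pct": 100 * self.mean_rel,
            "relative_error_sd_pct": 100 * self.sd_rel,
            "in_range_5_pct": self.pct_within_5,
            "in_range_10_pct": self.pct_within_10,
            "in_range_20_pct": self.pct_within_20,
            "mae_kg": self.mae,
            "mse_kg2": self.mse,
        }


def evaluate(predictions: np.ndarray, truths: np.ndarray) -> Metrics:
    """Relative-error, MAE/MSE and in-range statistics.

    ``eps_i = (truth_i - prediction_i) / truth_i`` so a positive relative
    error means the system underestimates.
    """
    pred = np.asarray(predictions, dtype=np.float64).reshape(-1)
    truth = np.asarray(truths, dtype=np.float64).reshape(-1)
    if len(pred) != len(truth) or len(pred) == 0:
        raise ValueError("predictions and truths must have equal, nonzero length")
    if np.any(truth == 0):
        raise ValueError("ground-truth weights must be nonzero")
    e = truth - pred
    eps = e / truth
    within = lambda r: float(np.mean(np.abs(eps) <= r) * 100.0)
    return Metrics(
        relative_errors=eps,
        mean_rel=float(eps.mean()),
        sd_rel=float(eps.std()),
        min_rel=float(eps.min()),
        max_rel=float(eps.max()),
        mae=float(np.mean(np.abs(e))),
        mse=float(np.mean(e**2)),
        pct_within_5=within(0.05),
        pct_within_10=within(0.10),
        pct_within_20=within(0.20),
    )
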