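"""Online passive-aggressive binary classifier (PA-I / PA-II) with hinge loss.

The classifier keeps a linear decision function f(x) = w.x + b and learns one
sample at a time: when the hinge loss max(0, 1 - y f(x)) is zero it stays
passive; otherwise it takes the smallest step that would restore a unit
margin, capped by the aggressiveness hyper-parameter C (PA-I) or softened by
it (PA-II).  The bias is treated as a unit pseudo-feature, so the update step
is tau = min(C, loss / (||x||^2 + 1)) for PA-I and
tau = loss / (||x||^2 + 1 + 1/(2C)) for PA-II, with w <- w + tau y x and
b <- b + tau y.

Because a margin-based rule on raw minutes/bpm/ms scales is meaningless,
training goes through a z-score :class:`Standardizer` fitted on the generic
training stream only and frozen for personalization and evaluation.

The sequential training loop is numba-compiled; ``pa_update`` is the plain
numpy single-step form and the test-suite pins the two to each other and to
an independent reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ValidationError

_VARIANT_CODES = {"PA-I": 1, "PA-II": 2}


@dataclass
class Standardizer:
    """Per-feature z-score transform; zero-variance features get scale 1."""

    loc: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        loc = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
        return cls(loc=loc, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.loc) / self.scale


@dataclass
class PAModel:
    """Linear decision function with PA update state."""

    weights: np.ndarray
    bias: float = 0.0
    aggressiveness_c: float = 1.0
    variant: str = "PA-I"
    n_updates: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.aggressiveness_c <= 0:
            raise ValidationError("aggressiveness C must be > 0")
        if self.variant not in _VARIANT_CODES:
            raise ValidationError(f"unknown PA variant {self.variant!r}")

    @classmethod
    def zeros(cls, n_features: int, aggressiveness_c: float = 1.0,
              variant: str = "PA-I") -> "PAModel":
        return cls(weights=np.zeros(n_features), bias=0.0,
                   aggressiveness_c=aggressiveness_c, variant=variant)

    def copy(self) -> "PAModel":
        return PAModel(weights=self.weights.copy(), bias=self.bias,
                       aggressiveness_c=self.aggressiveness_c,
                       variant=self.variant, n_updates=self.n_updates)


def hinge_loss(margin: float) -> float:
    """max(0, 1 - margin); zero for confidently correct classifications."""
    return max(0.0, 1.0 - float(margin))


def decision_score(model: PAModel, x: np.ndarray) -> np.ndarray | float:
    """w.x + b for a single sample or a (n, d) batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.weights.shape[0]:
        raise ValidationError(
            f"feature dimension {x.shape[-1]} does not match model "
            f"dimension {model.weights.shape[0]}")
    s = x @ model.weights + model.bias
    return float(s) if np.ndim(s) == 0 else s


def predict(model: PAModel, x: np.ndarray) -> np.ndarray | int:
    """sign(w.x + b) in {-1, +1}; a score of exactly 0 predicts +1."""
    s = decision_score(model, x)
    if np.ndim(s) == 0:
        return 1 if s >= 0 else -1
    return np.where(np.asarray(s) >= 0, 1, -1)


def pa_update(model: PAModel, x: np.ndarray, y: int) -> PAModel:
    """One passive-aggressive step on (x, y); mutates and returns ``model``.

    ``x`` must already be standardized; ``y`` is -1 or +1.
    """
    if y not in (-1, 1):
        raise ValidationError(f"label must be -1 or +1, got {y!r}")
    x = np.asarray(x, dtype=float)
    loss = hinge_loss(y * decision_score(model, x))
    if loss > 0.0:
        denom = float(x @ x) + 1.0  # bias as unit pseudo-feature
        if model.variant == "PA-I":
            tau = min(model.aggressiveness_c, loss / denom)
        else:
            tau = loss / (denom + 0.5 / model.aggressiveness_c)
        model.weights += tau * y * x
        model.bias += tau * y
        model.n_updates += 1
    return model


@njit(cache=True)
def _pa_run_avg(X, y, w, b, C, variant_code):  # pragma: no cover - numba kernel
    """One PA pass that also accumulates the running state average."""
    w_sum = np.zeros_like(w)
    b_sum = 0.0
    n_updates = 0
    for i in range(X.shape[0]):
        xi = X[i]
        margin = y[i] * (np.dot(w, xi) + b)
        loss = 1.0 - margin
        if loss > 0.0:
            denom = np.dot(xi, xi) + 1.0
            if variant_code == 1:
                tau = loss / denom
                if tau > C:
                    tau = C
            else:
                tau = loss / (denom + 0.5 / C)
            for j in range(w.shape[0]):
                w[j] += tau * y[i] * xi[j]
            b += tau * y[i]
            n_updates += 1
        w_sum += w
        b_sum += b
    return b, n_updates, w_sum / X.shape[0], b_sum / X.shape[0]


@njit(cache=True)
def _pa_run(X, y, w, b, C, variant_code):  # pragma: no cover - numba kernel
    n_updates = 0
    for i in range(X.shape[0]):
        xi = X[i]
        margin = y[i] * (np.dot(w, xi) + b)
        loss = 1.0 - margin
        if loss > 0.0:
            denom = np.dot(xi, xi) + 1.0
            if variant_code == 1:
                tau = loss / denom
                if tau > C:
                    tau = C
            else:
                tau = loss / (denom + 0.5 / C)
            for j in range(w.shape[0]):
                w[j] += tau * y[i] * xi[j]
            b += tau * y[i]
            n_updates += 1
    return b, n_updates


def _run_stream(model: PAModel, X: np.ndarray, y: np.ndarray) -> PAModel:
    """Apply sequential PA updates over a standardized stream (fast path)."""
    X = np.ascontiguousarray(X, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    b, n_upd = _pa_run(X, y, model.weights, model.bias,
                       model.aggressiveness_c, _VARIANT_CODES[model.variant])
    model.bias = float(b)
    model.n_updates += int(n_upd)
    return model


def _to_pm1(labels: np.ndarray) -> np.ndarray:
    """Map {0,1} (or already {-1,+1}) labels onto {-1.,+1.}."""
    y = np.asarray(labels)
    return np.where(y > 0, 1.0, -1.0)


def fit_generic(X: np.ndarray, labels: np.ndarray,
                aggressiveness_c: float = 1.0, epochs: int = 5,
                seed: int | np.random.SeedSequence = 0, variant: str = "PA-I",
                average_final_epoch: bool = True,
                ) -> tuple[PAModel, Standardizer]:
    """Train a generic PA model on a pooled labeled stream.

    Fits the standardizer on the training stream only, then runs ``epochs``
    sequential passes, reshuffling the stream each epoch with ``seed``.
    Deterministic for a fixed seed.  Raises if the stream is empty or holds a
    single class.

    ``average_final_epoch`` applies the standard online-to-batch conversion:
    the returned weights/bias are the running average of the model states
    visited during the last epoch rather than the endpoint of the update
    trajectory.  The endpoint of an online PA run is a single draw from an
    oscillating process and is dominated by the last few samples seen; the
    trajectory average is a far lower-variance summary of the same process
    and is used for the generic model that personalization starts from.
    Set to ``False`` for the raw final state.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(X) == 0:
        raise ValidationError("training stream must be a non-empty 2-D array")
    y = _to_pm1(labels)
    if np.unique(y).size < 2:
        raise ValidationError("training stream must contain both classes")
    std = Standardizer.fit(X)
    Xs = std.transform(X)
    model = PAModel.zeros(X.shape[1], aggressiveness_c, variant)
    rng = np.random.default_rng(seed)
    vcode = _VARIANT_CODES[variant]
    for epoch in range(int(epochs)):
        idx = rng.permutation(len(Xs))
        Xe = np.ascontiguousarray(Xs[idx])
        ye = y[idx]
        if average_final_epoch and epoch == int(epochs) - 1:
            b, n_upd, w_avg, b_avg = _pa_run_avg(
                Xe, ye, model.weights, model.bias, aggressiveness_c, vcode)
            model.weights = w_avg
            model.bias = float(b_avg)
            model.n_updates += int(n_upd)
        else:
            _run_stream(model, Xe, ye)
    return model, std


def fine_tune(model: PAModel, personal_X: np.ndarray,
              personal_labels: np.ndarray,
              standardizer: Standardizer) -> PAModel:
    """Personalize a *copy* of the generic model on one subject's first sessions.

    A single chronological pass of PA updates; single-class personal data is
    allowed (and typical).  With zero samples the copy is returned unchanged.
    """
    tuned = model.copy()
    personal_X = np.asarray(personal_X, dtype=float)
    if len(personal_X) == 0:
        return tuned
    Xs = standardizer.transform(personal_X)
    return _run_stream(tuned, Xs, _to_pm1(personal_labels))


def save_model(model: PAModel, standardizer: Standardizer, path) -> None:
    """Serialize model + standardizer to a plain-text key=value file."""
    def _vec(v):
        return ",".join(repr(float(x)) for x in v)
    lines = [
        f"variant={model.variant}",
        f"aggressiveness_c={model.aggressiveness_c!r}",
        f"bias={model.bias!r}",
        f"n_updates={model.n_updates}",
        f"weights={_vec(model.weights)}",
        f"loc={_vec(standardizer.loc)}",
        f"scale={_vec(standardizer.scale)}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> tuple[PAModel, Standardizer]:
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                k, _, v = line.partition("=")
                kv[k] = v
    def _vec(s):
        return np.array([float(x) for x in s.split(",")])
    model = PAModel(weights=_vec(kv["weights"]), bias=float(kv["bias"]),
                    aggressiveness_c=float(kv["aggressiveness_c"]),
                    variant=kv["variant"], n_updates=int(kv["n_updates"]))
    std = Standardizer(loc=_vec(kv["loc"]), scale=_vec(kv["scale"]))
    return model, std
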