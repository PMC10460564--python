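"""Bernoulli-Bernoulli restricted Boltzmann machine over miRNA profiles.

Each small molecule contributes one binary observation — its row of the
association matrix, a length-``nm`` vector saying which miRNAs it is
known to regulate.  A two-layer energy model

    E(v, h) = - sum_i b_i v_i - sum_j c_j h_j - sum_ij w_ij v_i h_j

with ``nm`` visible and ``s`` hidden units is trained on those rows by
k-step contrastive divergence (CD-k).  Prediction is a deterministic
two-step mean-field pass: hidden probabilities from the observed row,
then visible probabilities from the hidden probabilities; the
reconstructed visible probabilities are the association scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .data_model import AssociationMatrix, ScoreMatrix
from .errors import ConfigError, ValidationError


@dataclass(frozen=True)
class RBMParams:
    """Weights ``W`` (nm x s), visible biases ``b`` (nm), hidden biases ``c`` (s)."""

    W: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        b = np.asarray(self.b, dtype=float)
        c = np.asarray(self.c, dtype=float)
        if W.ndim != 2 or b.shape != (W.shape[0],) or c.shape != (W.shape[1],):
            raise ValidationError(
                f"inconsistent parameter shapes W{W.shape} b{b.shape} c{c.shape}"
            )
        for arr in (W, b, c):
            if not np.isfinite(arr).all():
                raise ValidationError("RBM parameters must be finite")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def save(self, path: str | Path) -> None:
        """Serialize to a portable JSON file (shapes + arrays)."""
        payload = {
            "n_visible": self.n_visible,
            "n_hidden": self.n_hidden,
            "W": self.W.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RBMParams":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            W=np.array(d["W"], dtype=float),
            b=np.array(d["b"], dtype=float),
            c=np.array(d["c"], dtype=float),
        )


@dataclass(frozen=True)
class RBMConfig:
    """Training hyperparameters.

    ``hidden_units`` is the model-selection knob (candidate grid 20..120
    in steps of 10); the optimizer settings are plain SGD CD-k defaults.
    """

    hidden_units: int = 40
    learning_rate: float = 0.05
    epochs: int = 100
    batch_size: int = 10
    cd_steps: int = 1
    seed: int = 0
    init_sd: float = 0.01

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be positive")
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be non-negative")
        if self.epochs < 1 or self.batch_size < 1 or self.cd_steps < 1:
            raise ConfigError("epochs, batch_size and cd_steps must be positive")


def energy(params: RBMParams, v: np.ndarray, h: np.ndarray) -> float:
    """Energy of a joint (visible, hidden) configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValidationError("state vector lengths do not match parameters")
    return float(-params.b @ v - params.c @ h - v @ params.W @ h)


def hidden_activation(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """P(h_j = 1 | v) = logistic(sum_i w_ij v_i + c_j), vectorized over rows."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != params.n_visible:
        raise ValidationError("visible vector length mismatch")
    return expit(v @ params.W + params.c)


def visible_activation(params: RBMParams, h: np.ndarray) -> np.ndarray:
    """P(v_i = 1 | h) = logistic(sum_j w_ij h_j + b_i), vectorized over rows."""
    h = np.asarray(h, dtype=float)
    if h.shape[-1] != params.n_hidden:
        raise ValidationError("hidden vector length mismatch")
    return expit(h @ params.W.T + params.b)


def initialize_params(nm: int, cfg: RBMConfig, rng: np.random.Generator) -> RBMParams:
    """Zero-mean Gaussian weights (sd ``init_sd``), zero biases."""
    return RBMParams(
        W=rng.normal(0.0, cfg.init_sd, size=(nm, cfg.hidden_units)),
        b=np.zeros(nm),
        c=np.zeros(cfg.hidden_units),
    )


def train_cd(
    assoc: AssociationMatrix,
    cfg: RBMConfig | None = None,
    init: RBMParams | None = None,
) -> RBMParams:
    """Train by CD-k on the SM row-observations; deterministic given the seed.

    Hidden samples drive the Gibbs chain; the gradient statistics use
    probabilities (for both hidden activations and the visible
    reconstruction) to reduce estimator variance.  Optimization is plain
    minibatch SGD without momentum or weight decay.
    """
    cfg = cfg or RBMConfig()
    V = assoc.A.astype(float)
    ns, nm = V.shape
    if ns == 0 or nm == 0:
        raise ValidationError("association matrix is empty")
    rng = np.random.default_rng(cfg.seed)
    params = init or initialize_params(nm, cfg, rng)
    W, b, c = params.W.copy(), params.b.copy(), params.c.copy()
    lr = cfg.learning_rate

    for _ in range(cfg.epochs):
        order = rng.permutation(ns)
        for start in range(0, ns, cfg.batch_size):
            v0 = V[order[start : start + cfg.batch_size]]
            nb = v0.shape[0]
            h0_prob = expit(v0 @ W + c)
            hk_sample = (rng.random(h0_prob.shape) < h0_prob).astype(float)
            for _step in range(cfg.cd_steps):
                vk_prob = expit(hk_sample @ W.T + b)
                vk_sample = (rng.random(vk_prob.shape) < vk_prob).astype(float)
                hk_prob = expit(vk_sample @ W + c)
                hk_sample = (rng.random(hk_prob.shape) < hk_prob).astype(float)
            # statistics use the chain's last probabilities, not samples
            hk_prob = expit(vk_prob @ W + c)
            W += lr * ((v0.T @ h0_prob) - (vk_prob.T @ hk_prob)) / nb
            b += lr * (v0 - vk_prob).mean(axis=0)
            c += lr * (h0_prob - hk_prob).mean(axis=0)
    return RBMParams(W=W, b=b, c=c)


def reconstruction_error(params: RBMParams, assoc: AssociationMatrix) -> float:
    """Mean squared error between the rows and their mean-field reconstruction."""
    V = assoc.A.astype(float)
    recon = visible_activation(params, hidden_activation(params, V))
    return float(np.mean((V - recon) ** 2))


def rbm_predict(params: RBMParams, assoc: AssociationMatrix) -> ScoreMatrix:
    """Deterministic two-step reconstruction of every SM row.

    Step 1: hidden probabilities P_j from the observed binary row.
    Step 2: visible probabilities from P — the predicted association
    scores, strictly inside (0, 1).
    """
    if assoc.n_mirnas != params.n_visible:
        raise ValidationError(
            f"model has {params.n_visible} visible units but matrix has "
            f"{assoc.n_mirnas} miRNAs"
        )
    P = hidden_activation(params, assoc.A.astype(float))
    scores = visible_activation(params, P)
    return ScoreMatrix(sms=assoc.sms, mirnas=assoc.mirnas, values=scores)
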