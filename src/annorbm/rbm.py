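"""A binary restricted Boltzmann machine trained by contrastive divergence.

An RBM is a bipartite undirected energy model over binary visible units
``v`` (here: GO terms, one unit per term) and binary hidden units ``h``
(latent functional features).  Its energy is

    E(v, h) = - sum_i a_i v_i - sum_j b_j h_j - sum_ij v_i W_ij h_j

with joint distribution P(v, h) = exp(-E(v, h)) / Z.  Because the graph is
bipartite, the conditionals factorise into logistic functions, which makes
block Gibbs sampling — and hence contrastive divergence (CD) learning —
cheap.  CD-k replaces the intractable model expectation in the
log-likelihood gradient ``<v_i h_j>_data - <v_i h_j>_model`` with the
expectation under a k-step Gibbs reconstruction of the data.

Exact enumeration routines (partition function, log-likelihood, gradient)
are provided for tiny instances; they are the oracles against which the CD
machinery is validated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logsumexp

from .errors import ValidationError

logger = logging.getLogger(__name__)

_SIGMOID_CLIP = 500.0  # expit saturates far earlier; guards exp overflow
_ENUM_GUARD = 20  # max c + m for exact enumeration


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function with clipped input; outputs strictly inside (0,1)."""
    out = expit(np.clip(x, -_SIGMOID_CLIP, _SIGMOID_CLIP))
    tiny = np.finfo(float).tiny
    return np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)


@dataclass
class RBMParams:
    """Weights ``W`` (c x m), visible biases ``a`` (c), hidden biases ``b`` (m)."""

    W: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.a.ndim != 1 or self.b.ndim != 1:
            raise ValidationError("W must be 2-d; a and b must be 1-d")
        c, m = self.W.shape
        if self.a.shape != (c,) or self.b.shape != (m,):
            raise ValidationError(
                f"inconsistent shapes: W {self.W.shape}, a {self.a.shape}, "
                f"b {self.b.shape}"
            )
        for arr in (self.W, self.a, self.b):
            if not np.isfinite(arr).all():
                raise ValidationError("parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def copy(self) -> "RBMParams":
        return RBMParams(self.W.copy(), self.a.copy(), self.b.copy())


@dataclass
class TrainConfig:
    """Hyperparameters for CD training.

    Defaults follow the standard recipe for annotation matrices: learning
    rate 0.01 for 25 epochs, minibatches of 100, L2 weight decay on the
    connection weights, dropout 0.5 on the hidden layer, and weights
    initialised uniformly on (0, 1).  ``gaussian`` initialisation (zero-mean,
    sigma 0.01) is available as a first-class alternative; all-positive
    initial weights can slow mixing on small instances.
    """

    learning_rate: float = 0.01
    epochs: int = 25
    cd_steps: int = 1
    batch_size: int = 100
    weight_decay: float = 1e-4
    dropout_rate: float = 0.5
    init: str = "uniform01"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValidationError("epochs must be non-negative")
        if self.cd_steps < 1:
            raise ValidationError("cd_steps must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValidationError("weight_decay must be non-negative")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.init not in ("uniform01", "gaussian"):
            raise ValidationError("init must be 'uniform01' or 'gaussian'")

    def replace(self, **kwargs) -> "TrainConfig":
        return replace(self, **kwargs)


def energy(v: np.ndarray, h: np.ndarray, params: RBMParams) -> float:
    """Energy of one joint configuration (v, h)."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (params.n_visible,) or h.shape != (params.n_hidden,):
        raise ValidationError(
            f"state shapes {v.shape}/{h.shape} do not match parameters "
            f"({params.n_visible} visible, {params.n_hidden} hidden)"
        )
    return float(-params.a @ v - params.b @ h - v @ params.W @ h)


def prob_h_given_v(v: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(h_j = 1 | v) = sigma(b_j + sum_i v_i W_ij), row-wise over a batch."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != params.n_visible:
        raise ValidationError(
            f"visible batch has {v.shape[1]} columns, expected {params.n_visible}"
        )
    return sigmoid(params.b + v @ params.W)


def prob_v_given_h(h: np.ndarray, params: RBMParams) -> np.ndarray:
    """P(v_i = 1 | h) = sigma(a_i + sum_j h_j W_ij), row-wise over a batch."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != params.n_hidden:
        raise ValidationError(
            f"hidden batch has {h.shape[1]} columns, expected {params.n_hidden}"
        )
    return sigmoid(params.a + h @ params.W.T)


def cd_update(
    v_batch: np.ndarray,
    params: RBMParams,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One contrastive-divergence parameter update on a minibatch.

    Hidden states are sampled from the data conditional; the reconstruction
    is sampled binary from the visible conditional; both correlation terms
    use hidden *probabilities* (the standard low-variance estimator).  A
    single Bernoulli dropout mask per minibatch is applied to the hidden
    units of both phases, so no activation rescaling is needed during
    training.  L2 weight decay acts on W only.

    Returns ``(dW, da, db)`` — deltas already scaled by the learning rate.
    """
    v_batch = np.atleast_2d(np.asarray(v_batch, dtype=float))
    n = v_batch.shape[0]
    if n == 0:
        raise ValidationError("empty minibatch")
    eps = config.learning_rate

    if config.dropout_rate > 0:
        mask = (rng.random(params.n_hidden) >= config.dropout_rate).astype(float)
    else:
        mask = np.ones(params.n_hidden)

    h_prob = prob_h_given_v(v_batch, params) * mask
    h_state = (rng.random(h_prob.shape) < h_prob).astype(float)
    v_recon = v_batch
    for _ in range(config.cd_steps):
        v_prob = prob_v_given_h(h_state, params)
        v_recon = (rng.random(v_prob.shape) < v_prob).astype(float)
        h_prob_recon = prob_h_given_v(v_recon, params) * mask
        h_state = (rng.random(h_prob_recon.shape) < h_prob_recon).astype(float)

    dW = eps * (v_batch.T @ h_prob - v_recon.T @ h_prob_recon) / n
    dW -= eps * config.weight_decay * params.W
    da = eps * (v_batch - v_recon).mean(axis=0)
    db = eps * (h_prob - h_prob_recon).mean(axis=0)
    return dW, da, db


def initial_params(
    n_visible: int, n_hidden: int, config: TrainConfig, rng: np.random.Generator
) -> RBMParams:
    """Initial weights per the configured scheme; biases start at zero."""
    if config.init == "uniform01":
        W = rng.random((n_visible, n_hidden))
    else:
        W = rng.normal(0.0, 0.01, size=(n_visible, n_hidden))
    return RBMParams(W, np.zeros(n_visible), np.zeros(n_hidden))


def reconstruction_cross_entropy(data: np.ndarray, params: RBMParams) -> float:
    """Mean-field reconstruction cross-entropy, the per-epoch progress signal."""
    h = prob_h_given_v(data, params)
    v_prob = prob_v_given_h(h, params)
    return float(
        -(data * np.log(v_prob) + (1 - data) * np.log(1 - v_prob)).mean()
    )


def train_rbm(
    data: np.ndarray,
    config: TrainConfig,
    *,
    rng: np.random.Generator | None = None,
    allow_probabilities: bool = False,
) -> RBMParams:
    """Train one RBM by CD on binary data.

    Rows are shuffled once per epoch and consumed in minibatches.  Set
    ``allow_probabilities`` when the input rows are activation probabilities
    from a lower layer (greedy stack training) rather than raw binary data.

    Returns the final parameters; per-epoch mean reconstruction
    cross-entropy is logged at debug level.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValidationError("training data is empty")
    n_hidden = max(1, data.shape[1] // 2)
    return train_rbm_sized(
        data, n_hidden, config, rng=rng, allow_probabilities=allow_probabilities
    )


def train_rbm_sized(
    data: np.ndarray,
    n_hidden: int,
    config: TrainConfig,
    *,
    rng: np.random.Generator | None = None,
    allow_probabilities: bool = False,
) -> RBMParams:
    """As :func:`train_rbm` but with an explicit hidden-layer width."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.size == 0:
        raise ValidationError("training data is empty")
    if allow_probabilities:
        if data.min() < 0 or data.max() > 1:
            raise ValidationError("training data must lie in [0, 1]")
    elif not np.isin(data, (0.0, 1.0)).all():
        raise ValidationError("training data must be binary")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, c = data.shape
    params = initial_params(c, n_hidden, config, rng)
    logger.debug(
        "epoch 0: reconstruction cross-entropy %.4f",
        reconstruction_cross_entropy(data, params),
    )
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = data[order[start : start + config.batch_size]]
            dW, da, db = cd_update(batch, params, config, rng)
            params.W += dW
            params.a += da
            params.b += db
        logger.debug(
            "epoch %d: reconstruction cross-entropy %.4f",
            epoch + 1,
            reconstruction_cross_entropy(data, params),
        )
    return params


# ---------------------------------------------------------------------------
# Exact enumeration oracles (tiny instances only)
# ---------------------------------------------------------------------------


def _check_enum_guard(params: RBMParams) -> None:
    if params.n_visible + params.n_hidden > _ENUM_GUARD:
        raise ValidationError(
            f"exact enumeration refused: c + m = "
            f"{params.n_visible + params.n_hidden} exceeds the guard of "
            f"{_ENUM_GUARD} units"
        )


def _all_states(n: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


def exact_partition(params: RBMParams) -> float:
    """Partition function Z by summing exp(-E) over all 2^(c+m) states."""
    _check_enum_guard(params)
    return float(np.exp(_log_partition(params)))


def _log_partition(params: RBMParams) -> float:
    V = _all_states(params.n_visible)
    H = _all_states(params.n_hidden)
    # -E for every (v, h) pair, as a 2^c x 2^m table
    neg_e = (V @ params.a)[:, None] + (H @ params.b)[None, :] + V @ params.W @ H.T
    return float(logsumexp(neg_e))


def exact_log_likelihood(data: np.ndarray, params: RBMParams) -> float:
    """Mean log P(v) over the rows of *data*, by exact enumeration."""
    _check_enum_guard(params)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    H = _all_states(params.n_hidden)
    # log sum_h exp(-E(v, h)) for each data row
    neg_e = (data @ params.a)[:, None] + (H @ params.b)[None, :] + data @ params.W @ H.T
    return float(np.mean(logsumexp(neg_e, axis=1)) - _log_partition(params))


def exact_gradient(
    data: np.ndarray, params: RBMParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact log-likelihood gradient: data minus model expectations.

    The W gradient is ``<v_i h_j>_data - <v_i h_j>_model`` with the hidden
    units marginalised analytically under the data distribution and the
    model expectation computed by full enumeration; bias gradients are the
    corresponding first moments.
    """
    _check_enum_guard(params)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]

    h_prob = prob_h_given_v(data, params)
    dW_data = data.T @ h_prob / n
    da_data = data.mean(axis=0)
    db_data = h_prob.mean(axis=0)

    V = _all_states(params.n_visible)
    H = _all_states(params.n_hidden)
    neg_e = (V @ params.a)[:, None] + (H @ params.b)[None, :] + V @ params.W @ H.T
    logZ = logsumexp(neg_e)
    P = np.exp(neg_e - logZ)  # joint over (v, h)
    dW_model = V.T @ P @ H
    da_model = V.T @ P.sum(axis=1)
    db_model = H.T @ P.sum(axis=0)

    return dW_data - dW_model, da_data - da_model, db_data - db_model
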