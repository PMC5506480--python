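"""Greedy layer-wise training of an RBM stack and mean-field reconstruction.

The deep model is a stack of RBMs.  The first RBM is trained on the binary
annotation matrix; each subsequent RBM is trained on the hidden activation
probabilities of the layer beneath it.  Hidden widths halve layer by layer
(5 hidden layers by default, widths clamped at 1 for tiny term sets).  After
greedy training the stack is unfolded: a deterministic mean-field pass
propagates probabilities up through every layer and back down through the
tied (transposed) weights, and the downward visible probabilities are the
predicted association scores.  There is no global fine-tuning pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ValidationError
from .rbm import (
    RBMParams,
    TrainConfig,
    prob_h_given_v,
    prob_v_given_h,
    reconstruction_cross_entropy,
    train_rbm_sized,
)

logger = logging.getLogger(__name__)

_ARCHIVE_FORMAT = "annorbm-drbm"
_ARCHIVE_VERSION = 1

DEFAULT_DEPTH = 5


def plan_layer_sizes(n_visible: int, depth: int = DEFAULT_DEPTH) -> list[int]:
    """Unit counts [c, m1, ..., mL]: each hidden width is half the previous.

    Widths are floor-divided and clamped at 1 so very small term sets remain
    trainable.
    """
    if n_visible < 2:
        raise ValidationError("need at least 2 visible units")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    sizes = [n_visible]
    for _ in range(depth):
        sizes.append(max(1, sizes[-1] // 2))
    return sizes


@dataclass
class DRBMStack:
    """An ordered list of greedily trained RBMs plus the layer-size plan."""

    layers: list[RBMParams]
    sizes: list[int]
    config: TrainConfig

    def __post_init__(self):
        if len(self.layers) != len(self.sizes) - 1:
            raise ValidationError("layer count does not match size plan")
        for t, layer in enumerate(self.layers):
            if (layer.n_visible, layer.n_hidden) != (self.sizes[t], self.sizes[t + 1]):
                raise ValidationError(
                    f"layer {t} has shape {layer.W.shape}, expected "
                    f"({self.sizes[t]}, {self.sizes[t + 1]})"
                )

    #: Optional row/column index lists recorded at save time.
    proteins: list[str] | None = None
    terms: list[str] | None = None

    @property
    def depth(self) -> int:
        return len(self.layers)

    def save(self, path, proteins=None, terms=None) -> None:
        """Serialise the stack (sizes, weights, config, indices) as JSON."""
        payload = {
            "format": _ARCHIVE_FORMAT,
            "version": _ARCHIVE_VERSION,
            "sizes": self.sizes,
            "config": asdict(self.config),
            "proteins": proteins if proteins is not None else self.proteins,
            "terms": terms if terms is not None else self.terms,
            "layers": [
                {"W": l.W.tolist(), "a": l.a.tolist(), "b": l.b.tolist()}
                for l in self.layers
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "DRBMStack":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != _ARCHIVE_FORMAT:
            raise ValidationError(f"{path} is not a DRBM model archive")
        if payload.get("version") != _ARCHIVE_VERSION:
            raise ValidationError(
                f"unsupported model archive version {payload.get('version')}"
            )
        layers = [
            RBMParams(np.array(l["W"]), np.array(l["a"]), np.array(l["b"]))
            for l in payload["layers"]
        ]
        return cls(
            layers,
            payload["sizes"],
            TrainConfig(**payload["config"]),
            proteins=payload.get("proteins"),
            terms=payload.get("terms"),
        )


def train_stack(
    data: np.ndarray,
    config: TrainConfig,
    depth: int = DEFAULT_DEPTH,
) -> DRBMStack:
    """Greedy layer-by-layer training of the RBM stack.

    Layer 1 sees the binary annotation matrix; the hidden activation
    probabilities of each trained layer are the input of the next.
    Deterministic given ``config.seed``.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    sizes = plan_layer_sizes(data.shape[1], depth)
    rng = np.random.default_rng(config.seed)
    layers: list[RBMParams] = []
    x = data
    for t in range(depth):
        params = train_rbm_sized(
            x, sizes[t + 1], config, rng=rng, allow_probabilities=t > 0
        )
        layers.append(params)
        logger.info(
            "layer %d (%d -> %d): reconstruction cross-entropy %.4f",
            t + 1,
            sizes[t],
            sizes[t + 1],
            reconstruction_cross_entropy(x, params),
        )
        x = np.asarray(prob_h_given_v(x, params))
    return DRBMStack(layers, sizes, config)


def reconstruct(stack: DRBMStack, v: np.ndarray) -> np.ndarray:
    """Deterministic mean-field reconstruction scores in [0, 1].

    Probabilities (never samples) are propagated up through every layer and
    back down through the transposed weights.  Hidden activations are scaled
    by the dropout keep-probability, matching the expected activation seen
    during training.  Entry (s, i) is the predicted association score of
    protein s with term i.
    """
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != stack.sizes[0]:
        raise ValidationError(
            f"input has {v.shape[1]} columns, model expects {stack.sizes[0]}"
        )
    keep = 1.0 - stack.config.dropout_rate
    x = v
    for layer in stack.layers:
        x = np.asarray(prob_h_given_v(x, layer)) * keep
    for layer in reversed(stack.layers):
        x = np.asarray(prob_v_given_h(x, layer))
    return x


def predict_missing(stack: DRBMStack, train_matrix) -> list[tuple[str, str, float]]:
    """Score every unannotated (protein, term) pair, sorted by score.

    Known annotations (1-entries of the training matrix) are excluded; the
    returned list covers exactly the zero-entries, descending by score.
    """
    scores = reconstruct(stack, train_matrix.values)
    rows, cols = np.nonzero(train_matrix.values == 0)
    out = [
        (train_matrix.proteins[i], train_matrix.terms[j], float(scores[i, j]))
        for i, j in zip(rows.tolist(), cols.tolist())
    ]
    out.sort(key=lambda r: (-r[2], r[0], r[1]))
    return out
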