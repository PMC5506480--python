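"""Model/Results front end for annotation completion.

:class:`DeepRBM` wraps the greedy RBM-stack machinery in the familiar
modelling idiom: build the model from an annotation matrix (or DataFrame),
call :meth:`DeepRBM.fit`, and receive a :class:`DeepRBMResults` carrying the
trained stack, the reconstruction scores, candidate predictions and a
``summary()`` table.  The underlying functional API lives in
:mod:`annorbm.drbm`, :mod:`annorbm.rbm` and :mod:`annorbm.metrics`.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .annotations import AnnotationMatrix, TemporalSplit
from .drbm import DEFAULT_DEPTH, DRBMStack, predict_missing, reconstruct, train_stack
from .errors import ValidationError
from .metrics import EvaluationReport, evaluate_split, term_frequency_baseline
from .rbm import TrainConfig


class DeepRBM:
    """Deep restricted Boltzmann machine over a binary annotation matrix.

    Parameters
    ----------
    matrix
        A true-path-closed binary :class:`AnnotationMatrix` (proteins in
        rows, GO terms in columns).
    depth
        Number of hidden layers; widths halve layer by layer.
    config
        CD training hyperparameters; defaults follow the standard recipe
        (learning rate 0.01, 25 epochs, dropout 0.5, L2 weight decay).

    Examples
    --------
    >>> model = DeepRBM(matrix, depth=2, config=TrainConfig(seed=7))
    >>> res = model.fit()
    >>> res.summary()            # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: AnnotationMatrix,
        depth: int = DEFAULT_DEPTH,
        config: TrainConfig | None = None,
    ):
        if not isinstance(matrix, AnnotationMatrix):
            raise ValidationError("matrix must be an AnnotationMatrix")
        self.matrix = matrix
        self.depth = depth
        self.config = config or TrainConfig()

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "DeepRBM":
        """Build from a 0/1 DataFrame (index: proteins, columns: terms)."""
        matrix = AnnotationMatrix(
            [str(p) for p in frame.index],
            [str(t) for t in frame.columns],
            frame.to_numpy(),
        )
        return cls(matrix, **kwargs)

    def fit(self, **config_overrides) -> "DeepRBMResults":
        """Greedy layer-wise CD training; returns a results object."""
        config = (
            replace(self.config, **config_overrides)
            if config_overrides
            else self.config
        )
        stack = train_stack(self.matrix.values, config, self.depth)
        return DeepRBMResults(self, stack)


class DeepRBMResults:
    """Fitted stack plus reconstruction scores and evaluation helpers."""

    def __init__(self, model: DeepRBM, stack: DRBMStack):
        self.model = model
        self.stack = stack
        self._scores: np.ndarray | None = None

    @property
    def scores(self) -> np.ndarray:
        """Mean-field association scores for every (protein, term) pair."""
        if self._scores is None:
            self._scores = reconstruct(self.stack, self.model.matrix.values)
        return self._scores

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=self.model.matrix.proteins,
            columns=self.model.matrix.terms,
        )

    def predict_missing(self) -> list[tuple[str, str, float]]:
        """Candidate new annotations: all zero-pairs, sorted by score."""
        return predict_missing(self.stack, self.model.matrix)

    def evaluate(self, split: TemporalSplit, threshold: float = 0.5) -> EvaluationReport:
        """Score the fit against annotations added in a newer snapshot."""
        if split.train.terms != self.model.matrix.terms:
            raise ValidationError("split term universe differs from the model's")
        return evaluate_split(self.scores, split, threshold=threshold)

    def baseline_report(self, split: TemporalSplit, threshold: float = 0.5) -> EvaluationReport:
        """Same evaluation for the term-frequency (prevalence) baseline."""
        return evaluate_split(
            term_frequency_baseline(split.train), split, threshold=threshold
        )

    def save(self, path) -> None:
        self.stack.save(path)

    def summary(self) -> pd.DataFrame:
        """Architecture and training summary as a tidy table."""
        cfg = self.stack.config
        rows = [
            ("proteins", self.model.matrix.shape[0]),
            ("terms (visible units)", self.model.matrix.shape[1]),
            ("layer sizes", " -> ".join(map(str, self.stack.sizes))),
            ("hidden layers", self.stack.depth),
            ("learning rate", cfg.learning_rate),
            ("epochs", cfg.epochs),
            ("CD steps", cfg.cd_steps),
            ("batch size", cfg.batch_size),
            ("weight decay (L2)", cfg.weight_decay),
            ("dropout", cfg.dropout_rate),
            ("init", cfg.init),
            ("seed", cfg.seed),
            ("mean score", float(self.scores.mean())),
        ]
        return pd.DataFrame(rows, columns=["field", "value"]).set_index("field")
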