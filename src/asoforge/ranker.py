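"""Scikit-learn style estimator facade over the EGT ranker.

``EGTRanker`` wraps pair construction, featurization, training and
scoring behind the familiar ``fit``/``predict`` contract so the model
composes with sklearn model selection and pipelines. ``X`` is a
sequence of (AsoSequence, ModificationPattern) tuples — the natural
sample unit of a pattern screen — ``y`` the inhibition rates, and
``groups`` the assay-condition keys that delimit valid comparisons.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .chemistry import FragmentLibrary
from .egt import EGTConfig, RankerModel, score_batch
from .training import EfficacyRecord, FeatureCache, make_pairs, train


class EGTRanker(BaseEstimator):
    """Edge-augmented graph-transformer ranking model for ASO variants.

    Parameters mirror :class:`~asoforge.egt.EGTConfig` plus the training
    protocol. Scores returned by :meth:`predict` are relative: higher
    means higher predicted efficacy within one sequence/condition, but
    the absolute scale is arbitrary.

    Attributes (after fitting)
    --------------------------
    model_ : RankerModel
        The trained parameter collection.
    version_id_ : str
        Content hash of the trained parameters and config.
    loss_history_ : list of float
        Mean training hinge loss per epoch.
    n_pairs_ : int
        Number of training pairs constructed from (X, y, groups).
    """

    def __init__(
        self,
        num_layers: int = 2,
        num_heads: int = 4,
        node_dim: int = 32,
        edge_dim: int = 8,
        ffn_mult: int = 2,
        dropout: float = 0.0,
        margin: float = 0.1,
        learning_rate: float = 1e-3,
        batch_pairs: int = 4,
        epochs: int = 30,
        min_gap: float = 0.05,
        patience: int = 10,
        max_pairs: int | None = None,
        seed: int = 0,
    ):
        self.num_layers = num_layers
        self.num_heads = num_heads
        self.node_dim = node_dim
        self.edge_dim = edge_dim
        self.ffn_mult = ffn_mult
        self.dropout = dropout
        self.margin = margin
        self.learning_rate = learning_rate
        self.batch_pairs = batch_pairs
        self.epochs = epochs
        self.min_gap = min_gap
        self.patience = patience
        self.max_pairs = max_pairs
        self.seed = seed

    def _config(self) -> EGTConfig:
        return EGTConfig(
            num_layers=self.num_layers,
            num_heads=self.num_heads,
            node_dim=self.node_dim,
            edge_dim=self.edge_dim,
            ffn_mult=self.ffn_mult,
            dropout=self.dropout,
            margin=self.margin,
            learning_rate=self.learning_rate,
            batch_pairs=self.batch_pairs,
            seed=self.seed,
        )

    def fit(self, X, y, groups=None, library: FragmentLibrary | None = None):
        """Train on a pattern screen.

        Parameters
        ----------
        X : sequence of (AsoSequence, ModificationPattern)
        y : array-like of float in [0, 1]
            Measured inhibition rates.
        groups : array-like of str, optional
            Condition keys; samples are only compared within a group.
            Defaults to a single shared condition.
        """
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if groups is None:
            groups = ["condition-0"] * len(X)
        records = [
            EfficacyRecord(
                sequence=seq, pattern=pat, condition_key=str(g), inhibition=float(v)
            )
            for (seq, pat), g, v in zip(X, groups, y)
        ]
        pairs = make_pairs(records, min_gap=self.min_gap)
        if self.max_pairs is not None and len(pairs) > self.max_pairs:
            rng = np.random.default_rng(self.seed)
            keep = rng.choice(len(pairs), size=self.max_pairs, replace=False)
            pairs = [pairs[i] for i in sorted(keep)]
        self._feature_cache = FeatureCache(library)
        self.model_ = train(
            pairs,
            config=self._config(),
            epochs=self.epochs,
            seed=self.seed,
            patience=self.patience,
            feature_cache=self._feature_cache,
        )
        self.version_id_ = self.model_.version_id
        self.loss_history_ = list(self.model_.loss_history)
        self.n_pairs_ = len(pairs)
        return self

    def predict(self, X) -> np.ndarray:
        """Score (sequence, pattern) samples; higher = better predicted."""
        if not hasattr(self, "model_"):
            raise RuntimeError("EGTRanker is not fitted")
        cache = getattr(self, "_feature_cache", None) or FeatureCache()
        feats = [cache(seq, pat) for seq, pat in X]
        out = np.empty(len(feats))
        step = max(2 * self.batch_pairs, 1)
        for start in range(0, len(feats), step):
            out[start : start + step] = score_batch(
                self.model_, feats[start : start + step]
            )
        return out

    def score(self, X, y, groups=None) -> float:
        """Spearman rank correlation between predictions and ``y``."""
        from scipy.stats import spearmanr

        return float(spearmanr(self.predict(X), np.asarray(y, dtype=float))[0])
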