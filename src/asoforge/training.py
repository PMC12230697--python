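"""Pair construction and learning-to-rank training.

Absolute inhibition rates are not comparable across assays (cell line,
dosage, transfection efficiency all shift the scale), so the ranker is
trained only on *within-condition comparisons*: ordered pairs of
records that share a nucleotide sequence and a condition key but differ
in modification pattern. Each violated pair contributes a hinge penalty
``max(0, t + f(x_neg) - f(x_pos))`` and parameters are updated with
RMSProp.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _autodiff as ad
from .chemistry import FragmentLibrary, build_oligo_smiles, smiles_to_graph
from .egt import EGTConfig, RankerModel, RMSProp, hinge_loss_tensor
from .errors import Divergence
from .featurize import GraphFeatures, featurize, pad_batch
from .notation import parse_notation, pattern_to_notation
from .patterns import ModificationPattern
from .sequences import AsoSequence, validate_sequence

logger = logging.getLogger("asoforge.training")

RECORD_COLUMNS = ("sequence", "pattern", "condition_key", "inhibition")


@dataclass(frozen=True)
class EfficacyRecord:
    """One assay outcome: a modified variant and its inhibition rate."""

    sequence: AsoSequence
    pattern: ModificationPattern
    condition_key: str
    inhibition: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.inhibition <= 1.0:
            raise ValueError(f"inhibition {self.inhibition} outside [0, 1]")
        if self.pattern.length != self.sequence.length:
            raise ValueError("pattern/sequence length mismatch")


@dataclass(frozen=True)
class TrainingPair:
    """An ordered comparison: ``pos`` beat ``neg`` in the same assay."""

    pos: EfficacyRecord
    neg: EfficacyRecord

    def __post_init__(self) -> None:
        if str(self.pos.sequence) != str(self.neg.sequence):
            raise ValueError("pair members must share a sequence")
        if self.pos.condition_key != self.neg.condition_key:
            raise ValueError("pair members must share a condition")
        if self.pos.pattern == self.neg.pattern:
            raise ValueError("pair members must differ in pattern")
        if not self.pos.inhibition > self.neg.inhibition:
            raise ValueError("pos must have strictly higher inhibition")


def make_pairs(
    records: list[EfficacyRecord], min_gap: float = 0.05
) -> list[TrainingPair]:
    """All within-group ordered pairs whose inhibition gap exceeds ``min_gap``.

    Records are grouped by (sequence, condition_key); within each group
    every unordered pair with ``|y_a - y_b| > min_gap`` yields one
    :class:`TrainingPair` with the higher-inhibition member as ``pos``.
    The default gap of 0.05 suppresses pairs whose ordering is likely
    measurement noise. Order of output is deterministic: groups in
    sorted key order, pairs in record order.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be nonnegative")
    groups: dict[tuple[str, str], list[EfficacyRecord]] = {}
    for rec in records:
        groups.setdefault((str(rec.sequence), rec.condition_key), []).append(rec)
    pairs: list[TrainingPair] = []
    for key in sorted(groups):
        members = groups[key]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                ra, rb = members[a], members[b]
                if ra.pattern == rb.pattern:
                    continue
                if abs(ra.inhibition - rb.inhibition) <= min_gap:
                    continue
                hi, lo = (ra, rb) if ra.inhibition > rb.inhibition else (rb, ra)
                pairs.append(TrainingPair(pos=hi, neg=lo))
    return pairs


class FeatureCache:
    """Memoizes the chemistry -> graph -> features pipeline per variant."""

    def __init__(self, library: FragmentLibrary | None = None):
        self.library = library
        self._store: dict[tuple, GraphFeatures] = {}

    def __call__(
        self, seq: AsoSequence, pattern: ModificationPattern
    ) -> GraphFeatures:
        key = (str(seq), pattern.sugar, pattern.linkage)
        if key not in self._store:
            smiles = build_oligo_smiles(seq, pattern, library=self.library)
            self._store[key] = featurize(smiles_to_graph(smiles))
        return self._store[key]


def train(
    pairs: list[TrainingPair],
    config: EGTConfig | None = None,
    epochs: int = 30,
    seed: int = 0,
    validation_pairs: list[TrainingPair] | None = None,
    patience: int = 10,
    feature_cache: FeatureCache | None = None,
    model: RankerModel | None = None,
    epoch_callback=None,
) -> RankerModel:
    """Fit the ranker on training pairs by minimizing the summed hinge loss.

    Pairs are shuffled each epoch (seeded) and consumed in minibatches
    of ``config.batch_pairs``; each step scores the 2x batch of graphs,
    averages the hinge losses and applies one RMSProp update. With
    ``validation_pairs``, training stops early once the validation mean
    hinge loss has not improved for ``patience`` epochs, returning the
    best parameters seen. ``epoch_callback(model, epoch)``, if given,
    runs after every epoch (e.g. for snapshotting or custom model
    selection). Fully reproducible given ``seed``.

    Raises
    ------
    Divergence
        If the training loss becomes non-finite.
    """
    if not pairs:
        raise ValueError("cannot train on an empty pair list")
    config = config or EGTConfig()
    cache = feature_cache or FeatureCache()
    if model is None:
        model = RankerModel.initialize(
            EGTConfig(**{**config.__dict__, "seed": seed})
        )
    config = model.config
    optimizer = RMSProp(model.params, learning_rate=config.learning_rate)
    rng = np.random.default_rng(seed + 1)

    feats = [
        (cache(p.pos.sequence, p.pos.pattern), cache(p.neg.sequence, p.neg.pattern))
        for p in pairs
    ]
    val_feats = None
    if validation_pairs:
        val_feats = [
            (cache(p.pos.sequence, p.pos.pattern), cache(p.neg.sequence, p.neg.pattern))
            for p in validation_pairs
        ]
    best_val = np.inf
    best_params = None
    stale = 0

    for epoch in range(epochs):
        order = rng.permutation(len(feats))
        t0 = time.time()
        losses: list[float] = []
        for start in range(0, len(order), config.batch_pairs):
            batch = [feats[i] for i in order[start : start + config.batch_pairs]]
            nodes, edges, mask = pad_batch(
                [f for fp, fn in batch for f in (fp, fn)]
            )
            scores = model.forward(nodes, edges, mask, training=True, rng=rng)
            n = len(batch)
            s = scores.reshape(n, 2)
            s_pos = ad.einsum("pk,k->p", s, ad.Tensor(np.array([1.0, 0.0], np.float32)))
            s_neg = ad.einsum("pk,k->p", s, ad.Tensor(np.array([0.0, 1.0], np.float32)))
            loss = hinge_loss_tensor(s_pos, s_neg, config.margin).mean()
            value = float(loss.data)
            if not np.isfinite(value):
                raise Divergence(f"non-finite training loss at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(value)
        mean_loss = float(np.mean(losses))
        model.loss_history.append(mean_loss)
        msg = f"epoch {epoch + 1}/{epochs}: mean hinge loss {mean_loss:.4f}"
        if val_feats is not None:
            val_loss = _mean_hinge(model, val_feats, config)
            msg += f", validation {val_loss:.4f}"
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.data.copy() for k, v in model.params.items()}
                stale = 0
            else:
                stale += 1
        logger.info("%s (%.1fs)", msg, time.time() - t0)
        if epoch_callback is not None:
            epoch_callback(model, epoch)
        if val_feats is not None and stale >= patience:
            logger.info("early stop at epoch %d", epoch + 1)
            break
    if best_params is not None:
        for k, v in model.params.items():
            v.data = best_params[k]
    return model


def _mean_hinge(model: RankerModel, pair_feats, config: EGTConfig) -> float:
    total = 0.0
    with ad.inference_mode():
        for start in range(0, len(pair_feats), config.batch_pairs):
            batch = pair_feats[start : start + config.batch_pairs]
            nodes, edges, mask = pad_batch(
                [f for fp, fn in batch for f in (fp, fn)]
            )
            s = model.forward(nodes, edges, mask).data.reshape(len(batch), 2)
            total += float(
                np.maximum(0.0, config.margin + s[:, 1] - s[:, 0]).sum()
            )
    return total / len(pair_feats)


# -- record file format ---------------------------------------------------


def write_records(path, records: list[EfficacyRecord]) -> None:
    """Write records as TSV with columns sequence, pattern, condition_key,
    inhibition; the pattern column uses the output notation grammar."""
    frame = pd.DataFrame(
        {
            "sequence": [str(r.sequence) for r in records],
            "pattern": [
                pattern_to_notation(r.sequence, r.pattern) for r in records
            ],
            "condition_key": [r.condition_key for r in records],
            "inhibition": [r.inhibition for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_records(path, max_length: int | None = None) -> list[EfficacyRecord]:
    """Read a TSV records file, validating every row.

    Sequences go through :func:`validate_sequence` and patterns through
    the notation parser; the parsed pattern must be consistent with the
    sequence column.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"condition_key": str})
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"records file missing columns {sorted(missing)}")
    records: list[EfficacyRecord] = []
    for row in frame.itertuples(index=False):
        kwargs = {} if max_length is None else {"max_length": max_length}
        seq = validate_sequence(row.sequence, **kwargs)
        parsed_seq, pattern = parse_notation(row.pattern)
        if str(parsed_seq) != str(seq):
            raise ValueError(
                f"pattern notation decodes to {parsed_seq}, row says {seq}"
            )
        records.append(
            EfficacyRecord(
                sequence=seq,
                pattern=pattern,
                condition_key=str(row.condition_key),
                inhibition=float(row.inhibition),
            )
        )
    return records
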