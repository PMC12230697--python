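import numpy as np
import pytest

from asoforge.egt import EGTConfig
from asoforge.errors import IllegalSymbol, NotationError
from asoforge.patterns import DNA, PS, ModificationPattern, enumerate_full_patterns
from asoforge.sequences import validate_sequence
from asoforge.training import (
    EfficacyRecord,
    FeatureCache,
    TrainingPair,
    make_pairs,
    read_records,
    train,
    write_records,
)
from tests.conftest import pattern_from_bits


def _record(seq, bits, condition, y, chem="LNA"):
    return EfficacyRecord(
        sequence=seq,
        pattern=pattern_from_bits(bits, chem),
        condition_key=condition,
        inhibition=y,
    )


@pytest.fixture(scope="module")
def at4():
    return validate_sequence("ATGC")


def test_make_pairs_all_comparisons(at4):
    records = [
        _record(at4, [1, 0, 0, 0], "c1", 0.9),
        _record(at4, [0, 1, 0, 0], "c1", 0.5),
        _record(at4, [0, 0, 1, 0], "c1", 0.1),
    ]
    pairs = make_pairs(records, min_gap=0.0)
    assert len(pairs) == 3
    assert all(p.pos.inhibition > p.neg.inhibition for p in pairs)


def test_make_pairs_respects_condition_groups(at4):
    records = [
        _record(at4, [1, 0, 0, 0], "c1", 0.9),
        _record(at4, [0, 1, 0, 0], "c2", 0.1),
    ]
    assert make_pairs(records, min_gap=0.0) == []


def test_make_pairs_gap_filter(at4):
    records = [
        _record(at4, [1, 0, 0, 0], "c1", 0.6),
        _record(at4, [0, 1, 0, 0], "c1", 0.5),
    ]
    assert make_pairs(records, min_gap=0.2) == []
    assert len(make_pairs(records, min_gap=0.05)) == 1


def test_make_pairs_empty_and_deterministic(at4):
    assert make_pairs([]) == []
    records = [
        _record(at4, [1, 0, 0, 0], "c1", 0.9),
        _record(at4, [0, 1, 0, 0], "c1", 0.2),
        _record(at4, [1, 1, 0, 0], "c0", 0.8),
        _record(at4, [0, 0, 1, 1], "c0", 0.3),
    ]
    p1, p2 = make_pairs(records), make_pairs(records)
    assert p1 == p2
    assert p1[0].pos.condition_key == "c0"  # groups in sorted order


def test_training_pair_invariants(at4):
    good = _record(at4, [1, 0, 0, 0], "c1", 0.9)
    with pytest.raises(ValueError):
        TrainingPair(pos=good, neg=good)  # same pattern
    with pytest.raises(ValueError):
        TrainingPair(pos=_record(at4, [0, 1, 0, 0], "c1", 0.5), neg=good)


@pytest.fixture(scope="module")
def training_pairs(at4):
    """50 pairs over the 16 patterns of a 4-mer, labelled by a planted rule."""
    rng = np.random.default_rng(5)
    patterns = list(enumerate_full_patterns(at4, "LNA"))
    weights = np.array([0.8, 0.4, -0.2, -0.6])
    records = []
    for pat in patterns:
        z = float(weights @ np.array(pat.modified_indicator()))
        y = 1.0 / (1.0 + np.exp(-z))
        records.append(
            EfficacyRecord(sequence=at4, pattern=pat, condition_key="c0",
                           inhibition=y)
        )
    pairs = make_pairs(records, min_gap=0.02)
    keep = sorted(rng.choice(len(pairs), size=50, replace=False))
    return [pairs[i] for i in keep]


def test_training_loss_descends(training_pairs, tiny_config):
    config = EGTConfig(**{**tiny_config.__dict__, "batch_pairs": 8})
    model = train(training_pairs, config=config, epochs=30, seed=3)
    history = model.loss_history
    assert len(history) == 30
    assert history[-1] < history[0]
    # epoch-averaged trend is non-increasing up to bounded noise
    assert min(history[-5:]) < min(history[:5])


def test_training_is_reproducible(training_pairs, tiny_config):
    m1 = train(training_pairs[:12], config=tiny_config, epochs=2, seed=9)
    m2 = train(training_pairs[:12], config=tiny_config, epochs=2, seed=9)
    assert m1.version_id == m2.version_id
    m3 = train(training_pairs[:12], config=tiny_config, epochs=2, seed=10)
    assert m3.version_id != m1.version_id


def test_contradictory_pairs_plateau_at_margin(at4, tiny_config):
    """Unseparable pairs cannot push the mean loss below the margin t."""
    a = _record(at4, [1, 0, 0, 0], "c1", 0.9)
    b = _record(at4, [0, 1, 0, 0], "c1", 0.1)
    a2 = _record(at4, [1, 0, 0, 0], "c2", 0.1)
    b2 = _record(at4, [0, 1, 0, 0], "c2", 0.9)
    pairs = make_pairs([a, b, a2, b2], min_gap=0.0)  # A>B and B>A
    assert len(pairs) == 2
    model = train(pairs, config=tiny_config, epochs=5, seed=0)
    assert model.loss_history[-1] >= tiny_config.margin - 1e-4


def test_train_rejects_empty():
    with pytest.raises(ValueError):
        train([], epochs=1, seed=0)


def test_early_stopping_restores_best(training_pairs, tiny_config):
    model = train(
        training_pairs[:16],
        config=tiny_config,
        epochs=6,
        seed=1,
        validation_pairs=training_pairs[16:24],
        patience=2,
    )
    assert len(model.loss_history) <= 6


def test_records_tsv_roundtrip(tmp_path, at4):
    records = [
        _record(at4, [1, 0, 1, 0], "plate-1", 0.73),
        _record(at4, [0, 0, 0, 0], "plate-1", 0.21),
        _record(at4, [1, 1, 1, 1], "plate-2", 0.5, chem="MOE"),
    ]
    path = tmp_path / "records.tsv"
    write_records(path, records)
    back = read_records(path)
    assert len(back) == 3
    for orig, new in zip(records, back):
        assert str(new.sequence) == str(orig.sequence)
        assert new.pattern.sugar == orig.pattern.sugar
        assert new.condition_key == orig.condition_key
        assert new.inhibition == pytest.approx(orig.inhibition)


def test_read_records_validates_rows(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "sequence\tpattern\tcondition_key\tinhibition\nATXG\tA*T*X*G\tc\t0.5\n"
    )
    with pytest.raises((IllegalSymbol, NotationError)):
        read_records(path)
    path.write_text(
        "sequence\tpattern\tcondition_key\tinhibition\nATGC\tA*T*G*G\tc\t0.5\n"
    )
    with pytest.raises(ValueError):
        read_records(path)  # notation decodes to a different sequence


def test_feature_cache_hits(at4):
    cache = FeatureCache()
    p = pattern_from_bits([1, 0, 0, 0], "LNA")
    f1 = cache(at4, p)
    f2 = cache(at4, p)
    assert f1 is f2
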