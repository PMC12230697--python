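import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

import asoforge._autodiff as ad
from asoforge.chemistry import mol_to_graph, smiles_to_graph
from asoforge.egt import (
    EGTConfig,
    RankerModel,
    RMSProp,
    hinge_loss_tensor,
    load_checkpoint,
    pairwise_hinge_loss,
    save_checkpoint,
    score,
    score_batch,
)
from asoforge.errors import CheckpointError, ShapeMismatch
from asoforge.featurize import featurize, pad_batch

MOLECULES = [
    "CCO", "c1ccccc1", "CC(=O)O", "C1CC1N", "O=P(O)(O)OC",
    "CS(=O)C", "CCN(CC)CC", "c1ccncc1", "OCC1OC(O)CC1O", "CC(C)C(N)C(=O)O",
]


@pytest.fixture(scope="module")
def model(tiny_config):
    return RankerModel.initialize(tiny_config)


def test_scores_are_finite_and_deterministic(model):
    f = featurize(smiles_to_graph("CCO"))
    s1, s2 = score(model, f), score(model, f)
    assert np.isfinite(s1) and s1 == s2


def test_score_invariant_under_atom_permutation(model, rng):
    for smiles in MOLECULES:
        mol = Chem.MolFromSmiles(smiles)
        perm = list(map(int, rng.permutation(mol.GetNumAtoms())))
        s = score(model, featurize(mol_to_graph(mol)))
        sp = score(model, featurize(mol_to_graph(Chem.RenumberAtoms(mol, perm))))
        assert abs(s - sp) < 1e-4


def test_batched_and_single_scores_agree(model):
    feats = [featurize(smiles_to_graph(s)) for s in MOLECULES[:4]]
    batched = score_batch(model, feats)
    singles = [score(model, f) for f in feats]
    assert np.allclose(batched, singles, atol=1e-5)


def test_shape_mismatch_rejected(model):
    with pytest.raises(ShapeMismatch):
        model.forward(np.zeros((1, 3, 99), np.float32),
                      np.zeros((1, 3, 3, 9), np.float32),
                      np.ones((1, 3), np.float32))


@pytest.mark.parametrize(
    "s_pos, s_neg, t, expected",
    [(1.0, 0.0, 0.1, 0.0), (0.5, 0.5, 0.1, 0.1), (0.0, 0.5, 0.1, 0.6)],
)
def test_hinge_loss_examples(s_pos, s_neg, t, expected):
    assert pairwise_hinge_loss(s_pos, s_neg, t) == pytest.approx(expected)


@settings(deadline=None, derandomize=True)
@given(
    s_pos=st.floats(-5, 5), s_neg=st.floats(-5, 5), t=st.floats(0, 2),
    delta=st.floats(0.001, 1.0),
)
def test_hinge_loss_monotonicity(s_pos, s_neg, t, delta):
    base = pairwise_hinge_loss(s_pos, s_neg, t)
    assert base >= 0
    assert (base == 0) == (s_pos >= s_neg + t)
    assert pairwise_hinge_loss(s_pos + delta, s_neg, t) <= base
    assert pairwise_hinge_loss(s_pos, s_neg + delta, t) >= base


def test_one_step_decreases_violated_pair_loss(tiny_config):
    model = RankerModel.initialize(tiny_config)
    feats = [featurize(smiles_to_graph(s)) for s in ("CCO", "CCN")]
    nodes, edges, mask = pad_batch(feats)

    def pair_loss():
        out = model.forward(nodes, edges, mask)
        s = out.reshape(1, 2)
        return hinge_loss_tensor(
            ad.einsum("pk,k->p", s, ad.Tensor(np.array([1.0, 0.0], np.float32))),
            ad.einsum("pk,k->p", s, ad.Tensor(np.array([0.0, 1.0], np.float32))),
            0.5,
        ).mean()

    before = pair_loss()
    assert float(before.data) > 0  # freshly initialized: pair is violated
    opt = RMSProp(model.params, learning_rate=1e-4)
    opt.zero_grad()
    before.backward()
    opt.step()
    after = float(pair_loss().data)
    assert after < float(before.data)


def test_edge_channels_affect_output(model):
    """Zeroing edge features must change the score on a multi-bond graph."""
    f = featurize(smiles_to_graph("CC=O"))
    s = score(model, f)
    zeroed = type(f)(
        node_matrix=f.node_matrix,
        edge_tensor=np.zeros_like(f.edge_tensor),
        mask=f.mask,
    )
    assert abs(score(model, zeroed) - s) > 1e-6


def test_dropout_is_seeded_and_training_only(tiny_config):
    cfg = EGTConfig(**{**tiny_config.__dict__, "dropout": 0.3})
    model = RankerModel.initialize(cfg)
    f = featurize(smiles_to_graph("CCO"))
    nodes, edges, mask = pad_batch([f])
    a = model.forward(nodes, edges, mask, training=True,
                      rng=np.random.default_rng(5)).data
    b = model.forward(nodes, edges, mask, training=True,
                      rng=np.random.default_rng(5)).data
    c = model.forward(nodes, edges, mask, training=True,
                      rng=np.random.default_rng(6)).data
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)
    # inference ignores dropout entirely
    d1 = model.forward(nodes, edges, mask, training=False).data
    d2 = model.forward(nodes, edges, mask, training=False).data
    assert np.array_equal(d1, d2)


def test_version_id_tracks_parameters(tiny_config):
    m1 = RankerModel.initialize(tiny_config)
    m2 = RankerModel.initialize(tiny_config)
    assert m1.version_id == m2.version_id
    m2.params["head2"].data = m2.params["head2"].data + 1.0
    assert m1.version_id != m2.version_id


def test_checkpoint_roundtrip(tmp_path, tiny_config):
    model = RankerModel.initialize(tiny_config)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model)
    loaded = load_checkpoint(path)
    assert loaded.version_id == model.version_id
    assert loaded.config == model.config
    f = featurize(smiles_to_graph("CCO"))
    assert score(loaded, f) == score(model, f)


def test_checkpoint_rejects_tampering(tmp_path, tiny_config):
    model = RankerModel.initialize(tiny_config)
    path = tmp_path / "model.npz"
    save_checkpoint(path, model)
    import numpy as onp

    with onp.load(path) as npz:
        arrays = {k: npz[k].copy() for k in npz.files}
    arrays["param:head2"] = arrays["param:head2"] + 1.0
    onp.savez(path, **arrays)
    with pytest.raises(CheckpointError):
        load_checkpoint(path)


def test_config_validation():
    with pytest.raises(ValueError):
        EGTConfig(node_dim=30, num_heads=4)
    with pytest.raises(ValueError):
        EGTConfig(margin=-0.1)
    with pytest.raises(ValueError):
        EGTConfig(pooling="max")
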