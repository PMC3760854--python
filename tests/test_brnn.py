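import numpy as np
import pytest

from pepbind.brnn import (
    ALL_FEATURES,
    BRNNModel,
    CHANNELS,
    N_CHANNELS,
    TrainingConfig,
    cross_validate,
    encode_inputs,
    ensemble_predict,
    learning_rate_trace,
    load_model,
    loss_and_gradients,
    make_folds,
    save_model,
    train_brnn,
    train_ensemble,
)
from pepbind.errors import ConfigurationError, ValidationError
from pepbind.evaluation import roc_auc
from pepbind.regions import ProteinRegion


def region_of(seq, parent_length=None):
    n = len(seq)
    return ProteinRegion("r", parent_length or n, 1, n, seq)


def numeric_gradients(model, x, y, eps=1e-6):
    """Central finite differences over every weight of the model."""
    grads = {}
    for name, p in model.parameters().items():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp, _ = loss_and_gradients(model, x, y)
            p[idx] = orig - eps
            lm, _ = loss_and_gradients(model, x, y)
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        grads[name] = g
    return grads


def max_tensor_relative_error(analytic, numeric):
    """Per-tensor relative error: ||ga - gn||_inf / (||ga||_inf + ||gn||_inf)."""
    worst = 0.0
    for name in analytic:
        ga, gn = analytic[name], numeric[name]
        denom = np.abs(ga).max() + np.abs(gn).max()
        worst = max(worst, np.abs(ga - gn).max() / max(denom, 1e-12))
    return worst


# ---------------------------------------------------------------------------
# Input encoding
# ---------------------------------------------------------------------------

def test_encoding_shape_and_one_hot():
    region = region_of("A" * 25 + "C" * 25, parent_length=200)
    ss = np.tile([0.2, 0.3, 0.5], (50, 1))
    x = encode_inputs(region, ss=ss, disorder=np.full(50, 0.7), vina=np.linspace(0, 1, 50))
    assert x.shape == (50, N_CHANNELS)
    assert (x[:, :20].sum(axis=1) == 1).all()
    assert x[0, CHANNELS["A"]] == 1 and x[-1, CHANNELS["C"]] == 1
    assert (x[:, CHANNELS["length"]] == 0.2).all()
    assert np.allclose(x[:, CHANNELS["disorder"]], 0.7)
    assert np.allclose(x[:, CHANNELS["vina"]], np.linspace(0, 1, 50))


def test_encoding_zero_fills_deselected_channels():
    region = region_of("ACDEF")
    x = encode_inputs(region, vina=np.ones(5), features={"vina"})
    struct = [CHANNELS["ss_helix"], CHANNELS["ss_strand"], CHANNELS["ss_coil"], CHANNELS["disorder"]]
    assert (x[:, struct] == 0).all()
    assert (x[:, CHANNELS["vina"]] == 1).all()
    seq_only = encode_inputs(region, features=frozenset())
    assert (seq_only[:, 21:] == 0).all()


def test_encoding_validates_tracks():
    region = region_of("ACDEF")
    with pytest.raises(ValidationError):
        encode_inputs(region, disorder=np.ones(4), features={"disorder"})
    bad_ss = np.tile([0.5, 0.5, 0.5], (5, 1))  # does not sum to 1
    with pytest.raises(ValidationError):
        encode_inputs(region, ss=bad_ss, features={"ss"})
    with pytest.raises(ValidationError):
        encode_inputs(region, features={"docking"})


def test_non_standard_residue_gets_zero_one_hot():
    region = region_of("AXDEF")
    with pytest.warns(UserWarning, match="non-standard"):
        x = encode_inputs(region, features=frozenset())
    assert x[1, :20].sum() == 0
    assert x[0, :20].sum() == 1


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def naive_predict(model, x):
    """Independent position-by-position reimplementation of the forward pass."""
    L, C = x.shape
    H = model.hidden
    hf = np.zeros(H)
    hfs = []
    for j in range(L):
        _, out = model.fwd.apply(np.concatenate([x[j], hf])[None])
        hf = out[0]
        hfs.append(hf)
    hb = np.zeros(H)
    hbs = [None] * L
    for j in reversed(range(L)):
        _, out = model.bwd.apply(np.concatenate([x[j], hb])[None])
        hb = out[0]
        hbs[j] = hb
    half = model.window // 2
    xp = np.vstack([np.zeros((half, C)), x, np.zeros((half, C))])
    preds = []
    for j in range(L):
        a = np.concatenate([xp[j : j + model.window].ravel(), hfs[j], hbs[j]])[None]
        _, logit = model.out.apply(a)
        preds.append(1.0 / (1.0 + np.exp(-logit[0, 0])))
    return np.array(preds)


def test_forward_matches_naive_reimplementation(rng):
    model = BRNNModel.init(rng, window=5, hidden=4, ff_hidden=6, n_channels=7)
    x = rng.uniform(0, 1, size=(12, 7))
    assert np.allclose(model.predict(x), naive_predict(model, x))


def test_zero_weights_give_constant_output_in_open_interval(rng):
    model = BRNNModel.init(rng, window=7, hidden=3, ff_hidden=4, n_channels=5)
    for p in model.parameters().values():
        p[...] = 0.0
    out = model.predict(rng.uniform(0, 1, size=(20, 5)))
    assert np.allclose(out, out[0])
    assert (out > 0).all() and (out < 1).all()


def test_output_strictly_within_unit_interval(rng):
    model = BRNNModel.init(rng, window=9, hidden=5, ff_hidden=8)
    region = region_of("ACDEFGHIKLMNPQRSTVWY")
    x = encode_inputs(region, features=frozenset())
    out = model.predict(x)
    assert (out > 0).all() and (out < 1).all()


def test_analytic_gradients_match_finite_differences(rng):
    model = BRNNModel.init(rng, window=3, hidden=3, ff_hidden=4, n_channels=6)
    x = rng.uniform(0, 1, size=(1, 10, 6))
    y = rng.integers(0, 2, size=(1, 10)).astype(float)
    _, analytic = loss_and_gradients(model, x, y)
    numeric = numeric_gradients(model, x, y)
    assert max_tensor_relative_error(analytic, numeric) < 1e-5


def test_batch_gradient_is_sum_of_per_sequence_gradients(rng):
    model = BRNNModel.init(rng, window=3, hidden=3, ff_hidden=4, n_channels=6)
    x = rng.uniform(0, 1, size=(3, 8, 6))
    y = rng.integers(0, 2, size=(3, 8)).astype(float)
    loss_b, grads_b = loss_and_gradients(model, x, y)
    losses, grads = zip(
        *(loss_and_gradients(model, x[i : i + 1], y[i : i + 1]) for i in range(3))
    )
    assert loss_b == pytest.approx(sum(losses))
    for name in grads_b:
        assert np.allclose(grads_b[name], sum(g[name] for g in grads))


# ---------------------------------------------------------------------------
# Learning-rate schedule
# ---------------------------------------------------------------------------

def test_lr_halves_after_fifty_stagnant_epochs():
    errors = [1.0] * 51  # epoch 1 sets the best; 50 stagnant epochs follow
    trace = learning_rate_trace(errors, lr=0.01, patience=50)
    assert trace[49] == 0.01
    assert trace[50] == 0.005


def test_lr_unchanged_while_error_improves():
    errors = np.linspace(1.0, 0.1, 200)
    assert set(learning_rate_trace(errors, 0.01, 50)) == {0.01}


def test_lr_halvings_count_matches_stagnation_runs(rng):
    # improvements at known epochs split the series into stagnation runs;
    # each full patience-length stretch within a run halves the rate once
    patience = 10
    errors = []
    best = 100.0
    runs = []
    for run_len in (25, 7, 42, 10):
        best -= 1.0
        errors.append(best)  # an improvement starts each run
        errors.extend([best + 0.5] * run_len)
        runs.append(run_len)
    trace = learning_rate_trace(errors, 1.0, patience)
    expected_halvings = sum(r // patience for r in runs)
    assert trace[-1] == 1.0 / 2**expected_halvings


# ---------------------------------------------------------------------------
# Training, folds, ensembling
# ---------------------------------------------------------------------------

def tiny_dataset(rng, n=6, L=12, channels=6):
    data = []
    for _ in range(n):
        x = rng.uniform(0, 1, size=(L, channels))
        y = (rng.uniform(0, 1, size=L) < 0.3).astype(float)
        y[0] = 1.0
        y[1] = 0.0
        data.append((x, y))
    return data


def test_zero_epochs_returns_initial_model(rng):
    data = tiny_dataset(rng)
    cfg = TrainingConfig(epochs=0, seed=9)
    trained = train_brnn(data, cfg, window=3)
    fresh = BRNNModel.init(
        np.random.default_rng(9), window=3, hidden=cfg.hidden,
        ff_hidden=cfg.ff_hidden, n_channels=6,
    )
    for name, p in trained.parameters().items():
        assert np.array_equal(p, fresh.parameters()[name])


def test_training_is_reproducible_and_reduces_loss(rng):
    data = tiny_dataset(rng)
    cfg = TrainingConfig(epochs=40, lr=0.5, seed=4)
    from pepbind.brnn import TrainingLog

    log1, log2 = TrainingLog(), TrainingLog()
    m1 = train_brnn(data, cfg, window=3, log=log1)
    m2 = train_brnn(data, cfg, window=3, log=log2)
    x = data[0][0]
    assert np.array_equal(m1.predict(x), m2.predict(x))
    assert log1.rows == log2.rows
    assert log1.rows[-1][1] < log1.rows[0][1]  # loss decreased over the run


def test_training_recovers_signal_from_noisy_docking_channel(rng):
    # the docking channel equals the label plus noise; a trained model must
    # rank held-out binding residues nearly perfectly
    channels = 6
    def make(n):
        items = []
        for _ in range(n):
            y = np.zeros(20)
            start = int(rng.integers(0, 15))
            y[start : start + 5] = 1.0
            x = np.zeros((20, channels))
            x[:, -1] = np.clip(y + rng.normal(0, 0.1, size=20), 0, 1)
            items.append((x, y))
        return items

    train_set, test_set = make(16), make(6)
    cfg = TrainingConfig(epochs=120, lr=0.5, seed=2)
    model = train_brnn(train_set, cfg, window=5)
    scores = np.concatenate([model.predict(x) for x, _ in test_set])
    labels = np.concatenate([y for _, y in test_set])
    assert roc_auc(scores, labels) > 0.9


def test_degenerate_labels_are_a_training_error(rng):
    x = rng.uniform(0, 1, size=(10, 6))
    with pytest.raises(ConfigurationError):
        train_brnn([(x, np.zeros(10))], TrainingConfig(epochs=1))


@pytest.mark.parametrize("n,folds,sizes", [(10, 10, {1}), (84, 10, {8, 9})])
def test_fold_partition_is_disjoint_and_covering(n, folds, sizes):
    parts = make_folds(n, folds, seed=0)
    assert len(parts) == folds
    assert {len(p) for p in parts} <= sizes
    flat = np.concatenate(parts)
    assert len(flat) == n and set(flat) == set(range(n))


def test_too_few_items_for_folds_is_an_error():
    with pytest.raises(ConfigurationError):
        make_folds(5, 10, seed=0)


def test_cross_validation_predicts_every_item_once(rng):
    data = tiny_dataset(rng, n=8, L=10)
    cfg = TrainingConfig(epochs=2, folds=4, ensemble_windows=(3,), seed=1)
    preds, assignment = cross_validate(data, cfg)
    assert len(preds) == 8
    assert all(p.shape == (10,) for p in preds)
    assert sorted(set(assignment)) == [0, 1, 2, 3]


def test_ensemble_mean_and_default_windows(rng):
    data = tiny_dataset(rng, n=4, L=10, channels=6)
    cfg = TrainingConfig(epochs=0, seed=0)
    models = train_ensemble(data, cfg)
    assert [m.window for m in models] == [7, 9, 11]

    x = rng.uniform(0, 1, size=(10, 6))
    one = BRNNModel.init(rng, window=3, hidden=3, ff_hidden=4, n_channels=6)
    assert np.allclose(ensemble_predict([one, one, one], x), one.predict(x))

    constants = []
    for p_target in (0.2, 0.4, 0.6):
        m = BRNNModel.init(rng, window=3, hidden=3, ff_hidden=4, n_channels=6)
        for p in m.parameters().values():
            p[...] = 0.0
        m.out.b2[...] = np.log(p_target / (1 - p_target))
        constants.append(m)
    assert np.allclose(ensemble_predict(constants, x), 0.4)

    with pytest.raises(ConfigurationError):
        ensemble_predict([], x)


def test_model_checkpoint_round_trip(tmp_path, rng):
    model = BRNNModel.init(rng, window=5, hidden=4, ff_hidden=6, n_channels=8)
    x = rng.uniform(0, 1, size=(15, 8))
    path = tmp_path / "model.json"
    save_model(model, path)
    loaded = load_model(path)
    assert np.array_equal(model.predict(x), loaded.predict(x))
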