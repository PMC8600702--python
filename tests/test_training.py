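"""Training harness: stratified folds, optimizer selection, epoch loop,
cross-validation partition properties, leakage hygiene."""

import numpy as np
import pytest

from fus2net import (
    Fus2NetConfig,
    TrainConfig,
    build_fus2net,
    cross_validate,
    generate_dataset,
    make_optimizer,
    small_config,
    stratified_kfold,
    train_fold,
)
from fus2net.preprocess import AugmentConfig


def test_stratified_646_646_tenfold_counts():
    """Balanced 646+646 set, k=10: every fold holds 64 or 65 of each class
    (brute-force recount of fold compositions)."""
    labels = np.array([0] * 646 + [1] * 646)
    folds = stratified_kfold(labels, 10, seed=0)
    assert sorted(np.bincount(folds.fold_index, minlength=10).tolist())
    for f in range(10):
        idx = folds.test_indices(f)
        n0 = int(np.sum(labels[idx] == 0))
        n1 = int(np.sum(labels[idx] == 1))
        assert n0 in (64, 65) and n1 in (64, 65)
    # partition: disjoint and exhaustive
    all_idx = np.concatenate([folds.test_indices(f) for f in range(10)])
    assert sorted(all_idx.tolist()) == list(range(1292))


def test_stratified_proportions_with_imbalance():
    labels = np.array([0] * 70 + [1] * 30)
    folds = stratified_kfold(labels, 10, seed=3)
    for f in range(10):
        idx = folds.test_indices(f)
        assert np.sum(labels[idx] == 0) == 7
        assert np.sum(labels[idx] == 1) == 3


def test_leave_one_out_degenerate_case():
    labels = np.arange(6)  # unique label per sample
    folds = stratified_kfold(labels, 6, seed=0)
    sizes = [len(folds.test_indices(f)) for f in range(6)]
    assert sizes == [1] * 6


def test_stratified_deterministic_and_seed_sensitive():
    labels = np.array([0, 1] * 30)
    a = stratified_kfold(labels, 5, seed=4)
    b = stratified_kfold(labels, 5, seed=4)
    np.testing.assert_array_equal(a.fold_index, b.fold_index)
    c = stratified_kfold(labels, 5, seed=5)
    assert not np.array_equal(a.fold_index, c.fold_index)


def test_stratified_rejects_k_above_n():
    with pytest.raises(ValueError):
        stratified_kfold([0, 1, 0], 4, seed=0)


def test_make_optimizer_names_and_rejection():
    assert make_optimizer("adam").name == "adam"
    assert make_optimizer("SGD").name == "sgd"
    hp = make_optimizer("rmsprop").hyperparameters()
    assert hp["lr"] == pytest.approx(0.001)
    with pytest.raises(ValueError):
        make_optimizer("adagrad")


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs_per_fold=0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="adagrad")
    with pytest.raises(ValueError):
        TrainConfig(balance_mode="sometimes")


@pytest.fixture(scope="module")
def mini_setup():
    ds = generate_dataset(small_config(10, 10, size=48, seed=31))
    arch = Fus2NetConfig(input_size=48, dropout_rate=0.0, l2_factor=0.0, seed=0)
    return ds, arch


def test_single_epoch_history_length(mini_setup):
    ds, arch = mini_setup
    tr = ds.subset(range(0, 14))
    va = ds.subset(range(14, 20))
    model = build_fus2net(arch)
    cfg = TrainConfig(epochs_per_fold=1, use_augmentation=False, seed=0)
    _, hist = train_fold(model, tr, va, cfg)
    assert len(hist.train_loss) == len(hist.val_loss) == 1
    assert len(hist.train_accuracy) == len(hist.val_accuracy) == 1


def test_train_fold_rejects_empty_split(mini_setup):
    ds, arch = mini_setup
    model = build_fus2net(arch)
    with pytest.raises(ValueError):
        train_fold(model, ds.subset([]), ds.subset([0]), TrainConfig(seed=0))


def test_augmentation_toggle_changes_batch_pixels(mini_setup):
    """Without augmentation two passes over the data see identical pixels;
    with augmentation successive draws differ."""
    from fus2net.preprocess import as_batch, augment

    ds, _ = mini_setup
    samples = ds.subset(range(8)).samples
    np.testing.assert_array_equal(as_batch(samples), as_batch(samples))
    rng = np.random.default_rng(0)
    aug1 = as_batch([augment(s, AugmentConfig(), rng) for s in samples])
    aug2 = as_batch([augment(s, AugmentConfig(), rng) for s in samples])
    assert not np.array_equal(aug1, aug2)


def test_learns_easy_phantoms_at_reduced_resolution():
    """Learnability smoke test: training accuracy on 60 phantoms at 64x64
    exceeds 0.9 within 20 epochs (the classes are separable by margin
    morphology, so the optimizer must be able to fit them)."""
    ds = generate_dataset(small_config(30, 30, size=64, seed=41))
    tr = ds.subset(list(range(0, 25)) + list(range(30, 55)))
    va = ds.subset(list(range(25, 30)) + list(range(55, 60)))
    arch = Fus2NetConfig(input_size=64, dropout_rate=0.0, l2_factor=0.0, seed=0)
    model = build_fus2net(arch)
    cfg = TrainConfig(optimizer="adam", epochs_per_fold=20,
                      use_augmentation=False, use_regularization=False, seed=0)
    _, hist = train_fold(model, tr, va, cfg)
    assert max(hist.train_accuracy) > 0.9


def test_cross_validate_partitions_and_mean(mini_setup):
    ds, arch = mini_setup
    cfg = TrainConfig(optimizer="sgd", epochs_per_fold=1, k_folds=2,
                      use_augmentation=False, balance_mode="none", seed=0)
    res = cross_validate(ds, cfg, arch)
    assert len(res.fold_results) == 2
    # every sample evaluated exactly once across folds (multiset equality)
    counted = sum(r.counts.total for r in res.fold_results)
    assert counted == len(ds)
    all_eval = np.concatenate(
        [res.fold_assignment.test_indices(f) for f in range(2)]
    )
    assert sorted(all_eval.tolist()) == list(range(len(ds)))
    accs = [r.accuracy for r in res.fold_results]
    assert res.mean_metrics()["accuracy"] == pytest.approx(np.mean(accs), abs=1e-12)


def test_per_fold_balancing_never_leaks_flips(mini_setup):
    """Flipped copies are created inside each training split only, so no
    mirror of a held-out image can be trained on."""
    ds, arch = mini_setup
    # 10 benign vs 4 malignant: imbalance forces per-fold balancing
    ds = ds.subset(list(range(0, 10)) + list(range(10, 14)))
    from fus2net.preprocess import balance_by_flip

    folds = stratified_kfold(ds.labels_int(), 2, seed=0)
    for f in range(2):
        train_ds = ds.subset(folds.train_indices(f))
        train_ids = {s.sample_id for s in train_ds}
        val_ids = {ds[i].sample_id for i in folds.test_indices(f)}
        counts = train_ds.class_counts
        n_sel = (max(counts.values()) - min(counts.values())) // 2
        assert n_sel > 0
        balanced = balance_by_flip(train_ds, n_sel, np.random.default_rng(0))
        flips = [s for s in balanced if s.sample_id.endswith(("-hflip", "-vflip"))]
        assert flips
        for s in flips:
            parent = s.sample_id.rsplit("-", 1)[0]
            assert parent in train_ids
            assert parent not in val_ids


def test_seeded_end_to_end_determinism(mini_setup):
    ds, arch = mini_setup
    cfg = TrainConfig(optimizer="adam", epochs_per_fold=1, k_folds=2,
                      use_augmentation=False, balance_mode="none", seed=7)
    r1 = cross_validate(ds, cfg, arch)
    r2 = cross_validate(ds, cfg, arch)
    np.testing.assert_array_equal(r1.fold_assignment.fold_index,
                                  r2.fold_assignment.fold_index)
    for a, b in zip(r1.fold_results, r2.fold_results):
        assert a.accuracy == b.accuracy
        assert a.counts == b.counts
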