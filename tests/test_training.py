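"""Joint training: initialisation, optimisation, evaluation, cohorts."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from gazehmm.faces import generate_identity_prototypes, render_stimulus_set
from gazehmm.training import (
    TrainConfig,
    evaluate_accuracy,
    initialize_individual,
    load_individual,
    run_cohort,
    save_individual,
    train_individual,
)


def _strategy_arrays(ind):
    return [t.data.copy() for t in ind.strategy_parameters()]


def test_initialisation_reproducible_given_seed(tiny_config):
    a = initialize_individual(tiny_config, 5)
    b = initialize_individual(tiny_config, 5)
    for ta, tb in zip(_strategy_arrays(a), _strategy_arrays(b)):
        assert np.array_equal(ta, tb)
    for ka, kb in zip(a.net.state_arrays().values(), b.net.state_arrays().values()):
        assert np.array_equal(ka, kb)


def test_initial_conv_filters_unit_norm(tiny_config):
    ind = initialize_individual(tiny_config, 0)
    for st in ind.net.conv_stacks:
        for w in (st[0], st[2]):
            norms = np.linalg.norm(w.data.reshape(-1, w.data.shape[-1]).astype(float), axis=0)
            assert np.abs(norms - 1).max() < 1e-6


def test_initial_roi_means_uniform_over_central_region(tiny_config):
    # sampling the ROI initialisation directly (without building a network
    # each time) across many seeds: x-coordinates should be uniform over
    # the central 80% of the image
    xs = []
    S = tiny_config.image_size
    for seed in range(1000):
        rng = np.random.default_rng(seed)
        xs.append(rng.uniform(0.1 * S, 0.9 * S, size=2)[0])
    stat = sps.kstest(xs, sps.uniform(loc=0.1 * S, scale=0.8 * S).cdf)
    assert stat.pvalue > 0.01
    ind = initialize_individual(tiny_config, 0)
    for mu in ind.roi_means:
        assert 0.1 * S <= mu.data[0] <= 0.9 * S
        assert 0.1 * S <= mu.data[1] <= 0.9 * S
        assert mu.data[2] == 1.0


def test_zero_epochs_leaves_individual_unchanged(tiny_config, tiny_stimuli):
    cfg = dataclasses.replace(tiny_config, epochs=0, checkpoint_epochs=())
    ind = initialize_individual(cfg, 1)
    before = _strategy_arrays(ind)
    train_individual(ind, tiny_stimuli)
    assert ind.history == []
    for ta, tb in zip(before, _strategy_arrays(ind)):
        assert np.array_equal(ta, tb)


def test_training_descends_and_snapshots_checkpoints(tiny_config, tiny_stimuli):
    cfg = dataclasses.replace(tiny_config, epochs=15, checkpoint_epochs=(5, 15))
    losses_first, losses_last = [], []
    for seed in range(3):
        ind = initialize_individual(cfg, seed)
        train_individual(ind, tiny_stimuli)
        assert len(ind.history) == 15
        assert set(ind.checkpoints) == {5, 15}
        losses_first.append(ind.history[0]["train_loss"])
        losses_last.append(ind.history[-1]["train_loss"])
    assert np.mean(losses_last) < np.mean(losses_first)


def test_unit_norm_invariant_after_training(tiny_config, tiny_stimuli):
    ind = initialize_individual(tiny_config, 2)
    train_individual(ind, tiny_stimuli)
    for st in ind.net.conv_stacks:
        for w in (st[0], st[2]):
            norms = np.linalg.norm(w.data.reshape(-1, w.data.shape[-1]).astype(float), axis=0)
            assert np.abs(norms - 1).max() < 1e-6


def test_training_reproducible_given_seed(tiny_config, tiny_stimuli):
    runs = []
    for _ in range(2):
        ind = initialize_individual(tiny_config, 3)
        train_individual(ind, tiny_stimuli)
        runs.append((ind.history, _strategy_arrays(ind)))
    assert runs[0][0] == runs[1][0]
    for ta, tb in zip(runs[0][1], runs[1][1]):
        assert np.array_equal(ta, tb)


def test_untrained_accuracy_is_at_chance_level():
    protos = generate_identity_prototypes(10, rng_seed=0, image_size=20)
    stim = render_stimulus_set(protos, exemplars_per_identity=4, rng_seed=1)
    cfg = TrainConfig(n_identities=10, image_size=20, epochs=1, checkpoint_epochs=(1,), seed=0)
    ind = initialize_individual(cfg, 0)
    acc = evaluate_accuracy(ind, stim, which="train", n_repeats=2, seed=0)
    # an untrained classifier cannot beat chance by much on 10 balanced classes
    assert acc < 0.35


def test_constant_classifier_accuracy_equals_class_frequency(tiny_config, tiny_stimuli):
    ind = initialize_individual(tiny_config, 0)
    for w in (ind.net.w_hidden, ind.net.w_out, ind.net.b_hidden, ind.net.b_out):
        w.data[:] = 0
    ind.net.b_out.data[1] = 10.0  # always predicts class 1
    imgs, labels = tiny_stimuli.subset("val")
    acc = evaluate_accuracy(ind, tiny_stimuli, n_repeats=3, seed=0)
    assert acc == pytest.approx(np.mean(labels == 1))


def test_accuracy_invariant_under_consistent_relabelling(tiny_config, tiny_stimuli):
    ind = initialize_individual(tiny_config, 1)
    train_individual(ind, tiny_stimuli)
    acc = evaluate_accuracy(ind, tiny_stimuli, seed=9)
    perm = np.array([1, 0])  # swap the two identities
    ind.net.w_out.data = ind.net.w_out.data[:, perm]
    ind.net.b_out.data = ind.net.b_out.data[perm]
    relabeled = dataclasses.replace(tiny_stimuli, labels=np.argsort(perm)[tiny_stimuli.labels])
    acc_perm = evaluate_accuracy(ind, relabeled, seed=9)
    assert acc_perm == pytest.approx(acc)


def test_empty_split_rejected(tiny_config, tiny_stimuli):
    ind = initialize_individual(tiny_config, 0)
    bad = dataclasses.replace(tiny_stimuli, split=np.array(["train"] * len(tiny_stimuli.images)))
    with pytest.raises(ValueError):
        evaluate_accuracy(ind, bad)


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=10, checkpoint_epochs=(20,))
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(fixation_weights=(0.2, 0.3, 0.5))


def test_cohort_produces_distinct_individuals(tiny_config, tiny_stimuli):
    cohort = run_cohort(tiny_config, n_individuals=2, stimuli=tiny_stimuli, seed0=10)
    assert cohort.n_individuals == 2
    assert cohort.statuses == ["ok", "ok"]
    s0 = cohort.individuals[0].strategy()
    s1 = cohort.individuals[1].strategy()
    assert not np.allclose(s0.rois[0].mean, s1.rois[0].mean)


def test_cohort_resume_reproduces_uninterrupted_run(tiny_config, tiny_stimuli, tmp_path):
    full = run_cohort(tiny_config, n_individuals=2, stimuli=tiny_stimuli, seed0=20)
    # interrupted run: first train only individual 0, then resume for both
    run_cohort(tiny_config, n_individuals=1, stimuli=tiny_stimuli, seed0=20, out_dir=tmp_path)
    resumed = run_cohort(tiny_config, n_individuals=2, stimuli=tiny_stimuli, seed0=20, out_dir=tmp_path)
    for a, b in zip(full.individuals, resumed.individuals):
        assert [h["train_loss"] for h in a.history] == pytest.approx(
            [h["train_loss"] for h in b.history]
        )
        for ta, tb in zip(_strategy_arrays(a), _strategy_arrays(b)):
            assert np.allclose(ta, tb)


def test_individual_save_load_roundtrip(tiny_config, tiny_stimuli, tmp_path):
    ind = initialize_individual(tiny_config, 4)
    train_individual(ind, tiny_stimuli)
    save_individual(ind, tmp_path / "ind.npz")
    back = load_individual(tmp_path / "ind.npz")
    assert back.history == ind.history
    assert set(back.checkpoints) == set(ind.checkpoints)
    for ka, kb in zip(ind.net.state_arrays().values(), back.net.state_arrays().values()):
        assert np.array_equal(ka, kb)
    sa, sb = ind.strategy(), back.strategy()
    for ra, rb in zip(sa.rois, sb.rois):
        assert np.allclose(ra.mean, rb.mean)
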