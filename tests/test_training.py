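"""Tests of identity splits, batching, the LR schedule and the SGD loop."""

import dataclasses

import numpy as np
import pytest

from aufaces.experiment import prepare_database
from aufaces.network import NetConfig, build_network
from aufaces.training import (
    FULL_LR_SCHEDULE,
    TrainConfig,
    batch_iterator,
    learning_rate_at,
    run_experiment,
    split_identities,
    train_run,
)
from tests.conftest import micro_config


class TestSplitIdentities:
    def test_full_protocol_split_sizes(self):
        ids = [f"p{i}" for i in range(60)]
        s = split_identities(ids, (40, 8, 12), seed=0)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (40, 8, 12)
        assert set(s.train_ids) | set(s.val_ids) | set(s.test_ids) == set(ids)

    def test_scaled_split(self):
        s = split_identities([f"p{i}" for i in range(15)], (10, 2, 3), seed=1)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (10, 2, 3)

    def test_same_seed_reproduces_partition(self):
        ids = [f"p{i}" for i in range(30)]
        assert split_identities(ids, (20, 4, 6), 7) == split_identities(ids, (20, 4, 6), 7)

    def test_indivisible_sizes_rejected(self):
        with pytest.raises(ValueError, match="split"):
            split_identities([f"p{i}" for i in range(25)], (40, 8, 12), 0)


class TestBatchIterator:
    def test_full_protocol_epoch_batching(self):
        batches = batch_iterator(14_000, 32, 0)
        assert len(batches) == 438
        assert all(len(b) == 32 for b in batches[:-1])
        assert len(batches[-1]) == 16

    def test_exact_division_has_no_remainder(self):
        batches = batch_iterator(64, 32, 0)
        assert [len(b) for b in batches] == [32, 32]

    def test_fewer_samples_than_batch(self):
        batches = batch_iterator(10, 32, 0)
        assert [len(b) for b in batches] == [10]

    def test_shuffle_covers_all_samples(self):
        batches = batch_iterator(100, 32, 5)
        assert sorted(np.concatenate(batches)) == list(range(100))


class TestLearningRateSchedule:
    @pytest.mark.parametrize("iteration,expected", [
        (0, 1e-4), (3_999, 1e-4), (4_000, 1e-5), (5_000, 1e-5),
        (8_000, 1e-6), (12_000, 1e-6),
    ])
    def test_full_protocol_schedule(self, iteration, expected):
        assert learning_rate_at(iteration, FULL_LR_SCHEDULE) == expected

    def test_unsorted_breakpoints_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            TrainConfig(lr_schedule=((0, 1e-4), (100, 1e-5), (100, 1e-6)))


@pytest.fixture(scope="module")
def micro_prepared():
    cfg = micro_config()
    net = build_network(cfg.net)
    prep = prepare_database(cfg.database_a, cfg.preprocess, cfg.augment, net)
    return cfg, net, prep


class TestTrainRun:
    def test_zero_learning_rate_leaves_weights_unchanged(self, micro_prepared):
        cfg, _, prep = micro_prepared
        net = build_network(cfg.net)
        before = net.fc_checksum()
        split = split_identities(list(prep.identities), (8, 2, 2), 0)
        tc = dataclasses.replace(cfg.train, total_iterations=30,
                                 lr_schedule=((0, 0.0),))
        train_run(net, prep, split, tc)
        assert net.fc_checksum() == before

    def test_initial_loss_near_log7_for_near_uniform_outputs(self, micro_prepared):
        cfg, _, prep = micro_prepared
        net = build_network(cfg.net)
        net.W3 *= 0.01          # near-uniform initial predictions
        split = split_identities(list(prep.identities), (8, 2, 2), 0)
        tc = dataclasses.replace(cfg.train, total_iterations=1,
                                 lr_schedule=((0, 0.0),))
        rec = train_run(net, prep, split, tc)
        assert abs(rec.losses[0] - np.log(7)) < 0.2

    def test_learning_beats_chance_on_twin_fixture(self, micro_prepared):
        cfg, _, prep = micro_prepared
        net = build_network(cfg.net)
        split = split_identities(list(prep.identities), (8, 2, 2), 0)
        rec = train_run(net, prep, split, cfg.train, batch_seed=1, dropout_seed=2)
        assert rec.epoch_train_acc[-1] > 0.5      # chance is 1/7

    def test_validation_curve_plateaus(self, micro_prepared):
        cfg, _, prep = micro_prepared
        net = build_network(cfg.net)
        split = split_identities(list(prep.identities), (8, 2, 2), 0)
        rec = train_run(net, prep, split, cfg.train, batch_seed=1, dropout_seed=2)
        last3 = rec.epoch_val_acc[-3:]
        assert rec.epoch_val_acc.max() - last3.mean() < 0.1

    def test_epoch_sample_count_matches_split_and_augmentation(self, micro_prepared):
        cfg, _, prep = micro_prepared
        n_train_ids = 8
        expected = n_train_ids * 7 * cfg.augment.n_variants
        split = split_identities(list(prep.identities), (8, 2, 2), 0)
        mask = np.isin(prep.identity, split.train_ids)
        assert mask.sum() == expected


class TestRunExperiment:
    def test_one_record_per_run_with_distinct_splits(self, micro_prepared):
        cfg, _, prep = micro_prepared
        records = run_experiment(prep, cfg.net, cfg.train, master_seed=0)
        assert len(records) == cfg.train.runs
        assert records[0].split != records[1].split

    def test_identical_master_seed_reproduces_records(self, micro_prepared):
        cfg, _, prep = micro_prepared
        a = run_experiment(prep, cfg.net, cfg.train, master_seed=3)
        b = run_experiment(prep, cfg.net, cfg.train, master_seed=3)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.losses, rb.losses)
            assert all(np.array_equal(x, y) for x, y in zip(ra.fc_params, rb.fc_params))

    def test_backbone_frozen_across_runs(self, micro_prepared):
        cfg, net, prep = micro_prepared
        records = run_experiment(prep, cfg.net, cfg.train, master_seed=0)
        assert {r.backbone_checksum for r in records} == {net.backbone_checksum()}
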