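"""Batch composition, subset policies and the three-stage update contracts."""

import numpy as np
import pytest

from unlearn.io import MultiSiteDataset, Sample, TrainConfig
from unlearn.training import (TrainingState, UnlearningPolicy, fit,
                              make_batches, pretrain, select_unlearning_subset,
                              unlearning_step, history_frame)

from conftest import make_flat_dataset


# ---------------------------------------------------------------------------
# make_batches
# ---------------------------------------------------------------------------


class TestMakeBatches:
    def _dataset(self, sizes):
        samples = []
        for d, n in enumerate(sizes, start=1):
            for _ in range(n):
                samples.append(Sample(image=np.zeros((4, 4)), domain_label=d,
                                      main_label=1.0))
        return MultiSiteDataset(samples)

    def test_every_batch_covers_every_domain(self):
        ds = self._dataset([100, 10, 5])
        batches = make_batches(ds, 32, seed=0)
        didx = ds.domain_index
        for b in batches:
            assert len(b) == 32
            assert set(didx[b]) == {0, 1, 2}

    def test_deterministic_given_seed(self):
        ds = self._dataset([20, 10])
        a = make_batches(ds, 8, seed=5)
        b = make_batches(ds, 8, seed=5)
        c = make_batches(ds, 8, seed=6)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_largest_domain_fully_covered_each_epoch(self):
        ds = self._dataset([50, 7, 3])
        batches = make_batches(ds, 16, seed=1)
        seen = np.concatenate(batches)
        largest = np.flatnonzero(ds.domain_index == 0)
        assert set(largest) <= set(seen)

    def test_batch_size_smaller_than_domains_rejected(self):
        ds = self._dataset([5, 5, 5])
        with pytest.raises(ValueError):
            make_batches(ds, 2, seed=0)

    def test_mask_restricts_composition(self):
        ds = self._dataset([10, 10])
        mask = ds.domain_index == 0
        batches = make_batches(ds, 4, seed=0, mask=mask)
        for b in batches:
            assert np.all(ds.domain_index[b] == 0)


# ---------------------------------------------------------------------------
# Subset-selection policies
# ---------------------------------------------------------------------------


class TestSelectUnlearningSubset:
    def _aged_dataset(self):
        rng = np.random.default_rng(0)
        samples = []
        for d, (lo, hi) in [(1, (40, 70)), (2, (60, 90))]:
            for age in np.linspace(lo, hi, 31):
                samples.append(Sample(image=rng.normal(size=(4, 4)),
                                      domain_label=d, main_label=float(age),
                                      confound_labels={"age": float(age),
                                                       "sex": int(rng.integers(2))}))
        return MultiSiteDataset(samples)

    def test_mode_all_flags_everything(self):
        ds = self._aged_dataset()
        for s in ds:
            s.in_u = False
        select_unlearning_subset(ds, UnlearningPolicy(mode="all"))
        assert all(s.in_u for s in ds)

    def test_overlap_flags_exactly_the_shared_window(self):
        ds = self._aged_dataset()
        select_unlearning_subset(ds, UnlearningPolicy(mode="overlap"))
        for s in ds:
            assert s.in_u == (60.0 <= s.main_label <= 70.0)

    def test_overlap_never_touches_in_p(self):
        ds = self._aged_dataset()
        before = [s.in_p for s in ds]
        select_unlearning_subset(ds, UnlearningPolicy(mode="overlap"))
        assert [s.in_p for s in ds] == before

    def test_disjoint_ranges_rejected(self):
        ds = self._aged_dataset()
        with pytest.raises(ValueError):
            select_unlearning_subset(
                ds, UnlearningPolicy(mode="overlap", age_window=(95.0, 99.0)))

    def test_balanced_subset_equalises_confound_counts(self):
        rng = np.random.default_rng(1)
        samples = []
        for d in (1, 2):
            # 80/20 sex imbalance, opposite directions per site
            for j in range(50):
                male = int(rng.random() < (0.8 if d == 1 else 0.2))
                samples.append(Sample(image=rng.normal(size=(4, 4)),
                                      domain_label=d, main_label=50.0,
                                      confound_labels={"sex": male}))
        ds = MultiSiteDataset(samples)
        select_unlearning_subset(
            ds, UnlearningPolicy(mode="balanced_subset", confound="sex", seed=0))
        sexes = ds.confound("sex")
        flags = ds.in_c("sex")
        for d in (0, 1):
            dom = ds.domain_index == d
            males = int((flags & dom & (sexes == 1)).sum())
            females = int((flags & dom & (sexes == 0)).sum())
            assert males == females > 0


# ---------------------------------------------------------------------------
# Stage contracts on a miniature model
# ---------------------------------------------------------------------------


def _mini_state(dataset, **overrides):
    kw = dict(task="regression", mode="unlearn", feature_dim=8, width_scale=0.5,
              head_hidden=8, batch_size=8, lr=1e-3, pretrain_max_epochs=2,
              pretrain_patience=2, unlearn_epochs=1, val_fraction=0.2, seed=0)
    kw.update(overrides)
    return TrainingState(dataset, TrainConfig(**kw))


class TestStageContracts:
    def test_partition_isolation_over_five_steps(self):
        ds = make_flat_dataset(12, n_domains=2)
        state = _mini_state(ds)
        part = state.model.partition()
        batch = np.arange(8)
        for _ in range(5):
            before = {k: [p.data.copy() for p in g]
                      for k, g in part.groups().items()}
            state.stage_domain(batch)
            after_d = {k: [p.data.copy() for p in g]
                       for k, g in part.groups().items()}
            # stage 2 changes only theta_d (bitwise elsewhere)
            for k in before:
                same = all(np.array_equal(a, b)
                           for a, b in zip(before[k], after_d[k]))
                assert same == (k != "theta_d")
            state.stage_confusion(batch)
            after_c = {k: [p.data.copy() for p in g]
                       for k, g in part.groups().items()}
            # stage 3 changes only theta_repr
            for k in after_d:
                same = all(np.array_equal(a, b)
                           for a, b in zip(after_d[k], after_c[k]))
                assert same == (k != "theta_repr")

    def test_task_stage_touches_only_repr_and_predictor(self):
        ds = make_flat_dataset(12, n_domains=2)
        state = _mini_state(ds)
        part = state.model.partition()
        before = {k: [p.data.copy() for p in g] for k, g in part.groups().items()}
        state.stage_task(np.arange(8))
        for k, g in part.groups().items():
            same = all(np.array_equal(a, p.data) for a, p in zip(before[k], g))
            assert same == (k in ("theta_d",))

    def test_domain_loss_decreases_on_frozen_extractor(self):
        # with the extractor frozen, repeated stage-2 updates on one batch
        # monotonically improve the (convex-ish) head fit overall
        ds = make_flat_dataset(16, n_domains=2)
        state = _mini_state(ds)
        batch = np.arange(16)
        losses = [state.stage_domain(batch) for _ in range(30)]
        assert losses[-1] < losses[0]

    def test_confusion_update_reduces_confusion_loss(self):
        ds = make_flat_dataset(16, n_domains=2)
        state = _mini_state(ds, lr_confusion=1e-4)
        batch = np.arange(16)
        for _ in range(10):
            state.stage_domain(batch)
        from unlearn import losses as L
        before = L.confusion_from_logits(state._domain_logits(batch)).item()
        state.stage_confusion(batch)
        after = L.confusion_from_logits(state._domain_logits(batch)).item()
        assert after < before

    def test_unlearning_step_runs_confound_pair(self):
        ds = make_flat_dataset(16, n_domains=2)
        state = _mini_state(ds, confounds=[{"name": "sex", "n_classes": 2}])
        rec = unlearning_step(state, np.arange(8), np.arange(8),
                              {"sex": np.arange(8)})
        assert {"lp", "ld", "lconf", "lc_sex", "lcconf_sex"} <= set(rec)


# ---------------------------------------------------------------------------
# fit-level contracts
# ---------------------------------------------------------------------------


class TestFit:
    def test_normal_mode_history_has_no_adversarial_losses(self):
        ds = make_flat_dataset(10, n_domains=2)
        cfg = TrainConfig(task="regression", mode="normal", feature_dim=8,
                          width_scale=0.5, batch_size=8, pretrain_max_epochs=2,
                          unlearn_epochs=1, pretrain_patience=2, seed=0)
        state = fit(ds, cfg)
        hist = history_frame(state)
        assert "ld" not in hist.columns
        assert "lconf" not in hist.columns

    def test_unlearn_mode_records_all_losses(self):
        ds = make_flat_dataset(10, n_domains=2)
        cfg = TrainConfig(task="regression", mode="unlearn", feature_dim=8,
                          width_scale=0.5, batch_size=8, pretrain_max_epochs=2,
                          unlearn_epochs=2, pretrain_patience=2, seed=0)
        state = fit(ds, cfg)
        hist = history_frame(state)
        last = hist.iloc[-1]
        assert last["phase"] == "unlearn"
        assert np.isfinite(last["ld"]) and np.isfinite(last["lconf"])
        assert np.isfinite(last["total"])

    def test_validation_loss_improves_during_pretraining(self):
        ds = make_flat_dataset(24, n_domains=2, image_shape=(8, 8))
        cfg = TrainConfig(task="regression", mode="normal", feature_dim=8,
                          width_scale=0.5, batch_size=8, lr=1e-2,
                          pretrain_max_epochs=20, unlearn_epochs=0,
                          pretrain_patience=20, seed=0)
        state = fit(ds, cfg)
        hist = history_frame(state)
        assert hist["val_lp"].iloc[-1] <= hist["val_lp"].iloc[0]

    def test_semi_supervised_site_never_enters_task_stage(self):
        # site 2 has no labels: every stage-1 batch index must be in_p
        rng = np.random.default_rng(0)
        samples = []
        for d in (1, 2):
            for _ in range(12):
                labelled = d == 1
                samples.append(Sample(
                    image=rng.normal(size=(8, 8)), domain_label=d,
                    main_label=float(rng.uniform(20, 80)) if labelled else None,
                    in_p=labelled))
        ds = MultiSiteDataset(samples)
        state = _mini_state(ds, val_fraction=0.0)
        from unlearn.training import _epoch_batches
        streams = _epoch_batches(state, 0, unlearn=True)
        in_p = state.train.in_p
        for b in streams["p"]:
            assert in_p[b].all()
        # unlearning stream still covers both sites
        covered = set(state.train.domain_index[np.concatenate(streams["u"])])
        assert covered == {0, 1}

    def test_reproducibility_same_seed_same_history(self):
        ds1 = make_flat_dataset(10, n_domains=2, rng=np.random.default_rng(5))
        ds2 = make_flat_dataset(10, n_domains=2, rng=np.random.default_rng(5))
        cfg = dict(task="regression", mode="unlearn", feature_dim=8,
                   width_scale=0.5, batch_size=8, pretrain_max_epochs=2,
                   unlearn_epochs=2, pretrain_patience=2, seed=3)
        h1 = history_frame(fit(ds1, TrainConfig(**cfg)))
        h2 = history_frame(fit(ds2, TrainConfig(**cfg)))
        assert np.allclose(h1["val_lp"], h2["val_lp"])

    def test_soft_label_regression_trains_and_predicts(self):
        ds = make_flat_dataset(12, n_domains=2)
        cfg = TrainConfig(task="soft_regression", mode="unlearn", feature_dim=8,
                          width_scale=0.5, batch_size=8, pretrain_max_epochs=2,
                          unlearn_epochs=1, pretrain_patience=2,
                          bin_range=(0.0, 100.0), sigma=10.0, seed=0)
        state = fit(ds, cfg)
        from unlearn.training import predict_ages
        preds = predict_ages(state, state.train.images)
        assert preds.shape == (len(state.train),)
        assert np.all((preds >= 0) & (preds <= 100))
        assert np.isfinite(state.history[-1]["val_lp"])

    def test_pretrain_stage2_keeps_task_parameters_bit_identical(self):
        ds = make_flat_dataset(12, n_domains=2)
        state = _mini_state(ds)
        part = state.model.partition()
        repr_before = [p.data.copy() for p in part.theta_repr + part.theta_p]
        state.stage_domain(np.arange(8))
        repr_after = [p.data for p in part.theta_repr + part.theta_p]
        assert all(np.array_equal(a, b) for a, b in zip(repr_before, repr_after))
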