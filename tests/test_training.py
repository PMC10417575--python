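"""Plateau schedule, training loop behavior, grid enumeration, ablation
reporting, and hard-example ranking."""

import numpy as np
import pytest

from vesselseg.architecture import ArchitectureConfig, build_model
from vesselseg.losses import SENTINEL
from vesselseg.synthetic import BenchmarkPatch
from vesselseg.training import (
    GridBudget,
    GridSpec,
    PlateauSchedule,
    TrainingConfig,
    ablation_report,
    rank_hard_examples,
    run_grid,
    simulate_schedule,
    train,
)


def reference_schedule(losses, lr, patience, factor, max_plateaus, min_delta):
    """Independent straightforward re-implementation of the schedule."""
    events = []
    best = None  # epoch 1 sets the baseline without counting as improvement
    waited = consecutive = 0
    for epoch, loss in enumerate(losses, start=1):
        if best is not None and loss < best - min_delta:
            best, waited, consecutive = loss, 0, 0
            events.append((epoch, lr, False, False))
            continue
        if best is None:
            best = loss
        waited += 1
        plateau = waited >= patience
        if plateau:
            lr *= factor
            consecutive += 1
            waited = 0
        stop = consecutive >= max_plateaus
        events.append((epoch, lr, plateau, stop))
        if stop:
            break
    return events


class TestPlateauSchedule:
    def test_constant_trace_plateaus_every_patience_epochs(self):
        df = simulate_schedule([0.5] * 60, lr=1e-4)
        plateau_epochs = df.loc[df.plateau, "epoch"].tolist()
        assert plateau_epochs == [10, 20, 30, 40]
        assert len(df) == 40  # stopped at the fourth consecutive plateau
        assert df.lr.iloc[-1] == pytest.approx(1e-4 * 0.1 ** 4)

    def test_strictly_decreasing_trace_never_plateaus(self):
        losses = np.linspace(1.0, 0.1, 50)
        df = simulate_schedule(losses)
        assert not df.plateau.any()
        assert len(df) == 50

    def test_improvement_resets_consecutive_plateau_count(self):
        # three plateaus, then a real improvement, then more plateaus:
        # the stop counter must restart after the improvement
        trace = [1.0] + [1.0] * 30 + [0.5] + [0.5] * 40
        df = simulate_schedule(trace)
        stops = df.loc[df.stop, "epoch"]
        assert len(stops) == 1
        assert stops.iloc[0] == 32 + 40  # 4 consecutive plateaus after reset

    def test_learning_rate_is_non_increasing(self):
        rng = np.random.default_rng(0)
        df = simulate_schedule(rng.random(80))
        assert (np.diff(df.lr) <= 1e-18).all()

    def test_hundred_random_traces_match_reference_event_for_event(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(5, 120))
            losses = np.round(rng.random(n), 3)
            patience = int(rng.integers(2, 12))
            sched = PlateauSchedule(1e-4, patience, 0.1, 4, 1e-4)
            got = []
            for epoch, loss in enumerate(losses, start=1):
                plateau, stop = sched.step(float(loss))
                got.append((epoch, sched.lr, plateau, stop))
                if stop:
                    break
            expected = reference_schedule(losses, 1e-4, patience, 0.1, 4, 1e-4)
            assert got == expected


def tiny_patches(n, size=64, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        img = rng.random((size, size, 3), dtype=np.float32)
        mask = rng.integers(0, 6, size=(size, size)).astype(np.uint8)
        mask[rng.random((size, size)) < 0.8] = SENTINEL
        out.append((img, mask))
    return out


class TestTrainLoop:
    def test_identical_seeds_reproduce_history(self):
        pairs = tiny_patches(4)
        cfg = TrainingConfig(batch_size=2, learning_rate=1e-3, max_epochs=2)
        histories = []
        for _ in range(2):
            model = build_model(ArchitectureConfig(levels=2, base_width=4), seed=3)
            histories.append(train(model, pairs[:3], pairs[3:], cfg).history)
        assert histories[0].equals(histories[1])

    def test_loss_decreases_over_five_epochs_on_learnable_data(self, benchmark):
        pairs = [(p.image, p.scribble) for p in benchmark.patches]
        for seed in range(3):
            model = build_model(
                ArchitectureConfig(levels=2, base_width=4), seed=seed
            )
            cfg = TrainingConfig(batch_size=4, learning_rate=1e-2, max_epochs=5,
                                 init_seed=seed, shuffle_seed=seed)
            hist = train(model, pairs[:8], pairs[8:10], cfg).history
            assert hist.train_loss.iloc[4] < hist.train_loss.iloc[0]

    def test_empty_sets_rejected(self):
        model = build_model(ArchitectureConfig(levels=1, base_width=2))
        with pytest.raises(ValueError):
            train(model, [], tiny_patches(1), TrainingConfig())

    def test_summary_mentions_variant_and_epochs(self):
        pairs = tiny_patches(2)
        model = build_model(ArchitectureConfig(levels=2, base_width=4))
        res = train(model, pairs[:1], pairs[1:],
                    TrainingConfig(batch_size=1, max_epochs=1))
        text = res.summary()
        assert "baseline" in text and "epochs trained:   1" in text


class TestGrid:
    def test_full_space_enumerates_the_cartesian_product(self):
        # 6 batch sizes x 4 dropouts x 3 learning rates x 2^3 toggles
        assert len(GridSpec().combinations()) == 6 * 4 * 3 * 2 ** 3 == 576

    def test_restricted_space_runs_eight_toggle_rows(self, benchmark):
        space = GridSpec(batch_sizes=(4,), dropouts=(0.125,),
                         learning_rates=(1e-3,))
        budget = GridBudget(max_epochs=1, levels=1, base_width=2, subset=4)
        pairs = [(p.image, p.scribble) for p in benchmark.patches]
        table = run_grid(space, pairs[:6], pairs[6:8], budget)
        assert len(table) == 8
        assert (table.error == "").all()
        table2 = run_grid(space, pairs[:6], pairs[6:8], budget)
        assert table.equals(table2)  # same seeds, identical table

    def test_resume_skips_finished_rows(self, tmp_path, benchmark):
        space = GridSpec(batch_sizes=(4,), dropouts=(0.0,),
                         learning_rates=(1e-3,), residual_options=(False,),
                         recurrent_options=(False,))
        budget = GridBudget(max_epochs=1, levels=1, base_width=2, subset=2)
        pairs = [(p.image, p.scribble) for p in benchmark.patches]
        path = tmp_path / "grid.csv"
        first = run_grid(space, pairs[:4], pairs[4:6], budget, results_path=path)
        second = run_grid(space, pairs[:4], pairs[4:6], budget, results_path=path)
        assert list(first.combo) == list(second.combo)


class TestHardExampleRanking:
    @staticmethod
    def perfect_model():
        class M:
            def predict(self, image):
                # read the class the patch encodes in its red channel
                cls = int(round(float(image[0, 0, 0]) * 5))
                probs = np.zeros(image.shape[:2] + (6,))
                probs[..., cls] = 1.0
                return probs

        return M()

    @staticmethod
    def patch_of_class(cls, size=16):
        img = np.full((size, size, 3), cls / 5.0, dtype=np.float32)
        mask = np.full((size, size), SENTINEL, np.uint8)
        mask[::4, ::4] = cls
        return img, mask

    def test_perfect_predictions_rank_stably_by_id(self):
        patches = [self.patch_of_class(c % 6) for c in range(5)]
        df = rank_hard_examples(self.perfect_model(), patches)
        assert df.loss.max() < 1e-6
        assert df.id.tolist() == [0, 1, 2, 3, 4]

    def test_corrupted_labels_rank_first(self):
        patches = [self.patch_of_class(c % 6) for c in range(5)]
        img, _ = self.patch_of_class(2)
        bad_mask = np.full((16, 16), SENTINEL, np.uint8)
        bad_mask[::4, ::4] = 4  # scribbles contradict the image content
        patches.append((img, bad_mask))
        df = rank_hard_examples(self.perfect_model(), patches)
        assert df.id.iloc[0] == 5
        assert df.loss.iloc[0] > 0.9

    def test_output_is_permutation_of_input_ids(self):
        patches = [self.patch_of_class(c % 6) for c in range(7)]
        df = rank_hard_examples(self.perfect_model(), patches)
        assert sorted(df.id.tolist()) == list(range(7))


class TestAblationReport:
    def test_identical_replicates_have_zero_sd(self, benchmark):
        pairs = [(p.image, p.scribble) for p in benchmark.patches]
        model = build_model(ArchitectureConfig(levels=1, base_width=2), seed=0)
        res = train(model, pairs[:2], pairs[2:3],
                    TrainingConfig(batch_size=2, max_epochs=1))
        eval_set = benchmark.patches[:2]
        metrics_df, auc_df = ablation_report({"baseline": [res] * 3}, eval_set)
        assert (metrics_df.filter(like="_sd") == 0).all().all()
        assert metrics_df.parameters.iloc[0] == model.num_parameters()
        assert metrics_df.dropout.iloc[0] == 0.125
        assert "auc_macro" in auc_df.columns

    def test_missing_replicates_flagged(self):
        with pytest.raises(ValueError):
            ablation_report({"baseline": []}, [])
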