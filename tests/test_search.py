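import numpy as np
import pytest
from autograd import grad
from scipy import stats

from grnas.config import TrainConfig
from grnas.metrics import bce_loss
from grnas.model import (
    ArchitectureChoice,
    SearchSpace,
    init_model_params,
    model_forward,
    scorer_input_width,
)
from grnas.search import (
    ArchParams,
    GumbelDraw,
    _split_arrays,
    _theta_from,
    derive_architecture,
    gumbel_softmax_sample,
    mixed_operation,
    run_search,
    run_training,
    write_trajectory,
)


@pytest.fixture
def two_candidate_arch():
    return ArchParams(logits={"slot": np.log([2.0, 1.0])}, tau=1.0)


class TestGumbelSampling:
    def test_single_candidate_is_degenerate(self):
        arch = ArchParams(logits={"slot": np.zeros(1)})
        draw = gumbel_softmax_sample(arch, "slot", np.random.default_rng(0))
        assert draw.theta.tolist() == [1.0]
        assert draw.hard_index == 0

    def test_unknown_slot_treated_as_collapsed(self):
        arch = ArchParams(logits={})
        draw = gumbel_softmax_sample(arch, "other", np.random.default_rng(0))
        assert draw.hard_index == 0

    def test_theta_sums_to_one_on_every_draw(self, two_candidate_arch):
        rng = np.random.default_rng(1)
        for _ in range(500):
            draw = gumbel_softmax_sample(two_candidate_arch, "slot", rng)
            assert abs(draw.theta.sum() - 1.0) <= 1e-9
            assert (draw.theta >= 0).all()

    def test_hard_index_frequency_follows_beta_weights(self, two_candidate_arch):
        rng = np.random.default_rng(0)
        n = 20_000
        hits = sum(
            gumbel_softmax_sample(two_candidate_arch, "slot", rng).hard_index == 0
            for _ in range(n)
        )
        p = 2.0 / 3.0
        assert abs(hits - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_frequencies_pass_chi_square_across_seeds(self):
        beta = np.array([4.0, 2.0, 1.0])
        arch = ArchParams(logits={"slot": np.log(beta)})
        expected = 5000 * beta / beta.sum()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            counts = np.zeros(3)
            for _ in range(5000):
                counts[gumbel_softmax_sample(arch, "slot", rng).hard_index] += 1
            chi2 = ((counts - expected) ** 2 / expected).sum()
            assert chi2 < stats.chi2.ppf(0.999, df=2)

    def test_low_temperature_concentrates_draws(self):
        # tau -> 0 limit: at tau=1e-6 the soft sample is numerically one-hot
        arch = ArchParams(logits={"slot": np.log([2.0, 1.0])}, tau=1e-6)
        rng = np.random.default_rng(0)
        assert all(
            gumbel_softmax_sample(arch, "slot", rng).theta.max() >= 0.99
            for _ in range(1000)
        )

    def test_draw_contract_validation(self):
        with pytest.raises(Exception):
            GumbelDraw(theta=np.array([0.6, 0.6]), hard_index=0)
        with pytest.raises(Exception):
            GumbelDraw(theta=np.array([0.7, 0.3]), hard_index=1)


class TestMixedOperation:
    def test_hard_one_hot_selects_candidate_exactly(self, rng):
        x = rng.standard_normal(5)
        cands = [lambda v: v * 1.0, lambda v: v * 2.0, lambda v: v * 3.0]
        draw = GumbelDraw(theta=np.array([0.2, 0.1, 0.7]), hard_index=2)
        out = mixed_operation(x, cands, draw)
        assert np.array_equal(out, x * 3.0)  # bit-identical

    def test_scalar_worked_example(self):
        cands = [lambda v: v * 1, lambda v: v * 2, lambda v: v * 3]
        draw = GumbelDraw(theta=np.array([0.3, 0.4, 0.3]), hard_index=1)
        assert mixed_operation(5.0, cands, draw) == 10.0

    def test_same_hard_index_same_output(self, rng):
        x = rng.standard_normal(4)
        cands = [lambda v: np.sin(v), lambda v: np.cos(v)]
        d1 = GumbelDraw(theta=np.array([0.9, 0.1]), hard_index=0)
        d2 = GumbelDraw(theta=np.array([0.6, 0.4]), hard_index=0)
        assert np.array_equal(mixed_operation(x, cands, d1), mixed_operation(x, cands, d2))

    def test_gradient_reaches_architecture_logits(self):
        u = np.array([0.3, 0.8])

        def loss(logits):
            theta = _theta_from(logits, u, 1.0)
            from autograd.tracer import getval

            hard = np.zeros(2)
            hard[int(np.argmax(getval(theta)))] = 1.0
            st = hard + (theta - getval(theta))
            return st[0] * 1.0 + st[1] * 5.0

        g = grad(loss)(np.zeros(2))
        assert np.any(g != 0)


class TestDeriveArchitecture:
    def test_argmax_selection(self):
        space = SearchSpace()
        logits = {name: np.zeros(len(c)) for name, c in space.slots(2).items()}
        logits["pool"] = np.log([0.1, 5.0, 0.2])
        choice = derive_architecture(ArchParams(logits=logits), space, 2)
        assert choice.pool == "max"  # index 1 of (sum, max, concat)

    def test_exact_tie_takes_lowest_index_with_warning(self):
        space = SearchSpace()
        logits = {name: np.zeros(len(c)) for name, c in space.slots(2).items()}
        with pytest.warns(UserWarning, match="tie"):
            choice = derive_architecture(ArchParams(logits=logits), space, 2)
        assert choice.pool == "sum"
        assert choice.agg == ("mean", "mean")

    def test_report_field_schema(self):
        space = SearchSpace()
        logits = {name: np.zeros(len(c)) for name, c in space.slots(2).items()}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = derive_architecture(ArchParams(logits=logits), space, 2).to_report()
        assert set(report) == {"Agg", "Combine", "Activation", "LayerConnect", "LayerAgg", "Pool"}


class TestSearchPhase:
    def _small(self, small_graph, small_split, **cfg_kwargs):
        cfg = TrainConfig(hidden_dim=8, **cfg_kwargs)
        arrays = _split_arrays(small_graph, small_split, cfg)
        return cfg, arrays, small_split

    def test_trajectory_has_one_record_per_epoch(self, small_graph, small_split):
        cfg, arrays, split = self._small(small_graph, small_split, search_epochs=20)
        _, traj, _ = run_search(
            arrays, split.train.pairs, split.train.labels,
            split.valid.pairs, split.valid.labels, SearchSpace(), cfg,
        )
        assert len(traj) == 20
        assert all({"epoch", "train_loss", "valid_auroc", "architecture"} <= set(r) for r in traj)

    def test_same_seed_identical_final_logits(self, small_graph, small_split):
        cfg, arrays, split = self._small(small_graph, small_split, search_epochs=5, seed=3)
        results = []
        for _ in range(2):
            arch, _, _ = run_search(
                arrays, split.train.pairs, split.train.labels,
                split.valid.pairs, split.valid.labels, SearchSpace(), cfg,
            )
            results.append(arch)
        for k in results[0].logits:
            assert np.array_equal(results[0].logits[k], results[1].logits[k])

    def test_fully_collapsed_space_leaves_beta_untouched(self, small_graph, small_split):
        space = SearchSpace(
            intra_agg=("sum",), intra_combine=("sum",), intra_activation=("relu",),
            layer_connect=("stack",), layer_agg=("skip",), pool=("sum",),
        )
        cfg, arrays, split = self._small(small_graph, small_split, search_epochs=3)
        arch, traj, _ = run_search(
            arrays, split.train.pairs, split.train.labels,
            split.valid.pairs, split.valid.labels, space, cfg,
        )
        assert arch.logits == {}  # nothing to search: plain training
        assert len(traj) == 3

    def test_trajectory_csv_round_trip(self, tmp_path, small_graph, small_split):
        import pandas as pd

        cfg, arrays, split = self._small(small_graph, small_split, search_epochs=2)
        _, traj, _ = run_search(
            arrays, split.train.pairs, split.train.labels,
            split.valid.pairs, split.valid.labels, SearchSpace(), cfg,
        )
        path = write_trajectory(traj, tmp_path / "traj.csv")
        df = pd.read_csv(path)
        assert list(df.columns) == ["epoch", "phase", "train_loss", "valid_auroc", "architecture_json"]
        assert len(df) == 2


class TestRetrainPhase:
    def test_first_epoch_loss_matches_bce_at_initialisation(self, small_graph, small_split):
        cfg = TrainConfig(hidden_dim=8, train_epochs=1, batch_size=10_000, seed=5)
        arrays = _split_arrays(small_graph, small_split, cfg)
        choice = ArchitectureChoice()
        _, traj, _ = run_training(
            arrays, small_split.train.pairs, small_split.train.labels,
            small_split.valid.pairs, small_split.valid.labels, choice, cfg,
        )
        rng = np.random.default_rng(cfg.seed)
        params0 = init_model_params(
            rng, arrays["X"].shape[1], cfg.hidden_dim, 2, scorer_input_width(choice, cfg.hidden_dim)
        )
        probs = np.asarray(model_forward(params0, arrays, small_split.train.pairs, choice))
        assert np.isclose(traj[0]["train_loss"], bce_loss(probs, small_split.train.labels), atol=1e-7)

    def test_trajectory_records_and_fields(self, small_graph, small_split):
        cfg = TrainConfig(hidden_dim=8, train_epochs=20, seed=1)
        arrays = _split_arrays(small_graph, small_split, cfg)
        _, traj, best = run_training(
            arrays, small_split.train.pairs, small_split.train.labels,
            small_split.valid.pairs, small_split.valid.labels, ArchitectureChoice(), cfg,
        )
        assert len(traj) == 20
        assert 0 <= best < 20
        assert all(np.isfinite(r["train_loss"]) for r in traj)
        assert all(r["valid_auroc"] is not None for r in traj)

    def test_same_seed_identical_final_parameters(self, small_graph, small_split):
        cfg = TrainConfig(hidden_dim=8, train_epochs=3, seed=9)
        arrays = _split_arrays(small_graph, small_split, cfg)
        outs = [
            run_training(
                arrays, small_split.train.pairs, small_split.train.labels,
                small_split.valid.pairs, small_split.valid.labels, ArchitectureChoice(), cfg,
            )
            for _ in range(2)
        ]
        assert np.array_equal(outs[0][0]["proj"]["W"], outs[1][0]["proj"]["W"])
        assert outs[0][2] == outs[1][2]

    def test_dropout_training_still_deterministic(self, small_graph, small_split):
        cfg = TrainConfig(hidden_dim=8, train_epochs=2, dropout=0.2, seed=4)
        arrays = _split_arrays(small_graph, small_split, cfg)
        losses = []
        for _ in range(2):
            _, traj, _ = run_training(
                arrays, small_split.train.pairs, small_split.train.labels,
                small_split.valid.pairs, small_split.valid.labels, ArchitectureChoice(), cfg,
            )
            losses.append(traj[-1]["train_loss"])
        assert losses[0] == losses[1]
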