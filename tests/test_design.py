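import numpy as np
import pandas as pd
import pytest

from teploop.activity import ActivityTable
from teploop.design import (
    CapacityError,
    SelectionPolicy,
    TableOracle,
    run_campaign,
    run_round,
    select_candidates,
)
from teploop.ml import ModelConfig
from teploop.synthetic import LandscapeSpec, initial_screening_table, make_landscape

from conftest import SMALL_ALPHABET

FAST_CFG = ModelConfig(n_trees=80, grid=({"max_features": "sqrt"},), seed=0)


def small_policy(**kw):
    defaults = dict(
        pool_size=200, batch_size=20, n_top=10, n_cluster_reps=6, n_random=4,
        k_clusters=6, seed=0,
    )
    defaults.update(kw)
    return SelectionPolicy(**defaults)


@pytest.fixture(scope="module")
def small_campaign_inputs(small_context):
    spec = LandscapeSpec(seed=555)
    oracle = make_landscape(spec, scales=small_context.scales)
    initial = initial_screening_table(
        oracle, seed=5, n_total=60, n_screen=400, n_top=40,
        alphabet=SMALL_ALPHABET,
    )
    return oracle, initial


class TestSelectionPolicy:
    def test_strata_must_sum_to_batch(self):
        with pytest.raises(ValueError):
            SelectionPolicy(batch_size=50, n_top=30, n_cluster_reps=10, n_random=5)

    def test_pool_must_cover_batch(self):
        with pytest.raises(ValueError):
            SelectionPolicy(pool_size=10, batch_size=50, n_top=50,
                            n_cluster_reps=0, n_random=0)


class TestSelectCandidates:
    def test_pure_top_policy_returns_highest_predicted(self, small_context):
        preds = np.linspace(0, 1, len(small_context.peptides))
        policy = small_policy(n_top=20, n_cluster_reps=0, n_random=0)
        batch = select_candidates(
            small_context.peptides, preds,
            small_context.X.to_numpy(), policy,
        )
        order = np.argsort(-preds, kind="stable")
        expected = sorted(
            (small_context.peptides[i] for i in order[:20]),
            key=lambda p: (-preds[small_context.index[p]], p),
        )
        assert sorted(batch, key=lambda p: (-preds[small_context.index[p]], p)) == expected
        assert len(batch) == 20

    def test_forced_selection_when_space_nearly_exhausted(self, small_context):
        preds = np.arange(len(small_context.peptides), dtype=float)
        keep = set(small_context.peptides[:20])
        exclude = frozenset(p for p in small_context.peptides if p not in keep)
        batch = select_candidates(
            small_context.peptides, preds, small_context.X.to_numpy(),
            small_policy(), exclude=exclude,
        )
        assert sorted(batch) == sorted(keep)

    def test_capacity_error(self, small_context):
        preds = np.zeros(len(small_context.peptides))
        exclude = frozenset(small_context.peptides[:-5])
        with pytest.raises(CapacityError):
            select_candidates(
                small_context.peptides, preds, small_context.X.to_numpy(),
                small_policy(), exclude=exclude,
            )

    def test_excluded_never_selected(self, small_context, rng):
        preds = rng.uniform(size=len(small_context.peptides))
        exclude = frozenset(small_context.peptides[i] for i in rng.choice(
            len(small_context.peptides), 300, replace=False))
        batch = select_candidates(
            small_context.peptides, preds, small_context.X.to_numpy(),
            small_policy(), exclude=exclude,
        )
        assert not set(batch) & exclude
        assert len(batch) == len(set(batch)) == 20

    def test_cluster_reps_cover_planted_clusters(self):
        # 10 well-separated blobs in feature space; reps should span >= 8
        rng = np.random.default_rng(0)
        centers = rng.normal(scale=50, size=(10, 6))
        feats, names = [], []
        for c, center in enumerate(centers):
            for i in range(40):
                feats.append(center + rng.normal(scale=0.1, size=6))
                names.append(f"blob{c}_{i:02d}")
        feats = np.asarray(feats)
        preds = rng.uniform(size=len(names))
        policy = SelectionPolicy(
            pool_size=400, batch_size=10, n_top=0, n_cluster_reps=10,
            n_random=0, k_clusters=10, seed=1,
        )
        batch = select_candidates(names, preds, feats, policy)
        blobs = {name.split("_")[0] for name in batch}
        assert len(blobs) >= 8


class TestRunRound:
    def test_zero_batch_advances_round_only(self, small_context, small_campaign_inputs):
        oracle, initial = small_campaign_inputs
        from teploop.design import RoundState

        state = RoundState(
            round_index=0, training=initial, cv=None, candidates=[],
            candidate_predictions=np.empty(0), r_history=[],
        )
        policy = small_policy(batch_size=0, n_top=0, n_cluster_reps=0, n_random=0)
        out = run_round(state, oracle, policy, FAST_CFG, small_context)
        assert out.round_index == 1
        assert len(out.training) == len(initial)
        assert out.candidates == []
        assert len(out.r_history) == 1

    def test_candidates_disjoint_from_training(self, small_context, small_campaign_inputs):
        oracle, initial = small_campaign_inputs
        from teploop.design import RoundState

        state = RoundState(
            round_index=0, training=initial, cv=None, candidates=[],
            candidate_predictions=np.empty(0), r_history=[],
        )
        out = run_round(state, oracle, small_policy(), FAST_CFG, small_context)
        assert not set(out.candidates) & set(initial.peptides)
        assert len(out.training) == len(initial) + 20


class TestRunCampaign:
    def test_round_size_accounting(self, small_context, small_campaign_inputs):
        oracle, initial = small_campaign_inputs
        history = run_campaign(
            initial, oracle, n_rounds=3, policy=small_policy(),
            config=FAST_CFG, context=small_context,
            batch_sizes=[20, 10, 0], seed=9,
        )
        # each round trains on the table before its batch is appended
        assert list(history.summary()["n_training"]) == [60, 80, 90]
        assert [len(s.training) for s in history.rounds] == [80, 90, 90]

    def test_single_round_history(self, small_context, small_campaign_inputs):
        oracle, initial = small_campaign_inputs
        history = run_campaign(
            initial, oracle, n_rounds=1, policy=small_policy(),
            config=FAST_CFG, context=small_context, seed=2,
        )
        assert len(history.rounds) == 1

    def test_same_seed_identical_trajectory(self, small_context, small_campaign_inputs):
        oracle, initial = small_campaign_inputs
        kw = dict(
            initial=initial, oracle=oracle, n_rounds=2, policy=small_policy(),
            config=FAST_CFG, context=small_context, batch_sizes=[20, 0], seed=4,
        )
        a = run_campaign(**kw)
        b = run_campaign(**kw)
        pd.testing.assert_frame_equal(a.summary(), b.summary())
        assert a.rounds[0].candidates == b.rounds[0].candidates

    def test_training_strictly_grows_and_batches_unseen(
        self, small_context, small_campaign_inputs
    ):
        oracle, initial = small_campaign_inputs
        history = run_campaign(
            initial, oracle, n_rounds=3, policy=small_policy(),
            config=FAST_CFG, context=small_context,
            batch_sizes=[20, 20, 0], seed=8,
        )
        seen = set(initial.peptides)
        for state in history.rounds:
            assert not set(state.candidates) & seen
            seen |= set(state.candidates)
        sizes = [len(s.training) for s in history.rounds]
        assert sizes == sorted(sizes)

    def test_top100_summaries_available(self, small_context, small_campaign_inputs):
        oracle, initial = small_campaign_inputs
        history = run_campaign(
            initial, oracle, n_rounds=1, policy=small_policy(),
            config=FAST_CFG, context=small_context, seed=3,
        )
        logos = history.top100_logos()
        adj = history.top100_adjacency()
        assert set(logos) == set(adj) == {1}
        np.testing.assert_allclose(logos[1].sum(axis=0), 1.0)
        assert adj[1].to_numpy().sum() == 3 * 100


class TestTableOracle:
    def test_lookup_matches_file(self, tmp_path):
        table = ActivityTable.from_records(
            [
                {"peptide": "SKIK", "relative_intensity": 1.0},
                {"peptide": "NNDD", "relative_intensity": 1.4},
            ],
            normalized=True,
        )
        path = tmp_path / "lab.csv"
        table.to_csv(path)
        oracle = TableOracle.from_csv(path)
        out = oracle(["NNDD"], seed=0, round_label=2)
        assert out.df["relative_intensity"].iloc[0] == pytest.approx(1.4)
        assert out.df["round"].iloc[0] == 2

    def test_unknown_peptide_raises(self):
        oracle = TableOracle(
            ActivityTable.from_records(
                [{"peptide": "SKIK", "relative_intensity": 1.0}], normalized=True
            )
        )
        with pytest.raises(KeyError):
            oracle(["AAAA"])
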