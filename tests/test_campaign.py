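"""Scoring the combinatorial space, batch selection, and the campaign loop."""

import numpy as np
import pandas as pd
import pytest

import thermocomb as tc
from thermocomb.synthetic import default_initial_counts
from thermocomb.variants import WILD_TYPE, parse_variant

from conftest import split_space


@pytest.fixture(scope="module")
def trained_heads(request):
    """Regression + discriminant heads fitted on a 10-site additive landscape."""
    ls = request.getfixturevalue("additive_landscape_10")
    train_v, _ = split_space(ls, 120, 0, seed=13)
    records = [
        tc.VariantRecord(
            variant=v, tm=ls.tm(v),
            relative_activity=max(0.0, 100.0 - 10.0 * v.order),
        )
        for v in [WILD_TYPE] + train_v
    ]
    cfg_tm = tc.HeadConfig(learning_rate=0.01, max_epochs=300, patience=30, seed=0)
    cfg_act = tc.HeadConfig(task="discriminant", learning_rate=0.01,
                            max_epochs=400, patience=60, seed=0)
    res_tm = tc.StabilityModel(records, ls.wild_type, config=cfg_tm).fit()
    res_act = tc.StabilityModel(records, ls.wild_type, config=cfg_act).fit()
    return ls, res_tm, res_act


class TestScoreSpace:
    def test_scores_full_space(self, trained_heads):
        ls, res_tm, res_act = trained_heads
        ranked = tc.score_space(res_tm, res_act, ls.candidates)
        assert len(ranked) == 2**10
        assert ranked["tm_score"].is_monotonic_decreasing
        assert set(ranked.columns) >= {"variant", "order", "tm_score",
                                       "acceptable", "probability"}

    def test_single_candidate_space_has_two_variants(self, trained_heads):
        ls, res_tm, res_act = trained_heads
        cs = tc.CandidateSet(ls.wild_type, (ls.candidates.candidates[0],))
        ranked = tc.score_space(res_tm, res_act, cs)
        assert len(ranked) == 2
        assert "WT" in set(ranked["variant"])

    def test_top_of_ranking_is_all_beneficial_combination(self, trained_heads):
        ls, res_tm, res_act = trained_heads
        ranked = tc.score_space(res_tm, res_act, ls.candidates)
        # restrict to orders the activity rule accepts (order <= 3 at 10%/mutation)
        acceptable = ranked[ranked["acceptable"]]
        best_pred = acceptable.iloc[0]["variant"]
        truth = {
            str(v): ls.tm(v)
            for v in tc.enumerate_combinations(ls.candidates, orders=range(4))
        }
        best_true = max(truth, key=truth.get)
        assert best_pred == best_true


class TestSelectBatch:
    def _ranked(self):
        rows = []
        for order in (1, 2, 3):
            for i in range(6):
                rows.append({
                    "variant": f"A{10*order + i}C", "order": order,
                    "tm_score": 70.0 - order - 0.1 * i,
                    "acceptable": i < 5, "probability": 0.9,
                })
        return pd.DataFrame(rows).sort_values("tm_score", ascending=False)

    def test_stratified_quota_per_order(self):
        policy = tc.SelectionPolicy(batch_size=9, stratify_by_order=True,
                                    orders=(1, 2, 3))
        batch = tc.select_batch(self._ranked(), policy)
        assert len(batch) == 9
        assert batch.groupby("order").size().tolist() == [3, 3, 3]

    def test_flat_top_of_ranking(self):
        policy = tc.SelectionPolicy(batch_size=4)
        batch = tc.select_batch(self._ranked(), policy)
        assert len(batch) == 4
        assert batch["tm_score"].tolist() == sorted(
            batch["tm_score"], reverse=True)

    def test_unacceptable_variants_never_selected(self):
        policy = tc.SelectionPolicy(batch_size=15)
        batch = tc.select_batch(self._ranked(), policy)
        assert batch["acceptable"].all()

    def test_excluded_variants_skipped_for_next_best(self):
        ranked = self._ranked()
        policy = tc.SelectionPolicy(batch_size=3)
        top = tc.select_batch(ranked, policy)
        batch = tc.select_batch(ranked, policy, exclude=set(top["variant"]))
        assert not set(batch["variant"]) & set(top["variant"])

    def test_underfilled_stratum_warns(self):
        policy = tc.SelectionPolicy(batch_size=18, stratify_by_order=True,
                                    orders=(1, 2, 3))
        with pytest.warns(UserWarning, match="quota"):
            batch = tc.select_batch(self._ranked(), policy)
        assert len(batch) == 15  # only 5 acceptable per stratum

    def test_quota_must_sum_to_batch(self):
        with pytest.raises(ValueError):
            tc.SelectionPolicy(batch_size=25, stratify_by_order=True,
                               orders=(5, 6, 7, 8, 9), per_stratum_quota=4)


@pytest.fixture(scope="module")
def campaign_results(creatinase_landscape_12):
    ls = creatinase_landscape_12
    initial = tc.sample_initial_dataset(
        ls, counts=default_initial_counts(12), seed=5)
    oracle = tc.LandscapeOracle(ls, seed=6)
    cfg = tc.HeadConfig(learning_rate=0.01, max_epochs=300, patience=30, seed=0)
    policies = [
        tc.SelectionPolicy(batch_size=25, stratify_by_order=True,
                           orders=(5, 6, 7, 8, 9)),
        tc.SelectionPolicy(batch_size=25),
    ]
    results = tc.run_campaign(initial, ls.candidates, oracle, 2, cfg,
                              policies=policies, seed=0)
    return ls, initial, results


class TestCampaign:
    def test_two_rounds_of_25(self, campaign_results):
        _, _, results = campaign_results
        assert [r.round_index for r in results] == [1, 2]
        assert all(len(r.selected) == 25 for r in results)

    def test_round1_stratified_5_per_order(self, campaign_results):
        _, _, results = campaign_results
        counts = results[0].selected.groupby("order").size()
        assert counts.loc[[5, 6, 7, 8, 9]].tolist() == [5, 5, 5, 5, 5]

    def test_best_measured_tm_non_decreasing(self, campaign_results):
        _, _, results = campaign_results
        assert results[1].best_measured_tm >= results[0].best_measured_tm

    def test_simple_regret_non_increasing(self, campaign_results):
        ls, _, results = campaign_results
        _, opt_tm = ls.optimum()
        best = -np.inf
        regrets = []
        for r in results:
            best = max(best, max(ls.tm(rec.variant) for rec in r.measured))
            regrets.append(opt_tm - best)
        assert regrets[1] <= regrets[0]
        assert all(r >= 0 for r in regrets)

    def test_selections_disjoint_from_training_and_across_rounds(self, campaign_results):
        _, initial, results = campaign_results
        initial_keys = {str(r.variant) for r in initial}
        r1 = set(results[0].selected["variant"])
        r2 = set(results[1].selected["variant"])
        assert not r1 & initial_keys
        assert not r2 & initial_keys
        assert not r1 & r2

    def test_training_set_grows_by_batch_size(self, campaign_results):
        _, initial, results = campaign_results
        assert results[0].training_size == len(initial)
        assert results[1].training_size == len(initial) + 25

    def test_synergistic_pair_frequency_non_decreasing(self, campaign_results):
        ls, initial, results = campaign_results
        from thermocomb.epistasis import pair_frequency
        pair = [ls.candidates.candidates[i] for i in ls.spec.synergy_pair]
        collections = [[r.variant for r in initial]] + [
            [parse_variant(s) for s in r.selected["variant"]] for r in results
        ]
        freqs = [c / t for c, t in pair_frequency(collections, pair)]
        assert freqs[0] <= freqs[1] <= freqs[2]

    def test_zero_rounds_returns_empty(self, creatinase_landscape_12):
        ls = creatinase_landscape_12
        out = tc.run_campaign([], ls.candidates, tc.LandscapeOracle(ls), 0,
                              tc.HeadConfig())
        assert out == []

    def test_rerun_with_same_seed_is_identical(self, campaign_results, creatinase_landscape_12):
        ls, initial, results = campaign_results
        oracle = tc.LandscapeOracle(ls, seed=6)
        cfg = tc.HeadConfig(learning_rate=0.01, max_epochs=300, patience=30, seed=0)
        policies = [
            tc.SelectionPolicy(batch_size=25, stratify_by_order=True,
                               orders=(5, 6, 7, 8, 9)),
            tc.SelectionPolicy(batch_size=25),
        ]
        rerun = tc.run_campaign(initial, ls.candidates, oracle, 2, cfg,
                                policies=policies, seed=0)
        for a, b in zip(results, rerun):
            assert a.selected["variant"].tolist() == b.selected["variant"].tolist()


def test_csv_round_trip_oracle(tmp_path, creatinase_landscape_12):
    ls = creatinase_landscape_12
    oracle = tc.CsvRoundTripOracle(tmp_path, ls.wild_type)
    variants = [ls.variant_from_indices([0]), ls.variant_from_indices([1])]
    with pytest.raises(FileNotFoundError, match="requests_round1"):
        oracle.measure(variants, round_index=1)
    assert (tmp_path / "requests_round1.csv").exists()
    pd.DataFrame({
        "variant": [str(v) for v in variants],
        "tm_celsius": [58.6, 59.0],
        "relative_activity_percent": [95.0, 97.0],
        "round": [1, 1],
    }).to_csv(tmp_path / "measurements_round1.csv", index=False)
    records = oracle.measure(variants, round_index=1)
    assert len(records) == 2
    assert records[0].tm == 58.6
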