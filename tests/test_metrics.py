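import math

import numpy as np
import pytest
import scipy.stats
from sklearn.metrics import matthews_corrcoef, precision_score, recall_score

from plmfuse import metrics as M
from plmfuse.types import LabelTrack


class TestQ3:
    @pytest.mark.parametrize("pred, obs, expected", [
        ("HHHHHHHHEO", "HHHHHHHHHH", 80.0),
        ("HEO", "HEO", 100.0),
        ("HHH", "EEE", 0.0),
    ])
    def test_direct_count(self, pred, obs, expected):
        assert M.q3(pred, obs) == expected

    def test_accepts_label_tracks(self):
        assert M.q3(LabelTrack.categorical("HE"), LabelTrack.categorical("HO")) == 50.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            M.q3("HE", "H")

    def test_relabeling_invariance(self, rng):
        mapping = {"H": "E", "E": "O", "O": "H"}
        for _ in range(20):
            n = rng.integers(1, 30)
            pred = "".join(rng.choice(list("HEO"), n))
            obs = "".join(rng.choice(list("HEO"), n))
            relab = lambda s: "".join(mapping[c] for c in s)
            assert M.q3(pred, obs) == M.q3(relab(pred), relab(obs))


class TestAggregation:
    def test_zero_spread(self):
        rep = M.aggregate_per_chain([80.0, 80.0, 80.0])
        assert (rep.mean, rep.sd, rep.se) == (80.0, 0.0, 0.0)

    def test_se_follows_sd_over_sqrt_n_minus_1(self):
        values = [78.0, 80.0, 82.0, 84.0, 76.0]
        rep = M.aggregate_per_chain(values)
        assert rep.sd == pytest.approx(np.std(values))
        assert rep.se == pytest.approx(np.std(values) / 2.0)
        assert rep.ci95_halfwidth == pytest.approx(1.96 * rep.se)

    def test_single_chain_flags_undefined(self):
        rep = M.aggregate_per_chain([50.0])
        assert rep.mean == 50.0
        assert rep.sd is None and rep.se is None


class TestSpearman:
    def test_perfect_orders(self):
        assert M.spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert M.spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert M.spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_flagged(self):
        assert math.isnan(M.spearman([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(200):
            n = rng.integers(3, 30)
            u = rng.integers(0, 5, n).astype(float)
            v = rng.integers(0, 5, n).astype(float)
            if np.ptp(u) == 0 or np.ptp(v) == 0:
                continue
            expected = scipy.stats.spearmanr(u, v).statistic
            assert M.spearman(u, v) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetric_under_inversion(self, rng):
        u = rng.normal(size=20)
        v = rng.normal(size=20)
        assert M.spearman(u, -v) == pytest.approx(-M.spearman(u, v))


class TestF1:
    def test_perfect_prediction(self):
        out = M.f1_binary("BBNN", "BBNN", positive="B")
        assert out == {"precision": 100.0, "recall": 100.0, "f1": 100.0}

    def test_hand_arithmetic(self):
        # TP=2, FP=1, FN=1
        out = M.f1_binary("BBBN", "BBNB", positive="B")
        assert out["precision"] == pytest.approx(200 / 3)
        assert out["recall"] == pytest.approx(200 / 3)
        assert out["f1"] == pytest.approx(200 / 3)

    def test_no_predicted_positives_convention(self):
        out = M.f1_binary("NNN", "BNN", positive="B")
        assert math.isnan(out["precision"])
        assert out["recall"] == 0.0
        assert out["f1"] == 0.0

    def test_matches_sklearn(self, rng):
        for _ in range(200):
            n = rng.integers(2, 30)
            pred = rng.choice(["B", "N"], n)
            obs = rng.choice(["B", "N"], n)
            if "B" not in pred or "B" not in obs:
                continue
            out = M.f1_binary("".join(pred), "".join(obs), positive="B")
            assert out["precision"] == pytest.approx(
                100 * precision_score(obs, pred, pos_label="B"))
            assert out["recall"] == pytest.approx(
                100 * recall_score(obs, pred, pos_label="B"))


class TestMcc:
    def test_perfect_and_inverted(self):
        obs = [1, 2, 7, 9, 3, 8]
        assert M.mcc_conservation(obs, obs) == pytest.approx(1.0)
        inverted = [9 if o <= 5 else 1 for o in obs]
        assert M.mcc_conservation(inverted, obs) == pytest.approx(-1.0)

    def test_hand_table(self):
        # TP=3, TN=3, FP=1, FN=1 -> (9-1)/sqrt(4^4) = 0.5
        obs = [9, 9, 9, 1, 1, 1, 1, 9]
        pred = [9, 9, 9, 1, 1, 1, 9, 1]
        assert M.mcc_conservation(pred, obs) == pytest.approx(0.5)

    def test_degenerate_table_flagged(self):
        assert math.isnan(M.mcc_conservation([9, 9], [9, 9]))

    def test_matches_sklearn_binarization(self, rng):
        for _ in range(200):
            n = rng.integers(2, 30)
            pred = rng.integers(1, 10, n)
            obs = rng.integers(1, 10, n)
            got = M.mcc_conservation(pred, obs)
            expected = matthews_corrcoef(obs > 5, pred > 5)
            if math.isnan(got):
                assert expected == 0.0 or len(set(obs > 5)) == 1
            else:
                assert got == pytest.approx(expected, abs=1e-12)


class TestSegments:
    @pytest.mark.parametrize("labels, expected", [
        ("OOHHHOO", [(2, 5)]),
        ("HHOHH", [(0, 2), (3, 5)]),
        ("OOO", []),
        ("HHHH", [(0, 4)]),
    ])
    def test_extraction(self, labels, expected):
        segs = M.extract_segments(labels, "H")
        assert [(s.start, s.end) for s in segs] == expected

    @pytest.mark.parametrize("pred, obs, expected", [
        ((12, 29), (10, 31), True),    # shifts 2,2; intersection 17 >= union 21/2
        ((10, 51), (10, 31), False),   # end shift 20 > 5
        ((10, 31), (10, 31), True),
        ((5, 8), (10, 13), False),     # start shift 5 ok but no half-union overlap
    ])
    def test_matching_rule(self, pred, obs, expected):
        p = M.Segment("T", *pred)
        o = M.Segment("T", *obs)
        assert M.segment_match(p, o) is expected

    def test_match_monotone_under_perturbation_beyond_rule(self):
        obs = M.Segment("T", 20, 40)
        assert M.segment_match(M.Segment("T", 20, 45), obs)
        assert not M.segment_match(M.Segment("T", 20, 46), obs)


class TestQok:
    def test_direct_count(self):
        good = ("OTTTO", "OTTTO")
        bad = ("TOOOO", "OOOTT")
        assert M.q_ok([good, good, bad], "T") == pytest.approx(200 / 3)

    def test_protein_without_observed_segments_excluded(self):
        no_obs = ("OTTTO", "OOOOO")
        good = ("OTTTO", "OTTTO")
        assert M.q_ok([good, no_obs], "T") == 100.0

    def test_extra_predicted_segment_fails_protein(self):
        pred = "TTOOOTT"
        obs = "TTOOOOO"
        assert M.q_ok([(pred, obs)], "T") == 0.0


class TestBaselines:
    def test_uniform_three_states(self):
        out = M.baseline_shuffle_labels([1 / 3] * 3, 100_000, seed=0)
        assert out["expected"] == pytest.approx(100 / 3)
        assert out["simulated"] == pytest.approx(100 / 3, abs=0.5)

    def test_uniform_ten_states(self):
        out = M.baseline_shuffle_labels([0.1] * 10, 100_000, seed=0)
        assert out["expected"] == pytest.approx(10.0)
        assert out["simulated"] == pytest.approx(10.0, abs=0.5)

    def test_degenerate_distribution(self):
        out = M.baseline_shuffle_labels([1.0, 0.0, 0.0], 100, seed=0)
        assert out["expected"] == 100.0
        assert out["simulated"] == 100.0

    def test_majority_class(self):
        tracks = ["OOOHHE", "OOOE"]
        cls, q = M.baseline_majority(tracks, ("H", "E", "O"))
        assert cls == "O"
        assert q == pytest.approx(60.0)

    def test_majority_tie_breaks_to_lowest_index(self):
        cls, q = M.baseline_majority(["HO"], ("H", "E", "O"))
        assert cls == "H"
        assert q == 50.0

    def test_all_one_class(self):
        cls, q = M.baseline_majority(["HHHH"], ("H", "E", "O"))
        assert (cls, q) == ("H", 100.0)


class TestQ10:
    def test_counts(self):
        pred = list("ABCDEFGHIJ")
        obs = list("ABCDEFGXYZ")
        assert M.q10(pred, obs) == 70.0
        assert M.q10(obs, obs) == 100.0
        assert M.q10(["A"] * 4, ["B"] * 4) == 0.0
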