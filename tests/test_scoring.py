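"""Slide scoring, Mann-Whitney AUC vs brute force, ensembles, correlations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histocart import (
    TileGrid,
    TilePredictionSet,
    correlate_scores,
    ensemble_predictions,
    ensemble_vote,
    predict_tiles,
    select_top_models,
    slide_auc,
    slide_score,
)


def auc_bruteforce(scores, labels):
    """Exhaustive pairwise enumeration: the Mann-Whitney definition."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def preds_frame(bits, slide_id="S", trait="t", model="1"):
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "row": 0,
            "col": range(len(bits)),
            "trait": trait,
            "model": model,
            "prediction": bits,
        }
    )


class TestSlideScore:
    @pytest.mark.parametrize(
        "bits, expected",
        [([1, 0, 0, 1, 0, 1, 0, 0], 0.375), ([1, 1, 1], 1.0), ([0, 0], 0.0)],
    )
    def test_fraction_positive(self, bits, expected):
        assert slide_score(preds_frame(bits)) == expected

    def test_invariant_under_tile_permutation(self, rng):
        bits = rng.integers(0, 2, 50).tolist()
        shuffled = list(bits)
        rng.shuffle(shuffled)
        assert slide_score(preds_frame(bits)) == slide_score(preds_frame(shuffled))

    def test_empty_slide_rejected(self):
        with pytest.raises(ValueError):
            slide_score(preds_frame([]))


class TestSlideAUC:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),   # perfect separation
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),   # pure ties
            # 4-pair enumeration: wins (0.9>0.4, 0.9>0.7), tie (0.4=0.4),
            # loss (0.4<0.7) -> 2.5/4
            ([0.9, 0.4, 0.4, 0.7], [1, 0, 1, 0], 0.625),
        ],
    )
    def test_worked_values(self, scores, labels, expected):
        assert slide_auc(scores, labels) == pytest.approx(expected)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12),
        data=st.data(),
    )
    def test_equals_bruteforce_enumeration(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda l: 0 < sum(l) < n
            )
        )
        assert slide_auc(scores, labels) == pytest.approx(
            auc_bruteforce(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            slide_auc([0.1, 0.9], [1, 1])


class TestModelSelection:
    def test_top_three_by_validation_auc(self):
        assert set(select_top_models([0.6, 0.9, 0.7, 0.8, 0.5])) == {2, 4, 3}

    def test_ties_prefer_lower_round(self):
        assert select_top_models([0.7] * 5) == [1, 2, 3]

    def test_k_equals_rounds_returns_all(self):
        assert set(select_top_models([0.1, 0.2, 0.3, 0.4, 0.5], k=5)) == {1, 2, 3, 4, 5}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            select_top_models([0.5] * 5, k=6)


class TestEnsembleVote:
    def test_worked_example(self):
        assert ensemble_vote([0, 0, 1]) == 0

    @pytest.mark.parametrize("votes", list(itertools.product([0, 1], repeat=3)))
    def test_exhaustive_majority_rule(self, votes):
        assert ensemble_vote(votes) == (1 if sum(votes) >= 2 else 0)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError):
            ensemble_vote([1, 0])

    def test_flip_one_member_changes_vote_only_on_disagreement(self, rng):
        """Flipping one vote flips the majority iff the other two disagree."""
        for _ in range(50):
            votes = rng.integers(0, 2, 3).tolist()
            i = int(rng.integers(3))
            flipped = list(votes)
            flipped[i] = 1 - flipped[i]
            others = [v for j, v in enumerate(votes) if j != i]
            changed = ensemble_vote(votes) != ensemble_vote(flipped)
            assert changed == (others[0] != others[1])


class TestEnsemblePredictions:
    def test_tilewise_majority_across_rounds(self):
        frames = [
            preds_frame(bits, model=str(m))
            for m, bits in enumerate([[1, 0, 0], [1, 1, 0], [0, 0, 1]], start=1)
        ]
        preds = TilePredictionSet(pd.concat(frames, ignore_index=True))
        ens = ensemble_predictions(preds, "t", [1, 2, 3])
        out = ens.frame.sort_values("col")["prediction"].tolist()
        assert out == [1, 0, 0]
        assert set(ens.frame["model"]) == {"ensemble"}

    def test_missing_member_vote_rejected(self):
        frames = [preds_frame([1, 0], model="1"), preds_frame([1], model="2"),
                  preds_frame([1, 1], model="3")]
        preds = TilePredictionSet(pd.concat(frames, ignore_index=True))
        with pytest.raises(ValueError, match="incomplete"):
            ensemble_predictions(preds, "t", [1, 2, 3])


class TestPredictTiles:
    def test_constant_predictor(self, full_grid):
        grid = full_grid(2, 3)
        tiles = {pos: np.zeros((4, 4, 3), np.uint8) for pos in grid.retained_positions()}
        preds, failed = predict_tiles(lambda t: 1, tiles, grid, trait="t")
        assert len(preds.frame) == 6
        assert not failed
        assert slide_score(preds.frame) == 1.0

    def test_background_tiles_skipped(self, full_grid):
        grid = full_grid(2, 2)
        grid.retained[1, 1] = False
        tiles = {pos: np.zeros((4, 4, 3), np.uint8) for pos in grid.retained_positions()}
        preds, _ = predict_tiles(lambda t: 0, tiles, grid, trait="t")
        assert len(preds.frame) == 3
        assert (1, 1) not in set(zip(preds.frame["row"], preds.frame["col"]))

    def test_predictor_failure_flags_slide_incomplete(self, full_grid):
        grid = full_grid(1, 3)
        tiles = {pos: np.zeros((4, 4, 3), np.uint8) for pos in grid.retained_positions()}

        def flaky(tile, _calls=[]):
            _calls.append(1)
            if len(_calls) == 2:
                raise RuntimeError("boom")
            return 1

        preds, failed = predict_tiles(flaky, tiles, grid, trait="t")
        assert failed == [(0, 1)]
        assert len(preds.frame) == 2


class TestCorrelateScores:
    def test_monotone_and_antimonotone(self):
        p = np.linspace(0.1, 1.0, 10)
        out = correlate_scores({"up": p, "down": p[::-1]}, {"up": p, "down": p})
        rho = dict(zip(out["trait"], out["rho"]))
        assert rho["up"] == pytest.approx(1.0)
        assert rho["down"] == pytest.approx(-1.0)

    def test_matches_rank_difference_formula(self):
        """5-point hand example: rho = 1 - 6*sum(d^2) / (n(n^2-1))."""
        scores = np.array([0.1, 0.9, 0.3, 0.8, 0.5])
        pct = np.array([0.2, 1.0, 0.6, 0.8, 0.4])
        from scipy.stats import rankdata

        d = rankdata(scores) - rankdata(pct)
        expected = 1 - 6 * (d ** 2).sum() / (5 * 24)
        out = correlate_scores({"t": scores}, {"t": pct})
        assert out.loc[0, "rho"] == pytest.approx(expected)

    def test_fdr_adjusts_across_traits(self, rng):
        scores = {f"t{i}": rng.random(20) for i in range(4)}
        pct = {f"t{i}": rng.random(20) for i in range(4)}
        out = correlate_scores(scores, pct)
        assert (out["fdr_p"] >= out["p_value"] - 1e-12).all()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_scores({"t": np.ones(5)}, {"t": np.linspace(0, 1, 5)})
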