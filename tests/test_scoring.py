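import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dentopt.model import Candidate
from dentopt.scoring import DeltaParams, Weights, delta, pattern_score, positional_score
from .conftest import make_candidate, pattern_from

PARAMS = DeltaParams()
K = PARAMS.k


def cand_at(tooth: int, cx: float, conf: float = 0.9) -> Candidate:
    return make_candidate(tooth, cx, conf)


class TestDelta:
    @pytest.mark.parametrize(
        "dist,order,expected",
        [
            (20.0, 1, 0.0),                 # below a
            (38.5, 1, 0.675),               # ascending ramp: k + (1-k)(8.5/17)
            (80.0, 1, 1.0),                 # plateau
            (120.0, 1, 0.75625),            # descending ramp: 1 - (1-k)(6/16)
            (150.0, 1, 0.0),                # beyond d
            (120.0, 2, 1.0),                # far plateau (97 < 120 < 164)
            (60.0, 2, 0.0),                 # below far a = 80
        ],
    )
    def test_analytic_values(self, dist, order, expected):
        v = delta(cand_at(1, 100.0), cand_at(2, 100.0 + dist), order, PARAMS)
        assert v == pytest.approx(expected, abs=1e-12)

    def test_missing_candidate_returns_k(self):
        present = cand_at(1, 100.0)
        missing = Candidate.missing(2)
        assert delta(present, missing, 1, PARAMS) == K
        assert delta(missing, present, 1, PARAMS) == K
        assert delta(missing, Candidate.missing(3), 2, PARAMS) == K

    @pytest.mark.parametrize("order,point,expected", [
        (1, 30.0, K), (1, 47.0, 1.0), (1, 114.0, 1.0), (1, 130.0, K),
        (2, 80.0, K), (2, 97.0, 1.0), (2, 164.0, 1.0), (2, 180.0, K),
    ])
    def test_threshold_boundaries_close_the_trapezoid(self, order, point, expected):
        v = delta(cand_at(1, 0.0), cand_at(2, point), order, PARAMS)
        assert v == pytest.approx(expected, abs=1e-12)

    @given(dist=st.floats(0, 500), order=st.sampled_from([1, 2]))
    @settings(max_examples=200, deadline=None)
    def test_range_and_symmetry(self, dist, order):
        a = cand_at(1, 200.0)
        b = cand_at(3, 200.0 + dist)
        v = delta(a, b, order, PARAMS)
        assert v == delta(b, a, order, PARAMS)
        assert v == 0.0 or K <= v <= 1.0

    def test_scale_factor_rescales_thresholds(self):
        half = DeltaParams(scale=0.5)
        assert delta(cand_at(1, 0.0), cand_at(2, 40.0), 1, half) == 1.0  # 40 in [23.5, 57]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            DeltaParams(near=(50, 47, 114, 130))
        with pytest.raises(ValueError):
            DeltaParams(k=1.2)


class TestPositionalScore:
    def test_all_plateau_neighbors_score_one(self):
        # positions 3..7 spaced 80 px: near |dx|=80 in (47,114), far 160 in (97,164)
        pat = pattern_from({x: cand_at(x, 80.0 * x) for x in range(3, 8)})
        assert positional_score(pat, 5, PARAMS) == 1.0

    def test_all_missing_neighborhood_scores_k(self):
        pat = pattern_from({})
        assert positional_score(pat, 5, PARAMS) == K

    def test_end_position_has_two_neighbors(self):
        # position 1: neighborhood {2, 3}; 2 on plateau, 3 missing
        pat = pattern_from({1: cand_at(1, 100.0), 2: cand_at(2, 180.0)})
        assert positional_score(pat, 1, PARAMS) == pytest.approx((1.0 + K) / 2)

    def test_neighborhood_sizes(self):
        from dentopt.scoring import _omega_indices

        assert len(_omega_indices(1, False)) == 2
        assert len(_omega_indices(2, False)) == 3
        assert len(_omega_indices(5, False)) == 4
        assert len(_omega_indices(32, False)) == 2

    def test_jaw_restriction_truncates_neighborhood(self):
        from dentopt.scoring import _omega_indices

        literal = _omega_indices(16, False)
        restricted = _omega_indices(16, True)
        assert (17, 1) in literal and (18, 2) in literal
        assert restricted == [(14, 2), (15, 1)]


def naive_pattern_score(pattern, weights, params, missing_conf):
    """Independent term-by-term recomputation of the combined objective."""
    total = 0.0
    for x in range(1, 33):
        c = pattern[x]
        mu_c = missing_conf if c.rank == 0 else c.confidence
        ds = []
        for i in (-2, -1, 1, 2):
            y = x + i
            if not 1 <= y <= 32:
                continue
            n = pattern[y]
            if c.rank == 0 or n.rank == 0:
                ds.append(params.k)
                continue
            dist = abs(c.box.center_x - n.box.center_x)
            a, b, cc, d = params.near if abs(i) == 1 else params.far
            if dist < a or dist > d:
                ds.append(0.0)
            elif dist <= b:
                ds.append(params.k + (1 - params.k) * (dist - a) / (b - a))
            elif dist <= cc:
                ds.append(1.0)
            else:
                ds.append(1.0 - (1 - params.k) * (dist - cc) / (d - cc))
        total += weights.omega_c * mu_c + weights.omega_p * sum(ds) / len(ds)
    return total / 32.0


class TestPatternScore:
    def test_perfect_pattern_scores_one(self):
        pat = pattern_from({x: cand_at(x, 80.0 * x, conf=1.0) for x in range(1, 33)})
        for w in (Weights(0.8, 0.2), Weights(0.5, 0.5)):
            assert pattern_score(pat, w, PARAMS, missing_conf=1.0) == pytest.approx(1.0)

    def test_all_missing_pattern_scores_k(self):
        pat = pattern_from({})
        assert pattern_score(pat, Weights(), PARAMS, missing_conf=K) == pytest.approx(K)

    def test_agrees_with_naive_recomputation(self, rng):
        for _ in range(25):
            assignments = {}
            for x in range(1, 33):
                if rng.random() < 0.3:
                    continue
                assignments[x] = cand_at(
                    x, float(rng.uniform(0, 2000)), conf=float(rng.uniform(0, 1))
                )
            pat = pattern_from(assignments)
            w = Weights(0.5, 0.5)
            got = pattern_score(pat, w, PARAMS, missing_conf=0.35)
            want = naive_pattern_score(pat, w, PARAMS, missing_conf=0.35)
            assert got == pytest.approx(want, abs=1e-12)
            assert 0.0 <= got <= 1.0

    def test_three_tooth_toy_pattern_matches_hand_sum(self):
        pat = pattern_from({
            1: cand_at(1, 100.0, conf=0.9),
            2: cand_at(2, 180.0, conf=0.8),
            3: cand_at(3, 260.0, conf=0.6),
        })
        w = Weights(0.8, 0.2)
        expected = naive_pattern_score(pat, w, PARAMS, 0.35)
        assert pattern_score(pat, w, PARAMS, 0.35) == pytest.approx(expected, abs=1e-12)

    @given(conf=st.floats(0.0, 1.0), bump=st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_confidence(self, conf, bump):
        higher = min(1.0, conf + bump)
        base = {x: cand_at(x, 80.0 * x, conf=0.8) for x in range(1, 6)}
        lo = pattern_from({**base, 3: cand_at(3, 240.0, conf=conf)})
        hi = pattern_from({**base, 3: cand_at(3, 240.0, conf=higher)})
        w = Weights(0.8, 0.2)
        assert pattern_score(hi, w, PARAMS) >= pattern_score(lo, w, PARAMS)

    def test_weights_must_be_convex(self):
        with pytest.raises(ValueError):
            Weights(0.8, 0.3)
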