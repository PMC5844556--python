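"""Exact interval-bidding auction: bid construction, the DP solver and its
brute-force cross-validation."""

import math

import numpy as np
import pytest

from cbscaffold.auction import (
    AuctionComplexityError,
    Bid,
    brute_force_auction,
    build_bids,
    estimate_complexity,
    solve_auction_exact,
)


def _bid(bidder, start, length, x_max, score, orientation="forward"):
    return Bid(
        bidder=bidder,
        x_start=start,
        x_end=(start - 1 + length - 1) % x_max + 1,
        length_px=length,
        orientation=orientation,
        score=score,
    )


def _random_instance(rng, max_bidders=8, x_max_range=(20, 61)):
    x_max = int(rng.integers(*x_max_range))
    circular = bool(rng.integers(2))
    bids = []
    for n in range(int(rng.integers(1, max_bidders + 1))):
        length = int(rng.integers(2, max(3, x_max // 2)))
        for _ in range(int(rng.integers(1, 5))):
            hi = x_max if circular else x_max - length + 1
            if hi < 1:
                continue
            s = int(rng.integers(1, hi + 1))
            bids.append(
                _bid(n, s, length, x_max, float(rng.random() * 10 + 0.1),
                     "forward" if rng.integers(2) else "flipped")
            )
    return bids[:24], x_max, circular


class TestBuildBids:
    def test_threshold_is_strict(self):
        pv = np.full(20, 0.5)
        pv[3] = 0.01  # exactly at threshold: no bid
        pv[4] = 0.009
        bids = build_bids([pv], [4], p_thresh=0.01)
        assert len(bids) == 1
        assert bids[0].x_start == 5 and bids[0].orientation == "forward"

    def test_fisher_transform_score(self):
        pv = np.ones(20)
        pv[2] = math.exp(-1.0)
        bids = build_bids([pv], [3], p_thresh=0.5)
        assert bids[0].score == pytest.approx(2.0, abs=1e-12)

    def test_no_significant_positions_gives_empty_list(self):
        assert build_bids([np.full(20, 0.02)], [3], p_thresh=0.01) == []

    def test_flipped_block_and_wrapping_end(self):
        pv = np.ones(20)
        pv[10 + 9] = 1e-4  # flipped orientation, start pixel 10 of 10
        bids = build_bids([pv], [4], p_thresh=0.01)
        (b,) = bids
        assert (b.orientation, b.x_start, b.x_end) == ("flipped", 10, 3)
        assert b.crosses_cut(10)


class TestExactSolver:
    def test_single_bid_is_placed(self):
        sol = solve_auction_exact([_bid(0, 3, 4, 20, 5.0)], 20)
        assert sol.total_score == 5.0 and len(sol.placements) == 1

    def test_bidder_placed_at_most_once(self):
        bids = [_bid(0, 1, 3, 20, 4.0), _bid(0, 10, 3, 20, 6.0)]
        sol = solve_auction_exact(bids, 20)
        assert len(sol.placements) == 1
        assert sol.total_score == 6.0

    def test_overlap_forces_a_choice(self):
        bids = [_bid(0, 1, 5, 20, 4.0), _bid(1, 3, 5, 20, 3.0), _bid(2, 8, 5, 20, 2.0)]
        sol = solve_auction_exact(bids, 20)
        assert sol.total_score == pytest.approx(6.0)
        assert {b.bidder for b in sol.placements} == {0, 2}

    def test_placing_nothing_can_be_optimal_locally(self):
        # one long cheap bid vs two short expensive ones occupying its span
        bids = [_bid(0, 1, 10, 20, 3.0), _bid(1, 1, 4, 20, 5.0), _bid(2, 6, 4, 20, 5.0)]
        sol = solve_auction_exact(bids, 20)
        assert sol.total_score == pytest.approx(10.0)

    def test_wraparound_bid_cases(self):
        # crossing bid is optimal
        bids = [_bid(0, 18, 6, 20, 9.0), _bid(1, 1, 3, 20, 4.0)]
        sol = solve_auction_exact(bids, 20)
        assert sol.total_score == pytest.approx(9.0 + 0.0)  # bid 1 overlaps the wrap
        bids = [_bid(0, 18, 6, 20, 9.0), _bid(1, 5, 3, 20, 4.0)]
        sol = solve_auction_exact(bids, 20)
        assert sol.total_score == pytest.approx(13.0)

    def test_cross_validation_against_brute_force(self):
        """Exactness on 200 seeded random instances, circular and linear."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            bids, x_max, circular = _random_instance(rng)
            a = solve_auction_exact(bids, x_max, circular=circular)
            b = brute_force_auction(bids, x_max, circular=circular)
            assert a.total_score == pytest.approx(b.total_score, abs=1e-9)
            a.validate()

    def test_gap_decomposition(self):
        """Splitting at bid-free pixels and solving parts independently
        gives the same total as solving the whole instance."""
        rng = np.random.default_rng(3)
        left = [_bid(n, int(rng.integers(1, 12)), 4, 60, float(rng.random() + 0.5))
                for n in range(3)]
        right = [_bid(3 + n, int(rng.integers(30, 42)), 4, 60, float(rng.random() + 0.5))
                 for n in range(3)]
        whole = solve_auction_exact(left + right, 60, circular=False)
        part = (
            solve_auction_exact(left, 60, circular=False).total_score
            + solve_auction_exact(right, 60, circular=False).total_score
        )
        assert whole.total_score == pytest.approx(part)

    def test_adding_disjoint_bid_never_decreases_total(self):
        rng = np.random.default_rng(13)
        for _ in range(30):
            bids, x_max, circular = _random_instance(rng, max_bidders=5)
            base = solve_auction_exact(bids, x_max, circular=circular).total_score
            occupied = np.zeros(x_max, dtype=bool)
            for b in bids:
                occupied[b.pixels(x_max) - 1] = True
            free = np.flatnonzero(~occupied) + 1
            if len(free) == 0:
                continue
            extra = _bid(999, int(free[0]), 1, x_max, 0.7)
            grown = solve_auction_exact(bids + [extra], x_max, circular=circular)
            assert grown.total_score >= base - 1e-12

    def test_deterministic_tie_breaking(self):
        bids = [_bid(1, 10, 3, 30, 5.0), _bid(0, 1, 3, 30, 5.0)]
        sol = solve_auction_exact(bids, 30)
        assert [b.bidder for b in sol.placements] == [0, 1]

    def test_entangled_instance_raises_guard_error(self):
        bids = [_bid(n, 1 + n, 10, 40, 1.0 + n) for n in range(6)]
        with pytest.raises(AuctionComplexityError, match="relevant bidders"):
            solve_auction_exact(bids, 40, max_active=3)
        # and succeeds with an adequate bound
        solve_auction_exact(bids, 40, max_active=6)


class TestBruteForce:
    def test_empty_instance(self):
        sol = brute_force_auction([], 30)
        assert sol.total_score == 0.0 and sol.placements == []

    def test_one_bidder_overlapping_self_bids(self):
        bids = [_bid(0, 1, 6, 20, 3.0), _bid(0, 4, 6, 20, 7.0)]
        sol = brute_force_auction(bids, 20)
        assert sol.total_score == 7.0 and len(sol.placements) == 1

    def test_size_guard(self):
        bids = [_bid(n, 1 + 2 * n, 2, 100, 1.0) for n in range(13)]
        with pytest.raises(ValueError, match="too large"):
            brute_force_auction(bids, 100)


class TestComplexityEstimate:
    def test_empty(self):
        assert estimate_complexity([], 50) == (0, 0, 0)

    def test_single_bidder_bound(self):
        bids = [_bid(0, 1, 5, 50, 1.0), _bid(0, 20, 5, 50, 2.0)]
        A, B, C = estimate_complexity(bids, 50)
        assert A == 1 and B == 10 and C <= 1

    def test_two_independent_clusters(self):
        bids = [_bid(n, 1 + n, 4, 60, 1.0) for n in range(3)]
        bids += [_bid(3 + n, 31 + n, 4, 60, 1.0) for n in range(3)]
        A, B, C = estimate_complexity(bids, 60)
        assert A == 6 and C == 3  # clusters do not inflate each other
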