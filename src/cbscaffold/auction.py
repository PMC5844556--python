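"""Exact combinatorial auction for non-overlapping contig placement.

Each contig is a bidder; a bid is an interval of consecutive reference
pixels (the contig at one position and orientation) with a positive score
-2 ln(p). The winner determination problem — maximize the summed score
subject to "each pixel sold at most once" and "each bidder wins at most
one interval" — is solved exactly by dynamic programming over bid end
positions with a bitmask over the currently *relevant* bidders:

* positions carrying no bid are skipped entirely (gap speedup), and
* a bidder's bit is projected out of the state as soon as none of its
  remaining bids can interact with future decisions (relevant-subset
  speedup), so the working mask width tracks the local bid density, not
  the total number of bidders.

Circular references are handled by conditioning on the content of the cut
between pixel x_max and pixel 1: either no placed bid crosses it (one
linear solve) or one specific wrap-around bid does (one linear solve per
crossing bid on the remaining free arc; two wrap-around bids always
overlap at pixel 1, so the cases are exhaustive). Expected cost scales as
A * B^2 * 2^C with A the active bidders, B the bid-carrying span and C the
maximal relevant-subset width.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Bid",
    "PlacementSolution",
    "AuctionComplexityError",
    "build_bids",
    "solve_auction_exact",
    "brute_force_auction",
    "estimate_complexity",
]

log = logging.getLogger(__name__)

_ORIENT_RANK = {"forward": 0, "flipped": 1}


class AuctionComplexityError(RuntimeError):
    """Raised when the relevant-bidder working set exceeds the bitmask
    guard; raise the bound C or thin the instance rather than accept a
    heuristic answer."""


@dataclass(frozen=True)
class Bid:
    """One contig at one position/orientation bidding for a pixel interval.

    Pixels are 1-based on the reference; the interval is the ``length_px``
    pixels ending at ``x_end`` (wrapping through pixel 1 when
    x_start > x_end).
    """

    bidder: int
    x_start: int
    x_end: int
    length_px: int
    orientation: str
    score: float

    def __post_init__(self):
        if self.score <= 0:
            raise ValueError("bid scores must be positive")
        if self.length_px < 1:
            raise ValueError("bid interval must cover at least one pixel")
        if self.orientation not in _ORIENT_RANK:
            raise ValueError(f"unknown orientation {self.orientation!r}")

    def sort_key(self):
        return (self.bidder, self.x_end, _ORIENT_RANK[self.orientation])

    def pixels(self, x_max: int) -> np.ndarray:
        return (self.x_start - 1 + np.arange(self.length_px)) % x_max + 1

    def crosses_cut(self, x_max: int) -> bool:
        return self.x_start + self.length_px - 1 > x_max


@dataclass
class PlacementSolution:
    """A feasible assignment of bidders to intervals with its total score."""

    placements: list[Bid]
    total_score: float
    x_max: int
    max_states: int = 1

    @property
    def occupied(self) -> np.ndarray:
        occ = np.zeros(self.x_max, dtype=bool)
        for b in self.placements:
            occ[b.pixels(self.x_max) - 1] = True
        return occ

    def validate(self) -> None:
        counts = np.zeros(self.x_max, dtype=int)
        bidders = [b.bidder for b in self.placements]
        if len(bidders) != len(set(bidders)):
            raise AssertionError("a bidder was placed more than once")
        for b in self.placements:
            counts[b.pixels(self.x_max) - 1] += 1
        if (counts > 1).any():
            raise AssertionError("overlapping placements")
        total = sum(b.score for b in self.placements)
        if abs(total - self.total_score) > 1e-9 * max(1.0, abs(total)):
            raise AssertionError("total_score inconsistent with placements")


def build_bids(pvalue_tables, lengths_px, p_thresh: float = 0.01) -> list[Bid]:
    """Positive placement scores b = -2 ln(p) for every (contig, position,
    orientation) with p strictly below p_thresh.

    ``pvalue_tables`` is a sequence of PValueTable (or bare p-vectors of
    length 2*x_max) indexed like ``lengths_px``. Positions with
    p >= p_thresh produce no bid at all.
    """
    if not 0 < p_thresh < 1:
        raise ValueError("p_thresh must lie in (0, 1)")
    bids: list[Bid] = []
    for n, (tab, m) in enumerate(zip(pvalue_tables, lengths_px)):
        pv = np.asarray(getattr(tab, "pvals", tab), dtype=float)
        logp = getattr(tab, "log_pvals", None)
        if logp is None:
            logp = np.log(np.maximum(pv, 1e-300))
        x_max = len(pv) // 2
        if m > x_max:
            raise ValueError("contig longer than the reference")
        for idx in np.flatnonzero(pv < p_thresh):
            x_start = int(idx % x_max) + 1
            bids.append(
                Bid(
                    bidder=n,
                    x_start=x_start,
                    x_end=(x_start - 1 + m - 1) % x_max + 1,
                    length_px=int(m),
                    orientation="forward" if idx < x_max else "flipped",
                    score=float(-2.0 * logp[idx]),
                )
            )
    return bids


# DP / solution states are (score, placement_key, placements); ties on the
# score go to the lexicographically smallest placement key, which makes
# every solver deterministic and mutually consistent.

def _better(a, b) -> bool:
    if b is None:
        return True
    if a[0] != b[0]:
        return a[0] > b[0]
    return a[1] < b[1]


def _state_with(state, bid: Bid):
    sc, key, pl = state
    return (
        sc + bid.score,
        tuple(sorted(key + (bid.sort_key(),))),
        pl + (bid,),
    )


def _solve_linear(bids: list[Bid], n_px: int, max_active: int):
    """Exact DP on a linear pixel range 1..n_px (bids must not wrap).

    Returns (score, placements, max_states).
    """
    if not bids:
        return 0.0, (), 1
    bidders = sorted({b.bidder for b in bids})
    bit = {n: 1 << i for i, n in enumerate(bidders)}
    first_start = {n: n_px + 1 for n in bidders}
    last_end = {n: 0 for n in bidders}
    for b in bids:
        first_start[b.bidder] = min(first_start[b.bidder], b.x_start)
        last_end[b.bidder] = max(last_end[b.bidder], b.x_end)

    by_end: dict[int, list[Bid]] = {}
    for b in sorted(bids, key=Bid.sort_key):
        by_end.setdefault(b.x_end, []).append(b)
    ends = sorted(by_end)

    empty = {0: (0.0, (), ())}
    snap_px = [0]
    snap_dicts = [empty]
    max_states = 1

    def snapshot_at(t: int) -> dict:
        return snap_dicts[bisect_right(snap_px, t) - 1]

    prev = empty
    for e in ends:
        active = [n for n in bidders if first_start[n] <= e <= last_end[n]]
        if len(active) > max_active:
            raise AuctionComplexityError(
                f"{len(active)} relevant bidders at pixel {e} exceed the "
                f"guard C = {max_active}; raise max_active to attempt the solve"
            )
        amask = 0
        for n in active:
            amask |= bit[n]
        cur: dict[int, tuple] = {}
        for mask, st in prev.items():
            pm = mask & amask
            if _better(st, cur.get(pm)):
                cur[pm] = st
        for b in by_end[e]:
            pred = snapshot_at(b.x_start - 1)
            bbit = bit[b.bidder]
            for mask, st in pred.items():
                if mask & bbit:
                    continue
                nst = _state_with(st, b)
                nm = (mask | bbit) & amask
                if _better(nst, cur.get(nm)):
                    cur[nm] = nst
        max_states = max(max_states, len(cur))
        snap_px.append(e)
        snap_dicts.append(cur)
        prev = cur

    best = None
    for st in prev.values():
        if _better(st, best):
            best = st
    return best[0], best[2], max_states


def _shift_bid(b: Bid, offset: int) -> Bid:
    return Bid(
        bidder=b.bidder,
        x_start=b.x_start - offset,
        x_end=b.x_end - offset,
        length_px=b.length_px,
        orientation=b.orientation,
        score=b.score,
    )


def solve_auction_exact(
    bids: list[Bid], x_max: int, circular: bool = True, max_active: int = 25
) -> PlacementSolution:
    """Global maximizer of the summed placement score under the non-overlap
    and at-most-one-interval-per-bidder constraints (exact)."""
    for b in bids:
        if b.length_px > x_max:
            raise ValueError("bid interval longer than the reference")
        if not (1 <= b.x_end <= x_max and 1 <= b.x_start <= x_max):
            raise ValueError("bid pixel out of range")
        if not circular and b.crosses_cut(x_max):
            raise ValueError("wrap-around bid on a linear reference")
    if not circular:
        sc, pl, ms = _solve_linear(bids, x_max, max_active)
        sol = PlacementSolution(sorted(pl, key=Bid.sort_key), sc, x_max, ms)
        sol.validate()
        return sol

    crossing = [b for b in bids if b.crosses_cut(x_max)]
    inside = [b for b in bids if not b.crosses_cut(x_max)]

    sc, pl, ms = _solve_linear(inside, x_max, max_active)
    best = (sc, tuple(sorted(p.sort_key() for p in pl)), pl, ms)
    for cb in sorted(crossing, key=Bid.sort_key):
        wrap_end = cb.x_start + cb.length_px - 1 - x_max  # last covered pixel
        free_lo, free_hi = wrap_end + 1, cb.x_start - 1  # inclusive free arc
        sub = [
            _shift_bid(b, wrap_end)
            for b in inside
            if b.bidder != cb.bidder
            and free_lo <= b.x_start
            and b.x_end <= free_hi
        ]
        sc, pl, ms = _solve_linear(sub, max(free_hi - free_lo + 1, 0), max_active)
        placements = tuple(_shift_bid(b, -wrap_end) for b in pl) + (cb,)
        cand = (
            sc + cb.score,
            tuple(sorted(p.sort_key() for p in placements)),
            placements,
            ms,
        )
        if _better(cand, best):
            best = cand
    sol = PlacementSolution(
        sorted(best[2], key=Bid.sort_key), best[0], x_max, max(best[3], 1)
    )
    sol.validate()
    return sol


def brute_force_auction(
    bids: list[Bid], x_max: int, circular: bool = True
) -> PlacementSolution:
    """Exhaustive branch-and-bound optimum; test oracle for small
    instances only."""
    bidders = {b.bidder for b in bids}
    if len(bidders) > 12 or len(bids) > 26 or x_max > 120:
        raise ValueError("instance too large for the brute-force oracle")
    for b in bids:
        if not circular and b.crosses_cut(x_max):
            raise ValueError("wrap-around bid on a linear reference")
    order = sorted(bids, key=lambda b: (-b.score,) + b.sort_key())
    masks = []
    for b in order:
        m = 0
        for px in b.pixels(x_max):
            m |= 1 << (int(px) - 1)
        masks.append(m)
    scores = [b.score for b in order]
    suffix = [0.0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix[i] = suffix[i + 1] + scores[i]
    best = [(0.0, (), ())]

    def dfs(i, occ, used, state):
        if _better(state, best[0]):
            best[0] = state
        if i == len(order) or state[0] + suffix[i] < best[0][0] - 1e-12:
            return
        b, m = order[i], masks[i]
        if not occ & m and b.bidder not in used:
            dfs(i + 1, occ | m, used | {b.bidder}, _state_with(state, b))
        dfs(i + 1, occ, used, state)

    dfs(0, 0, frozenset(), (0.0, (), ()))
    sol = PlacementSolution(
        sorted(best[0][2], key=Bid.sort_key), best[0][0], x_max
    )
    sol.validate()
    return sol


def estimate_complexity(bids: list[Bid], x_max: int):
    """Effective instance-size parameters (A, B, C) of the scaling
    A * B^2 * 2^C: active bidders, bid-carrying pixels, and the maximal
    concurrent relevant-bidder count."""
    if not bids:
        return 0, 0, 0
    A = len({b.bidder for b in bids})
    covered = np.zeros(x_max, dtype=bool)
    bidder_pixels: dict[int, np.ndarray] = {}
    for b in bids:
        px = b.pixels(x_max)
        covered[px - 1] = True
        mask = bidder_pixels.setdefault(b.bidder, np.zeros(x_max, dtype=bool))
        mask[px - 1] = True
    B = int(covered.sum())
    concurrent = np.zeros(x_max, dtype=int)
    for mask in bidder_pixels.values():
        concurrent[_covering_arc(mask)] += 1
    return A, B, int(concurrent.max())


def _covering_arc(mask: np.ndarray) -> np.ndarray:
    """Smallest circular arc containing all true pixels (the bidder's
    relevance window): the complement of the largest empty gap."""
    L = len(mask)
    idx = np.flatnonzero(mask)
    if len(idx) == L:
        return np.ones(L, dtype=bool)
    ext = np.concatenate([idx, [idx[0] + L]])
    d = np.diff(ext)
    k = int(np.argmax(d))
    arc = np.zeros(L, dtype=bool)
    start, stop = int(ext[k + 1]), int(ext[k]) + L
    for t in range(start, stop + 1):
        arc[t % L] = True
    return arc
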