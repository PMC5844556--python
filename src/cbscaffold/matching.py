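"""Sliding Pearson match scores of contig barcodes against a circular
reference barcode.

The reference is ``x_max`` pixels long and circular; a contig barcode of m
pixels is compared with every wrap-around reference window of m pixels, in
both orientations, giving ``2 * x_max`` scores ``C[n, x]``: entries
``0..x_max-1`` are forward starts, entries ``x_max..2*x_max-1`` the same
starts with the contig reversed. Scores are computed at integer pixel
offsets only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cbtheory import Barcode

__all__ = ["MatchTable", "BestMatch", "ReferenceMatcher", "sliding_pearson", "best_match"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchTable:
    """All 2*x_max Pearson scores of one contig against the reference."""

    contig_id: str
    scores: np.ndarray
    contig_len_px: int

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size % 2:
            raise ValueError("scores must be a 1-D vector of length 2*x_max")
        if (np.abs(s) > 1 + 1e-9).any():
            raise ValueError("Pearson scores must lie in [-1, 1]")
        object.__setattr__(self, "scores", np.clip(s, -1.0, 1.0))

    @property
    def x_max(self) -> int:
        return len(self.scores) // 2

    def to_frame(self) -> pd.DataFrame:
        x_max = self.x_max
        return pd.DataFrame(
            {
                "contig_id": self.contig_id,
                "x": np.tile(np.arange(1, x_max + 1), 2),
                "orientation": ["forward"] * x_max + ["flipped"] * x_max,
                "score": self.scores,
            }
        )


@dataclass(frozen=True)
class BestMatch:
    """Maximum score of a contig with its position and orientation."""

    contig_id: str
    c_hat: float
    x_star: int  # 1-based start pixel on the reference
    orientation: str  # 'forward' | 'flipped'


class ReferenceMatcher:
    """Precomputed circular-window machinery for one reference barcode.

    Window means/sds are cached per contig pixel length so that matching
    thousands of equal-length random barcodes reduces to one BLAS matrix
    product per orientation.
    """

    def __init__(self, reference: Barcode):
        if not reference.circular:
            raise ValueError("the reference barcode must be circular")
        self.reference = reference
        self.x_max = reference.n_px
        self._ref = np.asarray(reference.values, dtype=float)
        self._window_cache: dict[int, tuple] = {}

    def _windows(self, m: int):
        """(window matrix view, per-window mean, per-window sd) for length m."""
        if m in self._window_cache:
            return self._window_cache[m]
        if m > self.x_max:
            raise ValueError(
                f"contig of {m} px exceeds the {self.x_max}-px reference"
            )
        padded = np.concatenate([self._ref, self._ref[: m - 1]]) if m > 1 else self._ref
        W = np.lib.stride_tricks.sliding_window_view(padded, m)  # (x_max, m)
        mu = W.mean(axis=1)
        sd = W.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            log.warning(
                "%d zero-variance reference windows at length %d px score 0",
                int(degenerate.sum()), m,
            )
        self._window_cache[m] = (np.ascontiguousarray(W), mu, sd, degenerate)
        return self._window_cache[m]

    def match_many(self, contigs: np.ndarray) -> np.ndarray:
        """Scores for a batch of equal-length contig barcodes.

        ``contigs`` is (R, m); returns (R, 2*x_max) with the forward block
        first. Zero-variance contigs or windows score 0.
        """
        C = np.atleast_2d(np.asarray(contigs, dtype=float))
        R, m = C.shape
        W, mu_w, sd_w, degenerate = self._windows(m)
        mu_c = C.mean(axis=1)
        sd_c = C.std(axis=1)
        bad_c = sd_c == 0
        if bad_c.any():
            log.warning("%d zero-variance contig barcodes score 0", int(bad_c.sum()))
        denom = np.outer(np.where(sd_w == 0, np.inf, sd_w),
                         np.where(bad_c, np.inf, sd_c))
        out = np.empty((R, 2 * self.x_max))
        for block, cv in ((0, C), (1, C[:, ::-1])):
            cross = W @ cv.T / m  # (x_max, R)
            scores = (cross - np.outer(mu_w, mu_c)) / denom
            out[:, block * self.x_max : (block + 1) * self.x_max] = scores.T
        np.clip(out, -1.0, 1.0, out=out)
        return out

    def match(self, values: np.ndarray) -> np.ndarray:
        return self.match_many(np.asarray(values)[None, :])[0]

    def max_scores(self, contigs: np.ndarray) -> np.ndarray:
        """Maximum score over all positions and orientations per contig row."""
        return self.match_many(contigs).max(axis=1)


def sliding_pearson(contig: Barcode, reference: Barcode, contig_id: str = "contig",
                    matcher: ReferenceMatcher | None = None) -> MatchTable:
    """Pearson correlation of a contig barcode with every circular window of
    the reference, both orientations."""
    if matcher is None:
        matcher = ReferenceMatcher(reference)
    if contig.bp_per_px != matcher.reference.bp_per_px:
        raise ValueError("contig and reference barcodes must share bp_per_px")
    scores = matcher.match(contig.values)
    return MatchTable(contig_id=contig_id, scores=scores, contig_len_px=contig.n_px)


def best_match(table: MatchTable) -> BestMatch:
    """Global maximum of a match table; ties break to the smallest start
    pixel, forward before flipped."""
    x_max = table.x_max
    best = table.scores.max()
    candidates = np.flatnonzero(table.scores == best)
    idx = int(min(candidates, key=lambda i: (i % x_max, i // x_max)))
    return BestMatch(
        contig_id=table.contig_id,
        c_hat=float(best),
        x_star=idx % x_max + 1,
        orientation="forward" if idx < x_max else "flipped",
    )
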