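"""Scoring helpers: match detections against ground truth.

Used by the test-suite and the reproduction script to turn pipeline output
and simulator ground truth into precision/recall/F1 numbers.  Matching is
greedy one-to-one: centroids within a pixel tolerance for cells, frame
indices within a frame tolerance for spikes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MatchScore", "match_centroids", "match_events"]


@dataclass(frozen=True)
class MatchScore:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else 1.0

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else 1.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _greedy_match(cost: np.ndarray, max_cost: float) -> int:
    """Count one-to-one pairs with cost <= max_cost, greedily by ascending cost."""
    if cost.size == 0:
        return 0
    pairs = np.dstack(np.unravel_index(np.argsort(cost, axis=None), cost.shape))[0]
    used_r: set[int] = set()
    used_c: set[int] = set()
    n = 0
    for r, c in pairs:
        if cost[r, c] > max_cost:
            break
        if r in used_r or c in used_c:
            continue
        used_r.add(int(r))
        used_c.add(int(c))
        n += 1
    return n


def match_centroids(
    true_centroids: np.ndarray, detected_centroids: np.ndarray, tol: float = 3.0
) -> MatchScore:
    """Match 2-D centroids within Euclidean distance ``tol`` pixels."""
    t = np.atleast_2d(np.asarray(true_centroids, dtype=float))
    d = np.atleast_2d(np.asarray(detected_centroids, dtype=float))
    if t.size == 0 or d.size == 0:
        return MatchScore(t.shape[0] if t.size else 0, d.shape[0] if d.size else 0, 0)
    cost = np.linalg.norm(t[:, None, :] - d[None, :, :], axis=2)
    return MatchScore(t.shape[0], d.shape[0], _greedy_match(cost, tol))


def match_events(
    true_frames: np.ndarray, detected_frames: np.ndarray, tol: int = 2
) -> MatchScore:
    """Match event frame indices within ``tol`` frames."""
    t = np.asarray(true_frames, dtype=float).ravel()
    d = np.asarray(detected_frames, dtype=float).ravel()
    if t.size == 0 or d.size == 0:
        return MatchScore(t.size, d.size, 0)
    cost = np.abs(t[:, None] - d[None, :])
    return MatchScore(t.size, d.size, _greedy_match(cost, float(tol)))
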