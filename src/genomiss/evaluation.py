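"""Missingness signals and dynamic time warping (DTW) comparison.

The per-site proportion of missing samples along a segment is treated as a
1-D signal.  Signals from an empirical segment (N sites) and a masked
replicate (M < N sites) have different lengths, so they are compared with
classic unnormalized DTW: the minimum, over all monotone warping paths from
(1, 1) to (len(a), len(b)), of the summed pointwise distances |a_i - b_k|.
A lower distance means the replicate's missingness tracks the empirical
signal more closely.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core import GenotypeMatrix
from .missingness import apply_beta, apply_profile, fit_beta, fit_profile


def extract_signal(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-site proportion of missing samples, in genomic order."""
    if matrix.n_sites == 0:
        raise ValueError("cannot extract a signal from an empty matrix")
    return matrix.missing_mask().mean(axis=1)


def average_signals(signals: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of equal-length signals (e.g. across seeded runs)."""
    if not signals:
        raise ValueError("no signals to average")
    lengths = {len(s) for s in signals}
    if len(lengths) != 1:
        raise ValueError(f"signals have differing lengths: {sorted(lengths)}")
    return np.mean(np.stack([np.asarray(s, dtype=float) for s in signals]), axis=0)


@njit(cache=False)
def _dtw_dp(a, b):  # pragma: no cover - exercised via dtw_distance
    n, m = a.shape[0], b.shape[0]
    prev = np.full(m + 1, np.inf)
    curr = np.full(m + 1, np.inf)
    prev[0] = 0.0
    for i in range(1, n + 1):
        curr[0] = np.inf
        for k in range(1, m + 1):
            best = prev[k]
            if prev[k - 1] < best:
                best = prev[k - 1]
            if curr[k - 1] < best:
                best = curr[k - 1]
            curr[k] = abs(a[i - 1] - b[k - 1]) + best
        prev, curr = curr, prev
    return prev[m]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic DTW distance between two nonempty 1-D signals.

    Cumulative cost D(i,k) = |a_i - b_k| + min(D(i-1,k), D(i,k-1),
    D(i-1,k-1)) with D(0,0) = 0; the path runs from (1,1) to
    (len(a), len(b)).  No window constraint, no path-length normalization.
    """
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires nonempty signals")
    return float(_dtw_dp(a, b))


def benchmark_masking(
    empirical: GenotypeMatrix,
    replicate: GenotypeMatrix,
    n_runs: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Compare profile-based and beta-based masking against an empirical segment.

    The replicate is masked ``n_runs`` times with each method; the per-site
    missing-sample signals are averaged across runs; each averaged signal is
    compared to the empirical per-site signal with DTW.  Returns
    ``(dtw_profile, dtw_beta)`` — the profile method should score lower
    (closer) whenever the empirical missingness has spatial structure.
    """
    profile = fit_profile(empirical, replicate.n_sites)
    params = fit_beta(empirical)
    empirical_signal = extract_signal(empirical)
    profile_signals = [
        extract_signal(apply_profile(replicate, profile, rng))
        for _ in range(n_runs)
    ]
    beta_signals = [
        extract_signal(apply_beta(replicate, params, rng))
        for _ in range(n_runs)
    ]
    return (
        dtw_distance(empirical_signal, average_signals(profile_signals)),
        dtw_distance(empirical_signal, average_signals(beta_signals)),
    )


def dtw_alignment(a: np.ndarray, b: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """DTW distance plus one optimal warping path (0-based index pairs).

    Uses the full cumulative-cost matrix, so it is intended for moderate
    signal lengths (the distance alone uses a two-row recurrence).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW requires nonempty signals")
    n, m = len(a), len(b)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        cost = np.abs(a[i - 1] - b)
        for k in range(1, m + 1):
            D[i, k] = cost[k - 1] + min(D[i - 1, k], D[i, k - 1], D[i - 1, k - 1])
    path = []
    i, k = n, m
    while i >= 1 and k >= 1:
        path.append((i - 1, k - 1))
        moves = ((D[i - 1, k - 1], i - 1, k - 1), (D[i - 1, k], i - 1, k),
                 (D[i, k - 1], i, k - 1))
        _, i, k = min(moves)
    path.reverse()
    return float(D[n, m]), path
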