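"""Independent brute-force oracles used to cross-check the pipeline.

These reimplement the threshold chain and the rank tests from first
principles with plain scans and full enumeration, sharing no code with the
package under test.
"""

from __future__ import annotations

import itertools
from typing import Tuple

import numpy as np


# ---------------------------------------------------------------------------
# Threshold-chain oracle


def _runs(s: np.ndarray):
    """Maximal runs of equal values: list of (start, end, value)."""
    runs = []
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and s[j + 1] == s[i]:
            j += 1
        runs.append((i, j, s[i]))
        i = j + 1
    return runs


def _all_local_maxima(s: np.ndarray):
    """Every local maximum (first bin of its plateau), by exhaustive run scan."""
    runs = _runs(s)
    if len(runs) == 1:
        return []
    out = []
    for idx, (a, b, v) in enumerate(runs):
        left_ok = a == 0 or runs[idx - 1][2] < v
        right_ok = b == len(s) - 1 or runs[idx + 1][2] < v
        if left_ok and right_ok:
            out.append(a)
    return out


def _prominence_scan(s: np.ndarray, i: int) -> float:
    """Prominence by explicit outward scans to the nearest higher terrain.

    Sides that do not exist (boundary peaks) contribute no base.
    """
    n = len(s)
    bases = []
    li = i - 1
    while li >= 0 and s[li] <= s[i]:
        li -= 1
    if li + 1 <= i - 1:
        bases.append(float(np.min(s[li + 1 : i])))
    ri = i + 1
    while ri < n and s[ri] <= s[i]:
        ri += 1
    if i + 1 <= ri - 1:
        bases.append(float(np.min(s[i + 1 : ri])))
    if not bases:
        return 0.0
    return float(s[i]) - max(bases)


def _central_diff_loop(s: np.ndarray) -> np.ndarray:
    """Central differences written out bin by bin (one-sided at the ends)."""
    n = len(s)
    d = np.empty(n)
    for j in range(n):
        if j == 0:
            d[j] = s[1] - s[0]
        elif j == n - 1:
            d[j] = s[-1] - s[-2]
        else:
            d[j] = (s[j + 1] - s[j - 1]) / 2.0
    return d


def oracle_threshold(
    bin_edges: np.ndarray, smoothed: np.ndarray, prominence_frac: float = 0.05
) -> Tuple[int, int, float]:
    """Brute-force (first peak, sharpest-decline bin, tangent threshold).

    Enumerates every local maximum and every right-slope derivative bin
    directly; raises ValueError on degenerate histograms, mirroring the
    library's error contract.
    """
    s = np.asarray(smoothed, dtype=float)
    n = len(s)
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    width = float(bin_edges[1] - bin_edges[0])
    floor = prominence_frac * float(np.max(s))

    peak = None
    for i in _all_local_maxima(s):
        if _prominence_scan(s, i) >= floor:
            peak = i
            break
    if peak is None:
        raise ValueError("oracle: no qualifying peak")
    if peak >= n - 1:
        raise ValueError("oracle: peak leaves no right slope")

    # first substantial minimum right of the peak: local max of -s with
    # prominence >= the same floor
    stop = n - 1
    for j in _all_local_maxima(-s):
        if j > peak and _prominence_scan(-s, j) >= floor:
            stop = j
            break

    d = _central_diff_loop(s)
    decline, best = None, np.inf
    for j in range(peak + 1, stop + 1):
        if d[j] < best:  # strict: ties stay with the smaller j
            best, decline = d[j], j
    if decline is None or d[decline] >= 0:
        raise ValueError("oracle: no declining slope")

    slope = d[decline] / width
    threshold = float(centers[decline]) - float(s[decline]) / slope
    return peak, decline, threshold


def random_mixture_values(rng: np.random.Generator, n: int = 20000) -> np.ndarray:
    """Samples from a random 1-3 component Gaussian mixture, clipped at 0."""
    k = int(rng.integers(1, 4))
    means = np.sort(rng.uniform(50.0, 400.0, size=k))
    sigmas = rng.uniform(5.0, 40.0, size=k)
    weights = rng.dirichlet(np.ones(k))
    comps = rng.choice(k, size=n, p=weights)
    vals = rng.normal(means[comps], sigmas[comps])
    return np.clip(vals, 0.0, None)


# ---------------------------------------------------------------------------
# Rank-test oracles


def mann_whitney_enumeration(x, y) -> Tuple[float, float]:
    """Exact two-tailed Mann-Whitney by enumerating group-1 position subsets."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = np.asarray(x + y)
    n1 = len(x)
    # midranks
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    sv = pooled[order]
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    n2 = len(y)
    stat_obs = min(u_obs, n1 * n2 - u_obs)
    hits = total = 0
    for pos in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(pos)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if min(u, n1 * n2 - u) <= stat_obs + 1e-9:
            hits += 1
    return u_obs, hits / total


def spearman_hand_formula(x, y) -> float:
    """1 - 6*sum(d^2)/(n(n^2-1)) on midranks (exact only without ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def midranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        sv = v[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    d = midranks(x) - midranks(y)
    n = len(x)
    return 1.0 - 6.0 * float(np.sum(d**2)) / (n * (n**2 - 1))
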