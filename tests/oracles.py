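"""Independent brute-force reference implementations used only by the tests.

These re-derive the plateau rule and the moving median from their
definitions with plain Python loops, deliberately sharing no code with the
package, so they can serve as oracles for the vectorized implementations.
"""

from __future__ import annotations

import statistics

import numpy as np


def brute_moving_median(diffs, window):
    """Edge-truncated centered moving median, one loop per element."""
    half = window // 2
    out = []
    for i in range(len(diffs)):
        lo = max(0, i - half)
        hi = min(len(diffs), i + half + 1)
        out.append(statistics.median(diffs[lo:hi]))
    return out


def brute_plateau(values, window, k, min_run):
    """Exhaustive search over every contiguous run of difference indices.

    Returns 1-based value indices (a, b) of the best qualifying run under
    the rule: smoothed diff <= k * median(diffs) for every member; longest
    run wins; ties broken by smaller raw-difference sum, then leftmost.
    Returns None if the best run spans fewer than min_run values.
    """
    s = sorted(values)
    diffs = [s[i + 1] - s[i] for i in range(len(s) - 1)]
    smoothed = brute_moving_median(diffs, window)
    tau = k * statistics.median(diffs)
    best = None  # (length, run_sum, start)
    n_d = len(diffs)
    for i in range(n_d):
        for j in range(i, n_d):
            if all(smoothed[t] <= tau for t in range(i, j + 1)):
                length = j - i + 1
                run_sum = sum(diffs[i : j + 1])
                key = (-length, run_sum, i)
                if best is None or key < best[0]:
                    best = (key, i, j)
    if best is None:
        return None
    _, i, j = best
    if (j - i + 2) < min_run:
        return None
    return (i + 1, j + 2)


def brute_slice_stats(values, a, b):
    """Descriptive statistics of sorted(values)[a-1:b] from first principles."""
    seg = sorted(values)[a - 1 : b]
    n = len(seg)
    mean = sum(seg) / n
    var = sum((x - mean) ** 2 for x in seg) / (n - 1)
    return {
        "n_plateau": n,
        "mean": mean,
        "sd": var ** 0.5,
        "min": seg[0],
        "max": seg[-1],
    }


def brute_welch(a, b):
    """Welch's t statistic and Welch-Satterthwaite df by direct formula."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return t, df
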