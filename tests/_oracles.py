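"""Independent reference implementations used only by the tests.

Everything here is deliberately written with plain Python loops (no
vectorized histogram/convolution calls) so that agreement with the package
is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from stressid.rbf import Gradients, RBFNetwork, total_error


# ---------------------------------------------------------------------------
# histogram / split oracles
# ---------------------------------------------------------------------------

def oracle_bin_counts(vals, edges):
    """Count samples per bin by linear scan; last bin right-closed."""
    B = len(edges) - 1
    counts = [0] * B
    for v in vals:
        for b in range(B):
            last = b == B - 1
            if v >= edges[b] and (v <= edges[b + 1] if last else v < edges[b + 1]):
                counts[b] += 1
                break
    return counts


def oracle_smooth(counts, window):
    """Moving average with edge clamping, computed index by index."""
    counts = [float(c) for c in counts]
    if window <= 1 or len(counts) < 3:
        return counts
    pad = window // 2
    out = []
    for b in range(len(counts)):
        acc = 0.0
        for j in range(b - pad, b + pad + 1):
            acc += counts[min(max(j, 0), len(counts) - 1)]
        out.append(acc / window)
    return out


def oracle_find_split(
    X,
    bins=16,
    min_cluster_size=2,
    smoothing_window=3,
    valley_z=2.0,
):
    """Exhaustive enumeration of every (dim, bin) candidate.

    Returns ``(dim, bin_index, threshold)`` of the winning candidate or
    ``None``, applying the documented rules: interior smoothed local
    minimum, below the parent's mean per-bin count, significantly below the
    flanking peaks, median-of-bin threshold, minimum subclass sizes, and a
    peak above the parent mean on each side; deepest valley wins, ties
    toward the lowest dim then lowest bin.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2 * min_cluster_size:
        return None
    mean_parent = n / bins
    best_key, best = None, None
    for dim in range(1, d + 1):
        vals = [float(v) for v in X[:, dim - 1]]
        lo, hi = min(vals), max(vals)
        if lo == hi:
            continue
        edges = np.linspace(lo, hi, bins + 1)
        counts = oracle_bin_counts(vals, edges)
        smoothed = oracle_smooth(counts, smoothing_window)
        for b in range(1, bins - 1):
            is_valley = (
                smoothed[b] <= smoothed[b - 1]
                and smoothed[b] <= smoothed[b + 1]
                and (smoothed[b] < smoothed[b - 1] or smoothed[b] < smoothed[b + 1])
            )
            if not is_valley:
                continue
            peak_l = max(smoothed[:b])
            peak_r = max(smoothed[b + 1:])
            peak_min = min(peak_l, peak_r)
            if smoothed[b] >= mean_parent:
                continue
            if peak_min - smoothed[b] <= valley_z * math.sqrt(peak_min):
                continue
            in_bin = [
                v
                for v in vals
                if v >= edges[b]
                and (v <= edges[b + 1] if b == bins - 2 else v < edges[b + 1])
            ]
            if in_bin:
                ordered = sorted(in_bin)
                m = len(ordered)
                h = (
                    ordered[m // 2]
                    if m % 2
                    else 0.5 * (ordered[m // 2 - 1] + ordered[m // 2])
                )
            else:
                h = 0.5 * (edges[b] + edges[b + 1])
            left = [v for v in vals if v <= h]
            right = [v for v in vals if v > h]
            if len(left) < min_cluster_size or len(right) < min_cluster_size:
                continue
            if max(oracle_bin_counts(left, edges)) <= mean_parent:
                continue
            if max(oracle_bin_counts(right, edges)) <= mean_parent:
                continue
            key = (peak_min - smoothed[b], -dim, -b)
            if best_key is None or key > best_key:
                best_key, best = key, (dim, b, float(h))
    return best


# ---------------------------------------------------------------------------
# gradient oracle
# ---------------------------------------------------------------------------

def finite_difference_gradients(
    net: RBFNetwork, X, targets, step: float = 1e-6
) -> Gradients:
    """Central finite differences of the batch objective, parameter by
    parameter."""
    k, d = net.k, net.d

    def xi(weights, centers, widths):
        probe = replace(
            net,
            weights=np.asarray(weights, dtype=float),
            centers=np.asarray(centers, dtype=float),
            widths=np.asarray(widths, dtype=float),
        )
        return total_error(probe, X, targets)

    g_w = np.zeros(k)
    for j in range(k):
        up, down = net.weights.copy(), net.weights.copy()
        up[j] += step
        down[j] -= step
        g_w[j] = (xi(up, net.centers, net.widths) - xi(down, net.centers, net.widths)) / (
            2 * step
        )
    g_c = np.zeros((k, d))
    for j in range(k):
        for a in range(d):
            up, down = net.centers.copy(), net.centers.copy()
            up[j, a] += step
            down[j, a] -= step
            g_c[j, a] = (
                xi(net.weights, up, net.widths) - xi(net.weights, down, net.widths)
            ) / (2 * step)
    g_s = np.zeros(k)
    for j in range(k):
        up, down = net.widths.copy(), net.widths.copy()
        up[j] += step
        down[j] -= step
        g_s[j] = (
            xi(net.weights, net.centers, up) - xi(net.weights, net.centers, down)
        ) / (2 * step)
    return Gradients(weights=g_w, centers=g_c, widths=g_s)


def assert_gradients_close(analytic: Gradients, numeric: Gradients, rtol=1e-5):
    for name in ("weights", "centers", "widths"):
        a = np.asarray(getattr(analytic, name)).ravel()
        f = np.asarray(getattr(numeric, name)).ravel()
        # scale-floored relative error: finite differences carry ~1e-9 of
        # absolute noise, so components near zero are compared against 1
        denom = np.maximum(np.abs(f), 1.0)
        rel = np.abs(a - f) / denom
        assert rel.max() < rtol, f"{name}: max relative error {rel.max():.2e}"


def random_small_network(rng, k=3, d=2) -> RBFNetwork:
    return RBFNetwork(
        centers=rng.normal(0, 1, size=(k, d)),
        widths=rng.uniform(0.6, 2.0, size=k),
        weights=rng.normal(0, 1, size=k),
    )
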