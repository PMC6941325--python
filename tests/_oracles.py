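"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the
Mann-Whitney oracle enumerates all rank assignments, the mapping oracle
scores every (motif, matrix) pair by a direct per-position product, and the
log-rank oracle permutes stratum labels exhaustively.
"""

import itertools
import math

import numpy as np


def mwu_exhaustive(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all C(n, n_x) rank
    assignments of the pooled sample (requires no ties)."""
    x, y = list(x), list(y)
    pooled = x + y
    n, nx = len(pooled), len(x)
    mean = nx * (n - nx) / 2

    def ustat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b)

    u_obs = ustat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(n), nx):
        chosen = set(idx)
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in chosen]
        total += 1
        if abs(ustat(xs, ys) - mean) >= abs(u_obs - mean) - 1e-12:
            count += 1
    return u_obs, count / total


def score_motif_direct(weights, background, motif):
    """Per-position log2 odds computed scalar-by-scalar from the raw tables."""
    residues = "ACDEFGHIKLMNPQRSTVWY"
    total = 0.0
    for j, ch in enumerate(motif):
        if ch == "X":
            continue
        i = residues.index(ch)
        total += math.log2(weights[j][i] / background[i])
    return total


def map_exhaustive(motifs, matrices):
    """All (motif, matrix) pairs meeting the threshold, by direct scoring."""
    hits = set()
    for m in motifs:
        for mat in matrices:
            s = score_motif_direct(mat.weights, mat.background, m.residues)
            if s >= mat.score_threshold - 1e-9:
                hits.add((mat.protease_id, m.marker_id, m.terminus))
    return hits


def logrank_permutation_p(df, logrank_fn):
    """Exact permutation p of the log-rank chi-square over all stratum-label
    assignments preserving group sizes."""
    labels = df["stratum"].to_numpy()
    level_a = sorted(set(labels))[0]
    na = int((labels == level_a).sum())
    n = len(labels)
    chi_obs, _ = logrank_fn(df)
    count = total = 0
    for idx in itertools.combinations(range(n), na):
        perm = np.array(["b"] * n, dtype=object)
        perm[list(idx)] = "a"
        d2 = df.copy()
        d2["stratum"] = perm
        chi, _ = logrank_fn(d2)
        total += 1
        if chi >= chi_obs - 1e-9:
            count += 1
    return count / total


def km_by_hand(times, events):
    """Product-limit estimator computed directly from the definition."""
    order = np.argsort(times, kind="stable")
    times = np.asarray(times, float)[order]
    events = np.asarray(events, bool)[order]
    s = 1.0
    curve = []
    for t in np.unique(times):
        at_risk = (times >= t).sum()
        deaths = ((times == t) & events).sum()
        if deaths:
            s *= 1 - deaths / at_risk
            curve.append((t, s))
    return curve
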