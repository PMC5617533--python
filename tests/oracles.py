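"""Independent brute-force oracles used by the test suite.

Everything here is written as plain nested loops / direct textbook formulas,
deliberately sharing no code with the package implementation, so the two
routes can be compared exactly on small inputs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

OFFSETS_13 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def nglcm_brute(labels: np.ndarray, mask: np.ndarray, bins: int) -> np.ndarray:
    """Direction-averaged normalized co-occurrence matrix by triple loops."""
    nx, ny, nz = labels.shape
    mats = []
    for dx, dy, dz in OFFSETS_13:
        counts = np.zeros((bins, bins))
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if not mask[x, y, z]:
                        continue
                    for sx, sy, sz in ((dx, dy, dz), (-dx, -dy, -dz)):
                        u, v, w = x + sx, y + sy, z + sz
                        if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                            counts[labels[x, y, z] - 1, labels[u, v, w] - 1] += 1
        if counts.sum() > 0:
            mats.append(counts / counts.sum())
    assert mats, "no valid pairs"
    return np.mean(mats, axis=0)


def ngtdm_brute(labels: np.ndarray, mask: np.ndarray, bins: int):
    """NGTDM components (p, s, n_valid) by explicit neighborhood loops."""
    nx, ny, nz = labels.shape
    s = np.zeros(bins)
    counts = np.zeros(bins)
    n_valid = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                nbrs = []
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            if dx == dy == dz == 0:
                                continue
                            u, v, w = x + dx, y + dy, z + dz
                            if 0 <= u < nx and 0 <= v < ny and 0 <= w < nz and mask[u, v, w]:
                                nbrs.append(labels[u, v, w])
                if not nbrs:
                    continue
                n_valid += 1
                lv = labels[x, y, z]
                s[lv - 1] += abs(lv - np.mean(nbrs))
                counts[lv - 1] += 1
    p = counts / n_valid if n_valid else counts
    return p, s, n_valid


def ngtdm_features_brute(p, s, n_valid, bins, eps=1e-6):
    """Amadasun-King features by direct double loops over occupied levels."""
    levels = [i + 1 for i in range(bins) if p[i] > 0]
    ng = len(levels)
    psi = sum(p[i - 1] * s[i - 1] for i in levels)
    coarseness = 1.0 / (eps + psi)
    if ng <= 1:
        return dict(coarseness=coarseness, contrast=0.0, busyness=0.0,
                    complexity=0.0, strength=0.0)
    contrast = 0.0
    for i in levels:
        for j in levels:
            contrast += p[i - 1] * p[j - 1] * (i - j) ** 2
    contrast *= sum(s[i - 1] for i in levels) / (ng * (ng - 1) * n_valid)
    busy_den = 0.0
    for i in levels:
        for j in levels:
            busy_den += abs(i * p[i - 1] - j * p[j - 1])
    busyness = psi / busy_den if busy_den > 0 else 0.0
    complexity = 0.0
    for i in levels:
        for j in levels:
            complexity += (abs(i - j) / (n_valid * (p[i - 1] + p[j - 1]))) * (
                p[i - 1] * s[i - 1] + p[j - 1] * s[j - 1]
            )
    strength_num = 0.0
    for i in levels:
        for j in levels:
            strength_num += (p[i - 1] + p[j - 1]) * (i - j) ** 2
    strength = strength_num / (eps + sum(s[i - 1] for i in levels))
    return dict(coarseness=coarseness, contrast=contrast, busyness=busyness,
                complexity=complexity, strength=strength)


def km_brute(times, events):
    """Product-limit estimator from the risk table; returns (times, S)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(times)
    surv = 1.0
    out_t, out_s = [], []
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        if at_risk > 0:
            surv *= 1.0 - d / at_risk
        out_t.append(t)
        out_s.append(surv)
    return np.array(out_t), np.array(out_s)


def logrank_brute(groups):
    """k-sample log-rank chi-square from the risk tables.

    groups: list of (times, events).  Returns the chi-square statistic with
    k-1 degrees of freedom (first group dropped from the quadratic form).
    """
    k = len(groups)
    times = np.concatenate([np.asarray(t, float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, int) for _, e in groups])
    labels = np.concatenate([np.full(len(t), g) for g, (t, _) in enumerate(groups)])
    event_times = np.unique(times[events == 1])
    oe = np.zeros(k)
    cov = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        for g in range(k):
            ng = (at_risk & (labels == g)).sum()
            dg = ((times == t) & (events == 1) & (labels == g)).sum()
            oe[g] += dg - d * ng / n
        if n > 1:
            for g in range(k):
                ng = (at_risk & (labels == g)).sum()
                for h in range(k):
                    nh = (at_risk & (labels == h)).sum()
                    delta = 1.0 if g == h else 0.0
                    cov[g, h] += d * (n - d) / (n - 1) * (ng / n) * (delta - nh / n)
    v = cov[1:, 1:]
    u = oe[1:]
    return float(u @ np.linalg.solve(v, u))


def cox_single_covariate_brute(x, times, events):
    """MLE of a single-covariate Cox partial likelihood (no ties expected)."""
    x = np.asarray(x, float)
    times = np.asarray(times, float)
    events = np.asarray(events, int)

    def neg_logpl(beta):
        ll = 0.0
        for i in range(len(x)):
            if events[i] != 1:
                continue
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_logpl, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)
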