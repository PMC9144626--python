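"""Independent brute-force reference implementations used to cross-check
the package. Everything here is deliberately naive (per-pixel loops, set
arithmetic, grid search, exhaustive enumeration) and shares no code with
the implementation under test."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def confusion_tally(pred: np.ndarray, truth: np.ndarray, k: int = 3) -> np.ndarray:
    cm = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(truth.ravel().tolist(), pred.ravel().tolist()):
        cm[t, p] += 1
    return cm


def set_iou(pred: np.ndarray, truth: np.ndarray, cls: int) -> float:
    a = {tuple(ix) for ix in np.argwhere(pred == cls)}
    b = {tuple(ix) for ix in np.argwhere(truth == cls)}
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def weighted_iou_sets(pred: np.ndarray, truth: np.ndarray, k: int = 3) -> float:
    total = truth.size
    out = 0.0
    for cls in range(k):
        w = (truth == cls).sum() / total
        if w > 0:
            out += w * set_iou(pred, truth, cls)
    return out


def ks_statistic_loop(x, y) -> float:
    """sup |ECDF_x - ECDF_y| evaluated by explicit loops."""
    x = list(x)
    y = list(y)
    best = 0.0
    for t in list(x) + list(y):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def ks_exact_p_enumeration(x, y) -> float:
    """Exact two-sample KS p by enumerating every label assignment."""
    x = list(x)
    y = list(y)
    pooled = x + y
    d_obs = ks_statistic_loop(x, y)
    n = len(pooled)
    hits = trials = 0
    for comb in combinations(range(n), len(x)):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n) if i not in comb]
        if ks_statistic_loop(xs, ys) >= d_obs - 1e-12:
            hits += 1
        trials += 1
    return hits / trials


def fisher_direction_grid(x0: np.ndarray, x1: np.ndarray, n_grid: int = 7200) -> np.ndarray:
    """Maximize the Fisher criterion J(w) = (w.(m1-m0))^2 / (w.Sw.w) over a
    fine grid of unit directions (2-D features only)."""
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    sw = np.zeros((2, 2))
    for xs in (x0, x1):
        d = xs - xs.mean(axis=0)
        sw += d.T @ d
    thetas = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    ws = np.stack([np.cos(thetas), np.sin(thetas)], axis=1)
    num = (ws @ (m1 - m0)) ** 2
    den = np.einsum("ij,jk,ik->i", ws, sw, ws)
    return ws[np.argmax(num / np.maximum(den, 1e-300))]


def icc_oneway(groups: list[np.ndarray]) -> float:
    """One-way ANOVA intraclass correlation ICC(1,1)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    grand = np.concatenate(groups).mean()
    ss_between = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(ns, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    n_total = ns.sum()
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - (ns ** 2).sum() / n_total) / (k - 1)
    return float((ms_between - ms_within) / (ms_between + (n0 - 1) * ms_within))
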