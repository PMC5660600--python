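"""Independent brute-force oracles used to check the package numerics.

These deliberately use the plainest textbook formulations (explicit loops,
normal equations, full running sums) so they share no code path with the
implementations they verify.
"""
from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_oracle(x, y) -> float:
    """Textbook Pearson r over jointly finite entries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Normal-equations OLS: returns (beta, residuals)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta, y - X @ beta


def f_test_oracle(x: np.ndarray, y: np.ndarray):
    """Slope F-test via the t statistic of scipy.stats.linregress."""
    res = stats.linregress(x, y)
    n = len(x)
    t = res.slope / res.stderr
    f = t * t
    p = 2 * stats.t.sf(abs(t), n - 2)
    return res.slope, f, p


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up, written out longhand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def auroc_ranksum(pos: np.ndarray, neg: np.ndarray) -> float:
    """AROC via the Mann-Whitney identity (ties count half)."""
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def auroc_trapezoid(pos: np.ndarray, neg: np.ndarray) -> float:
    """AROC by trapezoidal integration of the empirical ROC curve."""
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    thresholds = np.unique(scores)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append(np.mean(pos >= t))
        fpr.append(np.mean(neg >= t))
    return float(np.trapezoid(tpr, fpr))


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho as Pearson on midranks."""
    return pearson_oracle(stats.rankdata(x), stats.rankdata(y))


def es_bruteforce(scores_ranked: np.ndarray, member_mask: np.ndarray) -> float:
    """Weighted KS enrichment score by walking the full ranked list."""
    n = len(scores_ranked)
    m = int(member_mask.sum())
    w = np.abs(scores_ranked)
    total = w[member_mask].sum()
    running = 0.0
    best = 0.0
    for i in range(n):
        if member_mask[i]:
            running += (w[i] / total) if total > 0 else 1.0 / m
        else:
            running -= 1.0 / (n - m)
        if abs(running) > abs(best) + 1e-9:  # ties keep the earlier extreme
            best = running
    return best


def kde_mode_oracle(x: np.ndarray, grid_size: int = 4096) -> float:
    """Dense-grid argmax of a hand-rolled Gaussian KDE (Silverman factor)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = x.std(ddof=1) * (3.0 * n / 4.0) ** (-0.2)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    dens = np.zeros_like(grid)
    for xi in x:
        dens += np.exp(-0.5 * ((grid - xi) / h) ** 2)
    return float(grid[np.argmax(dens)])


def mc_score_gap_oracle(
    slopes_att,
    slopes_pass,
    gamma: float,
    cnv_probs,
    mrna_sd: float,
    protein_sd: float,
    complex_sd: float,
    n_mc: int = 100_000,
    seed: int = 123,
) -> float:
    """Asymptotic attenuation-score gap by direct Monte-Carlo simulation.

    Draws ``n_mc`` samples per gene from the same generative equations
    (dosage -> mRNA -> protein, with the latent complex term for the
    attenuated genes) and returns mean(score | attenuated) - mean(score |
    pass-through).
    """
    rng = np.random.default_rng(seed)
    states = np.array([-2, -1, 0, 1, 2], dtype=float)

    def score(a: float, g: float) -> float:
        cnv = rng.choice(states, size=n_mc, p=np.asarray(cnv_probs))
        t = a * cnv + rng.normal(0, mrna_sd, n_mc)
        c = rng.normal(0, complex_sd, n_mc)
        p = g * t + (1 - g) * c + rng.normal(0, protein_sd, n_mc)
        return pearson_np(cnv, t) - pearson_np(cnv, p)

    def pearson_np(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    gap_att = np.mean([score(a, gamma) for a in slopes_att])
    gap_pass = np.mean([score(a, 1.0) for a in slopes_pass])
    return float(gap_att - gap_pass)
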