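"""Shared test utilities: signal builders and independent oracles.

The oracles here are deliberately naive (exhaustive enumeration,
brute-force path search, direct numerical integration) so they stay
independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy import integrate
from scipy import stats as sps


def tone(freq: float, fs: float = 128.0, dur: float = 10.0,
         amp: float = 1.0, phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(dur * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def band_power_at(freqs: np.ndarray, psd: np.ndarray, f0: float,
                  half_width: float = 1.0) -> float:
    mask = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    return float(psd[..., mask].sum(axis=-1).squeeze())


# ------------------------------------------------- rank-sum oracle

def exact_ranksum_p(x, y) -> float:
    """Two-sided p by exhaustive enumeration of all group labelings.

    Enumerates every C(n1+n2, n1) assignment of the pooled ranks to the
    first group and doubles the smaller tail of the observed U
    (capped at 1), the standard exact two-sided convention.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = x.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = comb(pooled.size, n1)
    le = ge = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


# ---------------------------------------------- efficiency oracle

def brute_force_distances(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths (edge length 1/w) by enumerating
    every simple path; inf when disconnected."""
    w = np.asarray(weights, float)
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)

    def dfs(node, target, visited, length):
        if node == target:
            dist[src, target] = min(dist[src, target], length)
            return
        for nxt in range(n):
            if nxt not in visited and w[node, nxt] > 0:
                dfs(nxt, target, visited | {nxt}, length + 1.0 / w[node, nxt])

    for src in range(n):
        for dst in range(n):
            if src != dst:
                dfs(src, dst, {src}, 0.0)
    return dist


def brute_force_global_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    if n < 2:
        return 0.0
    dist = brute_force_distances(weights)
    iu = np.triu_indices(n, 1)
    inv = np.where(np.isfinite(dist[iu]), 1.0 / dist[iu], 0.0)
    return float(inv.mean())


def brute_force_local_efficiency(weights: np.ndarray) -> float:
    w = np.asarray(weights, float)
    n = w.shape[0]
    vals = []
    for i in range(n):
        nbrs = np.flatnonzero((w[i] > 0) & (np.arange(n) != i))
        if nbrs.size < 2:
            vals.append(0.0)
        else:
            vals.append(brute_force_global_efficiency(w[np.ix_(nbrs, nbrs)]))
    return float(np.mean(vals))


def random_symmetric_graph(rng: np.random.Generator, n: int,
                           edge_prob: float = 0.7) -> np.ndarray:
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < edge_prob
    w = np.triu(w * mask, 1)
    w = w + w.T
    return w


# ------------------------------------------------- power oracle

def power_by_quadrature(d: float, n1: int, n2: int,
                        alpha: float = 0.05) -> float:
    """Two-sided two-sample t-test power via direct integration over the
    chi-square denominator, avoiding any noncentral-t routine."""
    df = n1 + n2 - 2
    delta = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = sps.t.ppf(1 - alpha / 2, df)

    def integrand(wv):
        s = np.sqrt(wv / df)
        return sps.chi2.pdf(wv, df) * (
            sps.norm.cdf(delta - tcrit * s) + sps.norm.cdf(-delta - tcrit * s))

    val, _ = integrate.quad(integrand, 0, sps.chi2.ppf(1 - 1e-12, df),
                            limit=200)
    return float(val)
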