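"""Independent oracles used by the test suite.

Each function re-derives a quantity by a route deliberately different from
the implementation under test: explicit DFT sums instead of FFT helpers,
exhaustive enumeration instead of closed forms, pairwise comparison counts
instead of rank sums, textbook sums-of-squares instead of a model fit.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np
from scipy import stats as sst


def direct_dft_welch(x: np.ndarray, fs: float = 256.0) -> np.ndarray:
    """Welch periodogram of one epoch by explicit DFT sums.

    Two non-overlapping half-epoch segments, periodic Hann window, one-sided
    density normalization; returns the full native one-sided grid.
    """
    x = np.asarray(x, dtype=float)
    seg = x.size // 2
    n_freq = seg // 2 + 1
    w = 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(seg) / seg)
    k = np.arange(n_freq)[:, None]
    n = np.arange(seg)[None, :]
    angles = -2.0 * np.pi * k * n / seg  # explicit DFT matrix, no FFT anywhere
    cos_m, sin_m = np.cos(angles), np.sin(angles)
    out = np.zeros(n_freq)
    for s in range(2):
        xi = x[s * seg : (s + 1) * seg] * w
        re = cos_m @ xi
        im = sin_m @ xi
        p = (re * re + im * im) / (fs * np.sum(w * w))
        p[1 : seg // 2] *= 2.0
        out += p
    return out / 2.0


def tally_transitions(states: np.ndarray, n_states: int = 3) -> np.ndarray:
    """Empirical transition count matrix from a state sequence."""
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    for a, b in zip(states[:-1], states[1:]):
        counts[int(a), int(b)] += 1
    return counts


def tally_state_percentages(states, codes=(0, 1, 2)) -> dict:
    n = len(states)
    return {c: 100.0 * sum(1 for s in states if s == c) / n for c in codes}


def two_hop_model(edges, seeds):
    """Brute-force seed subnetwork: enumerate all simple paths of length <= 2
    between seed pairs and collect their nodes and edges."""
    edge_set = {frozenset(e) for e in edges if e[0] != e[1]}
    nodes = {n for e in edge_set for n in e}
    seeds = set(seeds) & nodes
    adj = {n: set() for n in nodes}
    for e in edge_set:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    model_edges = set()
    connectors = set()
    for s, t in itertools.combinations(sorted(seeds), 2):
        if frozenset((s, t)) in edge_set:
            model_edges.add(frozenset((s, t)))
        for v in nodes - seeds:
            if s in adj[v] and t in adj[v]:
                connectors.add(v)
                model_edges.add(frozenset((s, v)))
                model_edges.add(frozenset((v, t)))
    return seeds, connectors, model_edges


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n) by term-wise sums."""
    total = comb(N, n)
    acc = 0
    for j in range(k, min(K, n) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return Fraction(acc, total)


def mw_enumeration(x, y):
    """Exact two-sided Mann-Whitney p via enumeration of group assignments.

    U is computed by pairwise comparison counts (ties count 1/2), a
    different route from rank sums.  Returns (U_observed, p).
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    nx = len(x)

    def u_of(idx_x):
        xs = [pooled[i] for i in idx_x]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx_x]
        u = 0.0
        for a in xs:
            for b in ys:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    u_obs = u_of(tuple(range(nx)))
    dist = [u_of(c) for c in itertools.combinations(range(len(pooled)), nx)]
    tol = 1e-9
    p_le = sum(1 for u in dist if u <= u_obs + tol) / len(dist)
    p_ge = sum(1 for u in dist if u >= u_obs - tol) / len(dist)
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def balanced_anova_ss(values, factor_a, factor_b):
    """Textbook sums-of-squares partition for a balanced two-way layout.

    Returns dict with (ss, df, F, p) per effect.  Only valid for balanced
    designs (equal cell counts).
    """
    values = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    a_levels = sorted(set(fa.tolist()))
    b_levels = sorted(set(fb.tolist()))
    grand = values.mean()
    n = values.size
    cell_n = n / (len(a_levels) * len(b_levels))
    ss_a = sum(
        (values[fa == la].size) * (values[fa == la].mean() - grand) ** 2 for la in a_levels
    )
    ss_b = sum(
        (values[fb == lb].size) * (values[fb == lb].mean() - grand) ** 2 for lb in b_levels
    )
    ss_ab = 0.0
    ss_e = 0.0
    for la in a_levels:
        for lb in b_levels:
            cell = values[(fa == la) & (fb == lb)]
            dev = cell.mean() - values[fa == la].mean() - values[fb == lb].mean() + grand
            ss_ab += cell.size * dev**2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = n - len(a_levels) * len(b_levels)
    out = {}
    for name, ss, df in (
        ("A", ss_a, df_a),
        ("B", ss_b, df_b),
        ("A:B", ss_ab, df_ab),
        ("Residual", ss_e, df_e),
    ):
        if name == "Residual":
            out[name] = {"ss": ss, "df": df, "F": np.nan, "p": np.nan}
        else:
            ms = ss / df
            mse = ss_e / df_e
            F = ms / mse if mse > 0 else (0.0 if ss <= 1e-12 else np.inf)
            p = float(sst.f.sf(F, df, df_e)) if np.isfinite(F) else 0.0
            if mse <= 0 and ss <= 1e-12:
                F, p = 0.0, 1.0
            out[name] = {"ss": ss, "df": df, "F": F, "p": p}
    assert abs(cell_n - round(cell_n)) < 1e-9, "oracle requires a balanced design"
    return out
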