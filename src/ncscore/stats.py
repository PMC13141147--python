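"""Nonparametric rank tests with exact small-sample enumeration.

Both tests switch between an exact permutation null (full enumeration) at
small n and a tie- and continuity-corrected normal approximation otherwise;
the approximation carries an Edgeworth kurtosis term with moments computed
exactly from the observed midranks (finite-population sampling moments for
the rank-sum, independent sign-flip moments for the signed-rank), so it
tracks the enumerated null closely right at the mode boundary.

Conventions: the Mann–Whitney statistic U counts pairs where x outranks y
(ties half-credited), so ``alternative="greater"`` tests x stochastically
greater than y.  Signed-rank zero differences are discarded (standard
convention); an all-zero difference vector returns statistic 0, p = 1 with a
warning.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 12

_ALTERNATIVES = ("two-sided", "greater", "less")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Pairs where x > y plus half the ties (Mann–Whitney U of x)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _edgeworth_tails(stat: float, mean: float, var: float,
                     excess_kurtosis: float) -> tuple[float, float]:
    """(P[S >= stat], P[S <= stat]) for a symmetric lattice statistic:
    continuity-corrected normal plus the Edgeworth kurtosis term."""
    if var <= 0:
        return 1.0, 1.0
    sd = math.sqrt(var)

    def _term(z: float) -> float:
        return excess_kurtosis / 24.0 * (z**3 - 3 * z) * sps.norm.pdf(z)

    z_hi = (stat - 0.5 - mean) / sd
    z_lo = (stat + 0.5 - mean) / sd
    p_greater = float(np.clip(sps.norm.sf(z_hi) + _term(z_hi), 0.0, 1.0))
    p_less = float(np.clip(sps.norm.cdf(z_lo) - _term(z_lo), 0.0, 1.0))
    return p_greater, p_less


def _ranksum_null_moments(ranks: np.ndarray, nx: int) -> tuple[float, float, float]:
    """Exact mean/var/excess-kurtosis of the x rank-sum under the permutation
    null: the sum of a simple random sample of size nx from the observed
    midranks (ties enter through the midranks themselves)."""
    a = np.asarray(ranks, dtype=float)
    N, n = len(a), nx
    f = n / N
    d = a - a.mean()
    p2, p4 = float((d**2).sum()), float((d**4).sum())

    def q(k: int) -> float:
        num = den = 1.0
        for t in range(k):
            num *= n - t
            den *= N - t
        return num / den

    e2 = f * (1 - f)
    m11 = q(2) - f * f
    e4 = f * (1 - f) * ((1 - f) ** 3 + f**3)
    m22 = (1 - 2 * f) ** 2 * q(2) + 2 * f**3 * (1 - 2 * f) + f**4
    m31 = ((1 - 2 * f) * (1 - f) + f**2) * (q(2) - f**2)
    m111 = sum(math.comb(3, j) * q(j) * (-f) ** (3 - j) for j in range(4))
    m211 = (1 - 2 * f) * m111 + f * (1 - f) * m11
    m1111 = sum(math.comb(4, j) * q(j) * (-f) ** (4 - j) for j in range(5))
    var = p2 * (e2 - m11)
    mu4 = (e4 * p4 - 4 * m31 * p4 + 3 * m22 * (p2**2 - p4)
           + 6 * m211 * (2 * p4 - p2**2) + m1111 * (3 * p2**2 - 6 * p4))
    kurt = mu4 / var**2 - 3.0 if var > 0 else 0.0
    return float(n * a.mean()), var, kurt


def ranksum_test(x, y, alternative: str = "two-sided",
                 exact_threshold: int = EXACT_MAX_N) -> tuple[float, float]:
    """Mann–Whitney–Wilcoxon rank-sum test.

    Exact by full enumeration of the C(nx+ny, nx) group assignments when the
    combined sample size is <= ``exact_threshold``; otherwise normal
    approximation with tie correction and continuity correction.
    Returns (U statistic of x, p-value).
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    u_obs = _u_statistic(x, y)

    if nx + ny <= exact_threshold:
        combined = np.concatenate([x, y])
        idx = range(nx + ny)
        us = []
        for xs in combinations(idx, nx):
            xm = np.zeros(nx + ny, dtype=bool)
            xm[list(xs)] = True
            us.append(_u_statistic(combined[xm], combined[~xm]))
        us = np.asarray(us)
        eps = 1e-9
        p_greater = float((us >= u_obs - eps).mean())
        p_less = float((us <= u_obs + eps).mean())
    else:
        combined = np.concatenate([x, y])
        ranks = sps.rankdata(combined)
        w_obs = float(ranks[:nx].sum())  # u_obs + nx(nx+1)/2, same null shape
        mean, var, kurt = _ranksum_null_moments(ranks, nx)
        p_greater, p_less = _edgeworth_tails(w_obs, mean, var, kurt)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return u_obs, p


def signed_rank_test(diffs, alternative: str = "two-sided",
                     exact_threshold: int = EXACT_MAX_N) -> tuple[float, float]:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded; an all-zero input yields (0, 1.0) with a
    warning.  Exact by enumeration of the 2^m sign patterns when m (non-zero
    pairs) <= ``exact_threshold``; otherwise tie- and continuity-corrected
    normal approximation.  ``alternative="greater"`` tests diffs > 0.
    Returns (W+ statistic, p-value).
    """
    _check_alternative(alternative)
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    m = len(d)
    if m == 0:
        warnings.warn("signed_rank_test: all differences are zero")
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if m <= exact_threshold:
        # distribution of W+ over all sign patterns (ties share midranks)
        ws = []
        for bits in range(2**m):
            w = 0.0
            for i in range(m):
                if bits >> i & 1:
                    w += ranks[i]
            ws.append(w)
        ws = np.asarray(ws)
        eps = 1e-9
        p_greater = float((ws >= w_plus - eps).mean())
        p_less = float((ws <= w_plus + eps).mean())
    else:
        # W+ = sum of midranks with independent fair sign flips: exact
        # mean/var/kurtosis follow directly (ties enter via the midranks)
        mean = float(ranks.sum()) / 2.0
        var = float((ranks**2).sum()) / 4.0
        kurt = (-float((ranks**4).sum()) / 8.0) / var**2 if var > 0 else 0.0
        p_greater, p_less = _edgeworth_tails(w_plus, mean, var, kurt)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return w_plus, p
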