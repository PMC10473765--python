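"""Independent straight-line reference implementations used as test oracles.

These are deliberately written from the definitional formulas with plain
loops, not shared with (or imported by) the package code they check.
"""

from __future__ import annotations

import math


def pbcor_reference(x, y, bend=0.2):
    """Percentage-bend correlation, directly from the definition."""
    n = len(x)

    def median(v):
        s = sorted(v)
        mid = n // 2
        return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])

    def bent_scores(v):
        med = median(v)
        devs = sorted(abs(vi - med) for vi in v)
        m = math.floor((1.0 - bend) * n + 0.5)
        omega = devs[m - 1]
        psi = [(vi - med) / omega for vi in v]
        low = sum(1 for u in psi if u < -1)
        high = sum(1 for u in psi if u > 1)
        core = sum(vi for vi, u in zip(v, psi) if -1 <= u <= 1)
        phi = (core + omega * (high - low)) / (n - low - high)
        return [max(-1.0, min(1.0, (vi - phi) / omega)) for vi in v]

    a = bent_scores(list(x))
    b = bent_scores(list(y))
    num = sum(ai * bi for ai, bi in zip(a, b))
    den = math.sqrt(sum(ai * ai for ai in a) * sum(bi * bi for bi in b))
    return num / den


def bh_stepup_reference(pvalues):
    """Benjamini-Hochberg adjusted p-values via the literal step-up rule."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, pvalues[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def levene_reference(groups):
    """Classic Levene F: one-way ANOVA on |x - group mean|. Returns F."""
    z = []
    for g in groups:
        mean = sum(g) / len(g)
        z.append([abs(v - mean) for v in g])
    k = len(z)
    n_total = sum(len(g) for g in z)
    grand = sum(sum(g) for g in z) / n_total
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in z)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in z)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        return math.inf if ss_between > 0 else math.nan
    return (ss_between / df_b) / (ss_within / df_w)


def ols_reference(X, y):
    """Coefficients from the normal equations, via Gaussian elimination."""
    k = len(X[0])
    A = [[sum(X[i][a] * X[i][b] for i in range(len(X))) for b in range(k)]
         for a in range(k)]
    rhs = [sum(X[i][a] * y[i] for i in range(len(X))) for a in range(k)]
    # Gauss-Jordan with partial pivoting
    for col in range(k):
        pivot = max(range(col, k), key=lambda r: abs(A[r][col]))
        A[col], A[pivot] = A[pivot], A[col]
        rhs[col], rhs[pivot] = rhs[pivot], rhs[col]
        scale = A[col][col]
        A[col] = [v / scale for v in A[col]]
        rhs[col] /= scale
        for r in range(k):
            if r != col and A[r][col] != 0:
                factor = A[r][col]
                A[r] = [vr - factor * vc for vr, vc in zip(A[r], A[col])]
                rhs[r] -= factor * rhs[col]
    return rhs


def cooks_reference(x, y):
    """Cook's distances via leave-one-out refits of a simple regression.

    d_i = sum_j (yhat_j - yhat_j^(i))^2 / (k * s^2), with the full-data
    residual mean square s^2 and k = 2 coefficients.
    """
    n = len(x)
    X = [[1.0, xi] for xi in x]
    b_full = ols_reference(X, y)
    yhat = [b_full[0] + b_full[1] * xi for xi in x]
    s2 = sum((yi - yh) ** 2 for yi, yh in zip(y, yhat)) / (n - 2)
    out = []
    for i in range(n):
        Xi = [row for j, row in enumerate(X) if j != i]
        yi = [v for j, v in enumerate(y) if j != i]
        b = ols_reference(Xi, yi)
        yhat_i = [b[0] + b[1] * xj for xj in x]
        out.append(sum((a - c) ** 2 for a, c in zip(yhat, yhat_i)) / (2 * s2))
    return out
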