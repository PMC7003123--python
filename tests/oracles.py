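"""Independent brute-force oracles: closed-form normal equations and the
definition of the Pearson correlation, written without numpy linear-algebra
or scipy.stats so they cannot share code paths with the implementation."""

import math


def ols_normal_equations(x, y):
    """Simple-regression intercept and slope from the normal equations."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def residuals_bruteforce(x, y):
    a, b = ols_normal_equations(x, y)
    return [yi - (a + b * xi) for xi, yi in zip(x, y)]


def pearson_definition(u, v):
    n = len(u)
    mu = sum(u) / n
    mv = sum(v) / n
    num = sum((a - mu) * (b - mv) for a, b in zip(u, v))
    den = math.sqrt(
        sum((a - mu) ** 2 for a in u) * sum((b - mv) ** 2 for b in v)
    )
    return num / den


def ccf_bruteforce(t, P, H):
    """Three-step CCF by explicit normal equations and the Pearson
    definition."""
    t, P, H = list(t), list(P), list(H)
    return pearson_definition(
        residuals_bruteforce(t, P), residuals_bruteforce(t, H)
    )


def r_squared_bruteforce(x, y):
    return pearson_definition(list(x), list(y)) ** 2
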