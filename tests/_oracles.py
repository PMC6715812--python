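"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain double loops straight from the
defining formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(indexed, mask, n_levels, direction, distance=1):
    """Symmetric GLCM by enumerating every in-mask ordered pixel pair."""
    dr, dc = OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    rows, cols = indexed.shape
    P = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                P[indexed[r, c] - 1, indexed[r2, c2] - 1] += 1
    return P + P.T


def first_order_bruteforce(sample):
    """First-order statistics recomputed from the definition formulas."""
    x = [float(v) for v in np.ravel(sample)]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    if var > 0:
        skew = (sum((v - mu) ** 3 for v in x) / n) / var**1.5
        kurt = (sum((v - mu) ** 4 for v in x) / n) / var**2
    else:
        skew = kurt = float("nan")
    xs = sorted(x)
    med = xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2
    lo, hi = min(x), max(x)
    if hi > lo:
        counts = [0] * 256
        for v in x:
            b = int((v - lo) / (hi - lo) * 256)
            counts[min(b, 255)] += 1
        ent = -sum(c / n * math.log2(c / n) for c in counts if c)
    else:
        ent = 0.0
    return {
        "mean_intensity": mu,
        "median_intensity": med,
        "intensity_variance": var,
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_minimum": lo,
        "intensity_maximum": hi,
        "intensity_range": hi - lo,
        "intensity_energy": sum(v * v for v in x),
        "intensity_entropy": ent,
    }


def second_order_bruteforce(p):
    """All 23 GLCM statistics by explicit double loops over (i, j).

    Base-2 logs with 0 log 0 = 0; correlation NaN for zero marginal
    variance; information measures NaN when both marginal entropies vanish.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[0]

    def lg(v):
        return math.log2(v) if v > 0 else 0.0

    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    py = [sum(p[i, j] for i in range(n)) for j in range(n)]
    mu_i = sum((i + 1) * px[i] for i in range(n))
    mu_j = sum((j + 1) * py[j] for j in range(n))
    var_i = sum((i + 1 - mu_i) ** 2 * px[i] for i in range(n))
    var_j = sum((j + 1 - mu_j) ** 2 * py[j] for j in range(n))

    auto = contrast = dissim = shade = prom = ssq = 0.0
    energy = entropy = 0.0
    idiff = idn = idm = idmn = invvar = 0.0
    maxp = 0.0
    p_sum = [0.0] * (2 * n + 1)
    p_dif = [0.0] * n
    hxy1 = 0.0
    for i in range(n):
        for j in range(n):
            v = p[i, j]
            I, J = i + 1, j + 1
            auto += I * J * v
            contrast += (I - J) ** 2 * v
            dissim += abs(I - J) * v
            base = I + J - mu_i - mu_j
            shade += base**3 * v
            prom += base**4 * v
            ssq += (I - mu_i) ** 2 * v
            energy += v * v
            entropy -= v * lg(v)
            idiff += v / (1 + abs(I - J))
            idn += v / (1 + abs(I - J) / n)
            idm += v / (1 + (I - J) ** 2)
            idmn += v / (1 + (I - J) ** 2 / n**2)
            if I != J:
                invvar += v / (I - J) ** 2
            maxp = max(maxp, v)
            p_sum[I + J] += v
            p_dif[abs(I - J)] += v
            hxy1 -= v * lg(px[i] * py[j])

    sum_avg = sum(k * p_sum[k] for k in range(2, 2 * n + 1))
    sum_var = sum((k - sum_avg) ** 2 * p_sum[k] for k in range(2, 2 * n + 1))
    sum_ent = -sum(p_sum[k] * lg(p_sum[k]) for k in range(2, 2 * n + 1))
    dif_avg = sum(k * p_dif[k] for k in range(n))
    dif_var = sum((k - dif_avg) ** 2 * p_dif[k] for k in range(n))
    dif_ent = -sum(p_dif[k] * lg(p_dif[k]) for k in range(n))

    hx = -sum(v * lg(v) for v in px)
    hy = -sum(v * lg(v) for v in py)
    hxy2 = -sum(px[i] * py[j] * lg(px[i] * py[j])
                for i in range(n) for j in range(n))
    hmax = max(hx, hy)
    imc1 = (entropy - hxy1) / hmax if hmax > 0 else float("nan")
    if hmax > 0:
        arg = 1 - math.exp(-2 * math.log(2) * (hxy2 - entropy))
        imc2 = math.sqrt(max(arg, 0.0))
    else:
        imc2 = float("nan")
    corr = ((auto - mu_i * mu_j) / math.sqrt(var_i * var_j)
            if var_i > 0 and var_j > 0 else float("nan"))

    return {
        "autocorrelation": auto,
        "cluster_prominence": prom,
        "cluster_shade": shade,
        "contrast": contrast,
        "correlation": corr,
        "difference_average": dif_avg,
        "difference_entropy": dif_ent,
        "difference_variance": dif_var,
        "dissimilarity": dissim,
        "joint_energy": energy,
        "joint_entropy": entropy,
        "inverse_difference": idiff,
        "inverse_difference_normalized": idn,
        "inverse_difference_moment": idm,
        "inverse_difference_moment_normalized": idmn,
        "inverse_variance": invvar,
        "maximum_probability": maxp,
        "sum_average": sum_avg,
        "sum_entropy": sum_ent,
        "sum_variance": sum_var,
        "sum_of_squares": ssq,
        "information_correlation_1": imc1,
        "information_correlation_2": imc2,
    }


def auc_pair_counting(scores, positives):
    """AUC as the probability a positive outranks a negative (ties = 1/2)."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def anova_f_bruteforce(groups):
    """One-way F statistic from the sum-of-squares decomposition."""
    groups = [list(map(float, g)) for g in groups]
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)
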