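"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit loops and textbook formulas,
deliberately sharing no code with the package, so agreement is a real
cross-check rather than a tautology.
"""

import numpy as np


def minmax_scores(values, direction):
    """Direction-aware min-max scoring of one indicator column."""
    lo, hi = min(values), max(values)
    out = []
    for v in values:
        if direction == "more_is_better":
            out.append((v - lo) / (hi - lo))
        else:
            out.append((hi - v) / (hi - lo))
    return out


def correlation_matrix_loops(x):
    """Pearson correlation matrix via explicit sums."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    means = [sum(x[:, j]) / n for j in range(p)]
    corr = np.empty((p, p))
    for j in range(p):
        for k in range(p):
            num = sum((x[i, j] - means[j]) * (x[i, k] - means[k]) for i in range(n))
            dj = sum((x[i, j] - means[j]) ** 2 for i in range(n))
            dk = sum((x[i, k] - means[k]) ** 2 for i in range(n))
            corr[j, k] = num / np.sqrt(dj * dk)
    return corr


def communalities_bruteforce(x, n_keep=None):
    """Communalities from an explicit eigendecomposition of the correlation
    matrix; Kaiser retention when n_keep is None."""
    corr = correlation_matrix_loops(x)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if n_keep is None:
        n_keep = max(1, int(np.sum(eigval >= 1.0)))
    p = corr.shape[0]
    comm = []
    for j in range(p):
        total = 0.0
        for k in range(n_keep):
            loading = eigvec[j, k] * np.sqrt(eigval[k])
            total += loading ** 2
        comm.append(total)
    return np.array(comm)


def weighted_sum_loops(scores, weights):
    """SQI per row as an explicit dot product."""
    out = []
    for row in scores:
        acc = 0.0
        for s, w in zip(row, weights):
            acc += s * w
        out.append(acc)
    return out


def syi_loops(series, sample_sd=True):
    """(mean − sd) / max with explicit sums."""
    n = len(series)
    mean = sum(series) / n
    ss = sum((v - mean) ** 2 for v in series)
    sd = (ss / (n - 1)) ** 0.5 if sample_sd else (ss / n) ** 0.5
    return (mean - sd) / max(series)


def anova_f_loops(groups):
    """(F, df_between, df_within, p-free) from hand sums of squares."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_values) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


def least_squares_closed_form(x, y):
    """Slope/intercept/R² from the normal equations."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ybar = sy / n
    ss_res = sum((yi - slope * xi - intercept) ** 2 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    return slope, intercept, 1 - ss_res / ss_tot


def pearson_r_loops(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = (sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)) ** 0.5
    return num / den
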