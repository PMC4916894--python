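"""Independent reference implementations used only to check the package.

Everything here is written as literal, loop-based arithmetic, deliberately
avoiding the vectorized code paths of the package itself.
"""

from __future__ import annotations

import math


def fluctuation_index_literal(ref: list[float], test: list[float], threshold: float = 0.15) -> float:
    """Step-by-step fluctuation index: derivative, bidirectional ratios,
    divide-by-zero correction, min-max normalization, percent above
    threshold, summed.  Plain Python floats and loops throughout."""
    n = len(ref)

    def deriv(vals):
        return [(vals[(i + 1) % n] - vals[(i - 1) % n]) / 2.0 for i in range(n)]

    def norm_max_abs(vals):
        m = max(abs(v) for v in vals)
        return [0.0] * n if m == 0 else [v / m for v in vals]

    def ratios(num, den):
        out = [None] * n
        finite = []
        for i in range(n):
            a, b = abs(num[i]), abs(den[i])
            if b > 0:
                out[i] = a / b
                finite.append(a / b)
        sub = max(finite) if finite else 1.0
        for i in range(n):
            if out[i] is None:
                out[i] = 1.0 if abs(num[i]) == 0 else sub
        return out

    def norm_min_max(vals):
        lo, hi = min(vals), max(vals)
        return [0.0] * n if hi == lo else [(v - lo) / (hi - lo) for v in vals]

    d1 = norm_max_abs(deriv(list(ref)))
    d2 = norm_max_abs(deriv(list(test)))
    r12 = norm_min_max(ratios(d1, d2))
    r21 = norm_min_max(ratios(d2, d1))
    f12 = 100.0 * sum(1 for v in r12 if v > threshold) / n
    f21 = 100.0 * sum(1 for v in r21 if v > threshold) / n
    return f12 + f21


def otsu_bruteforce(values: list[float], n_bins: int = 256) -> tuple[float, float]:
    """Exhaustive between-class-variance maximization over histogram bin edges.

    Returns (threshold, best between-class variance).  The threshold is the
    bin center at the variance-maximizing split, matching the convention
    that the mask is ``value > threshold``.
    """
    lo, hi = min(values), max(values)
    if hi == lo:
        raise ValueError("constant input")
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in values:
        k = min(int((v - lo) / width), n_bins - 1)
        counts[k] += 1
    centers = [lo + (k + 0.5) * width for k in range(n_bins)]
    total = len(values)
    best_var, best_thr = -1.0, centers[0]
    for split in range(n_bins - 1):  # classes: bins [0..split] vs [split+1..]
        w0 = sum(counts[: split + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(c * x for c, x in zip(counts[: split + 1], centers[: split + 1])) / w0
        mu1 = sum(c * x for c, x in zip(counts[split + 1 :], centers[split + 1 :])) / w1
        var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_thr = var, centers[split]
    return best_thr, best_var


def between_class_variance(values: list[float], threshold: float) -> float:
    """Between-class variance of the split ``value > threshold`` on raw values."""
    lo_class = [v for v in values if v <= threshold]
    hi_class = [v for v in values if v > threshold]
    if not lo_class or not hi_class:
        return 0.0
    total = len(values)
    w0, w1 = len(lo_class) / total, len(hi_class) / total
    mu0 = sum(lo_class) / len(lo_class)
    mu1 = sum(hi_class) / len(hi_class)
    return w0 * w1 * (mu0 - mu1) ** 2


def welch_ttest(a: list[float], b: list[float]) -> tuple[float, float]:
    """Textbook Welch t statistic and two-tailed p with Welch-Satterthwaite df."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, p
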