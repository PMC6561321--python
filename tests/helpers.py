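"""Independent brute-force oracles used by the test suite.

These are deliberately written with plain loops, straight from the
formula definitions, and share no code with the package implementation.
"""

import math

import numpy as np
from scipy.stats import rankdata


def tmm_bruteforce(data, ref_channel, trim_m=0.30, trim_a=0.05,
                   weighted=True):
    """Trimmed weighted mean of M-values, computed the long way.

    ``data`` is a pandas DataFrame (proteins x channels).  Returns a dict
    channel -> factor, rescaled to geometric mean 1.
    """
    totals = {ch: float(data[ch].sum()) for ch in data.columns}
    raw = {}
    for ch in data.columns:
        if ch == ref_channel:
            raw[ch] = 1.0
            continue
        M, A, w_var = [], [], []
        for _, row in data.iterrows():
            xk, xr = float(row[ch]), float(row[ref_channel])
            if xk <= 0 or xr <= 0:
                continue
            pk = xk / totals[ch]
            pr = xr / totals[ref_channel]
            M.append(math.log2(pk / pr))
            A.append(0.5 * math.log2(pk * pr))
            v = (totals[ch] - xk) / (totals[ch] * xk) + \
                (totals[ref_channel] - xr) / (totals[ref_channel] * xr)
            w_var.append(max(v, 1e-24))
        n = len(M)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(M, method="average")
        ra = rankdata(A, method="average")
        num = den = 0.0
        kept = 0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                kept += 1
                if weighted:
                    num += M[i] / w_var[i]
                    den += 1.0 / w_var[i]
                else:
                    num += M[i]
                    den += 1.0
        if kept < 10:  # mirror the untrimmed fallback
            num = den = 0.0
            for i in range(n):
                if weighted:
                    num += M[i] / w_var[i]
                    den += 1.0 / w_var[i]
                else:
                    num += M[i]
                    den += 1.0
        raw[ch] = 2.0 ** (num / den)
    log_mean = np.mean([math.log(v) for v in raw.values()])
    return {ch: v / math.exp(log_mean) for ch, v in raw.items()}


def anova_oneway_bruteforce(groups):
    """Scalar one-way ANOVA p-value from sums of squares, via scipy.stats.f."""
    from scipy.stats import f as fdist

    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    if ssw == 0:
        return 1.0 if ssb == 0 else 0.0
    F = (ssb / dfb) / (ssw / dfw)
    return float(fdist.sf(F, dfb, dfw))
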