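"""Independent brute-force reference implementations of the metrics.

Deliberately written as plain loops / textbook formulas, sharing no code with
the package, so that agreement between the two is a meaningful check.
"""

import math

from scipy import stats


def nrmse_oracle(test, ref):
    n = len(ref)
    sq = sum((float(a) - float(b)) ** 2 for a, b in zip(test, ref))
    return math.sqrt(sq / n) / (max(ref) - min(ref))


def pearson_oracle(test, ref):
    n = len(ref)
    mx = sum(test) / n
    my = sum(ref) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(test, ref))
    sxx = sum((a - mx) ** 2 for a in test)
    syy = sum((b - my) ** 2 for b in ref)
    return sxy / math.sqrt(sxx * syy)


def xapen_oracle(test, ref, m=2, r=0.2):
    """Double-loop template counting, standardized series."""
    def standardize(s):
        n = len(s)
        mean = sum(s) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in s) / n)
        return [(v - mean) / (sd or 1.0) for v in s]

    u = standardize(list(test))
    v = standardize(list(ref))
    n = len(u)

    def phi(mm):
        nt = n - mm + 1
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                if max(abs(u[i + k] - v[j + k]) for k in range(mm)) <= r:
                    count += 1
            total += math.log(count / nt)
        return total / nt

    return phi(m) - phi(m + 1)


def slope_oracle(series, t):
    """Closed-form simple linear regression slope."""
    n = len(t)
    mt = sum(t) / n
    ms = sum(series) / n
    num = sum((a - mt) * (b - ms) for a, b in zip(t, series))
    den = sum((a - mt) ** 2 for a in t)
    return num / den


def bland_altman_oracle(test, ref):
    d = [a - b for a, b in zip(test, ref)]
    n = len(d)
    mean = sum(d) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in d) / (n - 1))
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def ttest_oracle(values, mu0=0.0):
    n = len(values)
    mean = sum(values) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    t = (mean - mu0) / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return t, p
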