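"""Independent textbook-formula oracles, coded with plain Python loops.

These deliberately avoid the package's own code paths (and numpy
vectorisation) so they can serve as cross-checks for the pooling and HWE
implementations.
"""

from math import exp, sqrt


def fixed_pool(ys, vs):
    """Inverse-variance weighted mean and its standard error."""
    num = 0.0
    den = 0.0
    for y, v in zip(ys, vs):
        num += y / v
        den += 1.0 / v
    return num / den, sqrt(1.0 / den)


def cochran_q(ys, vs):
    mu, _ = fixed_pool(ys, vs)
    q = 0.0
    for y, v in zip(ys, vs):
        q += (y - mu) ** 2 / v
    return q


def i_squared(ys, vs):
    q = cochran_q(ys, vs)
    if q <= 0.0:
        return 0.0
    df = len(ys) - 1
    return max(0.0, (q - df) / q) * 100.0


def dl_tau2(ys, vs):
    q = cochran_q(ys, vs)
    s1 = sum(1.0 / v for v in vs)
    s2 = sum(1.0 / v**2 for v in vs)
    return max(0.0, (q - (len(ys) - 1)) / (s1 - s2 / s1))


def random_pool(ys, vs):
    """DerSimonian-Laird pooled mean and standard error."""
    t2 = dl_tau2(ys, vs)
    num = 0.0
    den = 0.0
    for y, v in zip(ys, vs):
        num += y / (v + t2)
        den += 1.0 / (v + t2)
    return num / den, sqrt(1.0 / den)


def hwe_chi2(cc, ct, tt):
    """Pearson chi-square against Hardy-Weinberg expected counts."""
    n = cc + ct + tt
    p = (2 * cc + ct) / (2.0 * n)
    q = 1.0 - p
    expected = [n * p * p, 2.0 * n * p * q, n * q * q]
    chi2 = 0.0
    for obs, e in zip([cc, ct, tt], expected):
        chi2 += (obs - e) ** 2 / e
    return chi2


def odds_ratio(a, b, c, d):
    """Ratio of exposure odds, computed as odds then divided."""
    return (a / b) / (c / d)
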