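"""Independent brute-force evaluation of the disproportionality formulas.

Deliberately written as direct textbook arithmetic (plain ``math``, no
log-space tricks, per-cell chi-square expansion, literal Bate-1998
fractions) so it shares no code path with the package implementation.
"""

import math


def ror(a, b, c, d):
    return (a / c) / (b / d)


def ror_ci(a, b, c, d, z=1.96):
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    point = ror(a, b, c, d)
    return (
        math.exp(math.log(point) - z * se),
        math.exp(math.log(point) + z * se),
    )


def prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def prr_ci(a, b, c, d, z=1.96):
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    point = prr(a, b, c, d)
    return (
        math.exp(math.log(point) - z * se),
        math.exp(math.log(point) + z * se),
    )


def chi2(a, b, c, d, yates=False):
    """Pearson chi-square as the per-cell sum over observed vs expected."""
    n = a + b + c + d
    rows, cols = (a + b, c + d), (a + c, b + d)
    total = 0.0
    obs = [[a, b], [c, d]]
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            diff = abs(obs[i][j] - e)
            if yates:
                diff = max(diff - 0.5, 0.0)
            total += diff**2 / e
    return total


def ic(a, b, c, d):
    n = a + b + c + d
    return math.log2(a * n / ((a + b) * (a + c)))


def bcpnn(a, b, c, d, alpha1=1.0, beta1=1.0, gamma11=1.0, alpha=2.0, beta=2.0):
    """(EIC, VIC, IC025) from the closed-form posterior moments."""
    n = a + b + c + d
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    eic = math.log2(
        (a + gamma11) * (n + alpha) * (n + beta)
        / ((n + gamma) * (a + b + alpha1) * (a + c + beta1))
    )
    vic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - a - b + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
        + (n - a - c + beta - beta1) / ((a + c + beta1) * (1 + n + beta))
    ) / math.log(2) ** 2
    return eic, vic, eic - 2 * math.sqrt(vic)


def ebgm(a, b, c, d):
    n = a + b + c + d
    return a * n / ((a + c) * (a + b))


def ebgm_bounds(a, b, c, d, z=1.96):
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    point = ebgm(a, b, c, d)
    return (
        math.exp(math.log(point) - z * se),
        math.exp(math.log(point) + z * se),
    )
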