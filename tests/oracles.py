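"""Independent literal-evaluation oracles for the estimators.

Each oracle is a direct term-by-term transcription of the defining formula
in plain Python (math/cmath loops), deliberately sharing no code with the
package implementation.
"""

import cmath
import math


def wrap(x: float) -> float:
    """Wrap a single angle to (-pi, pi]."""
    w = math.fmod(x, 2 * math.pi)
    if w <= -math.pi:
        w += 2 * math.pi
    elif w > math.pi:
        w -= 2 * math.pi
    return w


def oracle_circ_mean(angles):
    z = sum(cmath.exp(1j * a) for a in angles)
    rbar = abs(z) / len(angles)
    mu = cmath.phase(z) if rbar > 1e-12 else 0.0
    return mu, rbar


def oracle_ccorr_standard(alpha, beta):
    mu, _ = oracle_circ_mean(alpha)
    nu, _ = oracle_circ_mean(beta)
    num = sum(math.sin(a - mu) * math.sin(b - nu) for a, b in zip(alpha, beta))
    da = sum(math.sin(a - mu) ** 2 for a in alpha)
    db = sum(math.sin(b - nu) ** 2 for b in beta)
    return num / math.sqrt(da * db)


def oracle_ccorr_adjusted(alpha, beta):
    mu, _ = oracle_circ_mean(alpha)
    nu, _ = oracle_circ_mean(beta)
    r_diff = abs(sum(cmath.exp(1j * (a - b)) for a, b in zip(alpha, beta)))
    r_sum = abs(sum(cmath.exp(1j * (a + b)) for a, b in zip(alpha, beta)))
    da = sum(math.sin(a - mu) ** 2 for a in alpha)
    db = sum(math.sin(b - nu) ** 2 for b in beta)
    return (r_diff - r_sum) / (2 * math.sqrt(da * db))


def oracle_plv(alpha, beta):
    z = sum(cmath.exp(1j * (a - b)) for a, b in zip(alpha, beta))
    return abs(z) / len(alpha)


def oracle_hodges_ajne_m(angles, ndirections=3600):
    """Brute-force half-plane scan over a fixed grid of directions."""
    n = len(angles)
    best = n
    for k in range(ndirections):
        theta = -math.pi + 2 * math.pi * k / ndirections
        inside = sum(1 for a in angles if 0 <= wrap(a - theta) < math.pi)
        best = min(best, inside, n - inside)
    return best


def oracle_hodges_ajne_m_exact(angles):
    """Literal minimum over all half-planes of the strictly-inside count.

    Evaluates the count at midpoints between every pair of consecutive
    boundary events (data angles and their antipodes), where it is
    piecewise constant, via a plain per-point membership loop.
    """
    n = len(angles)
    events = sorted({wrap(a) for a in angles} | {wrap(a + math.pi) for a in angles})
    best = n
    for k, e in enumerate(events):
        nxt = events[(k + 1) % len(events)] + (2 * math.pi if k + 1 == len(events) else 0)
        theta = (e + nxt) / 2.0
        inside = sum(1 for a in angles if 0 < wrap(a - theta) < math.pi)
        best = min(best, inside, n - inside)
    return best


def oracle_hodges_ajne_pvalue(n, m):
    if n - 2 * m <= 0:
        return 1.0
    if n <= 50:
        p = (n - 2 * m) * math.comb(n, m) * 2.0 ** (1 - n)
    else:
        big_a = math.pi * math.sqrt(n) / (2 * (n - 2 * m))
        p = math.sqrt(2 * math.pi) / big_a * math.exp(-math.pi**2 / (8 * big_a**2))
    return min(1.0, p)
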