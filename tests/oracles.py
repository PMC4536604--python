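"""Independent brute-force reference implementations.

Each statistic is recomputed from its textbook definition with explicit
loops (no numpy/scipy shortcuts, no code shared with the package) so the
package kernels can be checked against a genuinely independent route.
"""

from __future__ import annotations

import math


def brute_mean(values):
    return sum(values) / len(values)


def brute_sample_sd(values):
    m = brute_mean(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


def brute_cv_percent(values):
    return brute_sample_sd(values) / brute_mean(values) * 100.0


def brute_mean_abs(values):
    return sum(abs(v) for v in values) / len(values)


def brute_pearson_r(x, y):
    mx, my = brute_mean(x), brute_mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def brute_bland_altman(x, y, k_sd=2.0):
    diffs = [b - a for a, b in zip(x, y)]
    bias = brute_mean(diffs)
    sd = brute_sample_sd(diffs)
    return bias, sd, bias - k_sd * sd, bias + k_sd * sd


def brute_daily_mean_se(rows):
    """rows: (day, lab, value) triples -> {day: (mean, se or None, n)}."""
    by_day: dict = {}
    for day, _lab, value in rows:
        by_day.setdefault(day, []).append(value)
    out = {}
    for day, values in by_day.items():
        mean = brute_mean(values)
        se = (
            brute_sample_sd(values) / math.sqrt(len(values))
            if len(values) > 1
            else None
        )
        out[day] = (mean, se, len(values))
    return out


def brute_westgard(z):
    """Westgard multirule flags by windowed scans over the whole series."""
    n = len(z)
    flags = [set() for _ in range(n)]
    for i in range(n):
        if abs(z[i]) > 2:
            flags[i].add("1_2s")
        if abs(z[i]) > 3:
            flags[i].add("1_3s")
    for i in range(1, n):
        a, b = z[i - 1], z[i]
        if (a > 2 and b > 2) or (a < -2 and b < -2):
            flags[i].add("2_2s")
        if ((a > 2 and b < -2) or (a < -2 and b > 2)) and abs(b - a) >= 4:
            flags[i].add("R_4s")
    for i in range(3, n):
        window = z[i - 3 : i + 1]
        if all(v > 1 for v in window) or all(v < -1 for v in window):
            flags[i].add("4_1s")
    for i in range(9, n):
        window = z[i - 9 : i + 1]
        if all(v > 0 for v in window) or all(v < 0 for v in window):
            flags[i].add("10_x")
    return [frozenset(s) for s in flags]
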