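"""Independent brute-force reference implementations.

Written as literal double loops straight from the defining formulas,
deliberately sharing no code with the package. They exist solely as
oracles for the vectorized implementations.
"""

import math


def _dist(a, b, metric):
    if metric == "chebyshev":
        return max(abs(x - y) for x, y in zip(a, b))
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def apen_bruteforce(x, m, r, metric="chebyshev"):
    """Approximate entropy: hard threshold, self-matches included."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm):
        templates = [x[i:i + mm] for i in range(N - mm + 1)]
        total = 0.0
        for ti in templates:
            count = 0
            for tj in templates:
                if _dist(ti, tj, metric) <= r:
                    count += 1
            total += math.log(count / len(templates))
        return total / len(templates)

    return phi(m) - phi(m + 1)


def fzen_bruteforce(x, m, n, r, metric="chebyshev"):
    """Fuzzy entropy: baseline-removed templates, exponential membership,
    self-matches excluded, 1/(N-m) outer and 1/(N-m-1) inner normalization."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm):
        count = N - m  # same template count at both embedding orders
        templates = []
        for i in range(count):
            t = x[i:i + mm]
            mean = sum(t) / len(t)
            templates.append([v - mean for v in t])
        outer = 0.0
        for i in range(count):
            inner = 0.0
            for j in range(count):
                if j == i:
                    continue
                d = _dist(templates[i], templates[j], metric)
                inner += math.exp(-(d ** n) / r)
            outer += inner / (count - 1)
        return outer / count

    return math.log(phi(m)) - math.log(phi(m + 1))


def mse_bruteforce(a, b):
    total = 0.0
    for x, y in zip(a, b):
        total += (x - y) ** 2
    return total / len(a)
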