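"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's own code paths (and the scipy
convenience wrappers they rely on) so that agreement is meaningful.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from math import comb


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact P(X >= k) by summing the hypergeometric pmf with integer arithmetic."""
    total = comb(N, n)
    s = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(s, total)


def welch_t(a, b):
    """Textbook Welch statistic: t, Welch-Satterthwaite df (no p-value)."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def pearson_r(x, y) -> float:
    """Long-form sample correlation: cov / (sd_x * sd_y)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def bh_adjust(p):
    """Direct evaluation of the step-up formula (quadratic time)."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [0.0] * m
    for rank_pos, i in enumerate(order):
        q = min(
            min(m * p[order[j]] / (j + 1) for j in range(rank_pos, m)),
            1.0,
        )
        out[i] = q
    return out


def kcore_bruteforce(nodes, edges) -> dict:
    """Core numbers via exhaustive induced-subgraph checking.

    core(v) = max over induced subgraphs S containing v of the minimum
    degree within S.  Exponential; only for tiny graphs.
    """
    nodes = list(nodes)
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    core = {v: 0 for v in nodes}
    for size in range(1, len(nodes) + 1):
        for subset in combinations(nodes, size):
            s = set(subset)
            mindeg = min(len(adj[v] & s) for v in subset)
            for v in subset:
                core[v] = max(core[v], mindeg)
    return core
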