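"""Independent reference implementations used only by the test suite.

Each oracle is written from the textbook definition, deliberately sharing no
code with the package: a character-by-character triplet scan for cytosine
contexts, full hypergeometric enumeration for the two-sided Fisher test, the
sort-based Benjamini-Hochberg step-up, and the closed-form Welch t-test.
"""

from __future__ import annotations

import math

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_context(seq: str, pos: int, strand: str) -> str:
    """Triplet-scan context call: pos is 1-based; strand-oriented downstream bases."""
    if strand == "+":
        down = seq[pos : pos + 2]
    else:
        down = "".join(_COMP[b] for b in reversed(seq[max(0, pos - 3) : pos - 1]))
    if len(down) >= 1 and down[0] == "G":
        return "CG"
    if len(down) < 2 or down[0] == "N" or down[1] == "N":
        return "NA"
    return "CHG" if down[1] == "G" else "CHH"


def brute_cytosines(seq: str) -> list[tuple[int, str, str]]:
    """(pos, strand, context) for every C on + and every G (minus-strand C)."""
    out = []
    for i, b in enumerate(seq, start=1):
        if b == "C":
            out.append((i, "+", brute_context(seq, i, "+")))
        if b == "G":
            out.append((i, "-", brute_context(seq, i, "-")))
    return out


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support.

    Sums P(x) over all tables with the observed margins whose probability does
    not exceed the observed table's (with the conventional 1+1e-7 relative
    tolerance for ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    logp = [
        _log_comb(r1, x) + _log_comb(r2, c1 - x) - _log_comb(n, c1)
        for x in range(lo, hi + 1)
    ]
    p_obs = math.exp(logp[a - lo])
    total = sum(math.exp(lp) for lp in logp if math.exp(lp) <= p_obs * (1 + 1e-7))
    return min(1.0, total)


def bh_stepup(pvals) -> list[float]:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


def welch_t(x, y) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p from the closed form."""
    from scipy.stats import t as tdist  # distribution function only

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((xi - mx) ** 2 for xi in x) / (nx - 1)
    vy = sum((yi - my) ** 2 for yi in y) / (ny - 1)
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by summation."""
    hi = min(K, n)
    return sum(
        math.exp(_log_comb(K, x) + _log_comb(N - K, n - x) - _log_comb(N, n))
        for x in range(k, hi + 1)
    )
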