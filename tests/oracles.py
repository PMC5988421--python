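"""Independent reference implementations used to cross-check the package.

These deliberately use different routes than the library code: exhaustive
enumeration, closed-form algebra and rational arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction

from scipy.special import betainc

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def brute_force_scan(
    read: str,
    window: str,
    breakpoint: int,
    min_overlap: int = 6,
    max_mismatches: int = 0,
    scan_both_strands: bool = True,
):
    """Exhaustive junction scan over every offset and both strands.

    Returns (strand, offset, left, right) for the preferred qualifying
    alignment (forward before reverse, smallest offset first) or None.
    A qualifying alignment lies fully inside the window, has at most
    ``max_mismatches`` mismatching positions ('N' never matches), and
    per-side overlaps with the breakpoint both >= ``min_overlap``.
    """
    n = len(read)
    orientations = [("forward", read)]
    if scan_both_strands:
        orientations.append(("reverse", revcomp(read)))
    for strand, oriented in orientations:
        for offset in range(0, len(window) - n + 1):
            mm = 0
            for a, b in zip(oriented, window[offset : offset + n]):
                if a != b or a == "N" or b == "N":
                    mm += 1
            if mm > max_mismatches:
                continue
            left = breakpoint - offset
            right = n - left
            if left >= min_overlap and right >= min_overlap:
                return strand, offset, left, right
    return None


def welch_p_closed_form(a, b) -> tuple[float, float, float]:
    """Welch t, df and two-sided p from first principles.

    p uses the regularized incomplete beta form of the t CDF rather
    than scipy.stats.t.
    """
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, df, float(p)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by rational enumeration over margin-fixed tables.

    Probability-mass rule: sum hypergeometric probabilities of every
    table with the observed margins whose probability is at most that of
    the observed table.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_weight(k: int) -> Fraction:
        # unnormalized hypergeometric weight C(r1,k) C(r2,c1-k)
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k))

    total = Fraction(math.comb(n, c1))
    observed = table_weight(a)
    acc = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = table_weight(k)
        if w <= observed:
            acc += w
    return acc / total


def km_by_hand(times_events: list[tuple[float, int]]) -> list[tuple[float, float]]:
    """Product-limit estimate from (time, event) pairs, events before
    censorings at ties.  Returns [(event_time, S(t))]."""
    s = 1.0
    out = []
    event_times = sorted({t for t, e in times_events if e == 1})
    for t in event_times:
        at_risk = sum(1 for ti, _ in times_events if ti >= t)
        d = sum(1 for ti, e in times_events if ti == t and e == 1)
        s *= 1 - d / at_risk
        out.append((t, s))
    return out
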