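"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the normalizer oracle
enumerates every equivalent variant representation by direct haplotype
comparison; the exact-test oracle enumerates all 2x2 tables with fixed
margins via binomial coefficients; the Wilson oracle inverts the score test
numerically.
"""

from __future__ import annotations

from math import comb, sqrt

from scipy.optimize import brentq
from scipy.stats import norm

VALID = set("ACGT")


def apply_variant(seq: str, pos: int, ref: str, alt: str) -> str:
    """Haplotype produced by substituting ref -> alt at 1-based pos."""
    assert seq[pos - 1 : pos - 1 + len(ref)] == ref
    return seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]


def enumerate_equivalents(
    seq: str, pos: int, ref: str, alt: str, window: int = 40, max_ref: int = 12
) -> list[tuple[int, str, str]]:
    """All valid (pos, ref, alt) representations yielding the same haplotype."""
    target = apply_variant(seq, pos, ref, alt)
    delta = len(target) - len(seq)
    out = []
    lo = max(1, pos - window)
    hi = min(len(seq), pos + window)
    for p in range(lo, hi + 1):
        for lr in range(0, max_ref + 1):
            if p - 1 + lr > len(seq):
                continue
            r = seq[p - 1 : p - 1 + lr]
            la = lr + delta
            if la < 0:
                continue
            a = target[p - 1 : p - 1 + la]
            if not r or not a or r == a:
                continue
            if set(r) - VALID or set(a) - VALID:
                continue
            if seq[: p - 1] + a + seq[p - 1 + lr :] == target:
                out.append((p, r, a))
    return out


def minimal_representation(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-most irreducible representation among all equivalents.

    Irreducible: trailing bases differ, and no shared leading base while both
    alleles are longer than one (the single anchor base of an indel is the
    only permitted shared prefix).
    """
    candidates = [
        (p, r, a)
        for p, r, a in enumerate_equivalents(seq, pos, ref, alt)
        if r[-1] != a[-1] and not (len(r) > 1 and len(a) > 1 and r[0] == a[0])
    ]
    assert candidates, "no irreducible representation found"
    candidates.sort(key=lambda c: (c[0], len(c[1]) + len(c[2])))
    return candidates[0]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact conditional p by full enumeration with fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = comb(n, r1)

    def pmf(x: int) -> float:
        return comb(c1, x) * comb(n - c1, r1 - x) / denom

    p_obs = pmf(a)
    lo = max(0, r1 - (n - c1))
    hi = min(r1, c1)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7))
    return min(total, 1.0)


def wilson_upper_numeric(count: int, total: int, ci_level: float) -> float:
    """Upper Wilson bound by inverting the score test with a root finder."""
    z = norm.ppf(1 - (1 - ci_level) / 2)
    phat = count / total

    def f(p: float) -> float:
        return (phat - p) ** 2 - z * z * p * (1 - p) / total

    if phat >= 1.0:
        return 1.0
    return brentq(f, min(phat + 1e-12, 1.0), 1.0)


def brute_force_overlaps(cohort, population, min_overlap: int = 1):
    """Quadratic all-pairs interval overlap scan on (contig, start, end)."""
    pairs = []
    for c in cohort:
        for p in population:
            if c.contig != p.contig:
                continue
            ov = min(c.end, p.end) - max(c.start, p.start)
            if ov >= min_overlap:
                pairs.append((c, p, ov))
    return pairs
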