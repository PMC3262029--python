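"""Independent brute-force oracles used by the test suite.

Everything here is written with plain Python primitives (no imports from the
package under test) so that agreement between the package and these
functions is a genuine cross-check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _naive_match_forward(seq, pos, flanks, spacers, mask_policy):
    """Mismatch count for one candidate, or None if suppressed."""
    length = sum(len(f) for f in flanks) + sum(spacers)
    span = seq[pos : pos + length]
    if mask_policy == "skip_masked" and any(c.islower() or c.upper() == "N" for c in span):
        return None
    mm = 0
    off = 0
    for i, flank in enumerate(flanks):
        for base in flank:
            c = span[off].upper()
            if c == "N":
                return None
            if c != base:
                mm += 1
            off += 1
        if i < len(spacers):
            off += spacers[i]
    return mm


def naive_scan(seq, flanks, spacer_ranges, max_mismatch=0, strands="both",
               mask_policy="ignore_mask"):
    """All-positions/all-spacers/all-strands enumeration.

    Returns ``{(start, length, strand): min_mismatches}`` with start the
    leftmost sense-strand base.
    """
    n = len(seq)
    found: dict[tuple, int] = {}

    def record(key, mm):
        if key not in found or mm < found[key]:
            found[key] = mm

    spacer_sets = list(itertools.product(
        *(range(lo, hi + 1) for lo, hi in spacer_ranges)))
    seqs = []
    if strands in ("forward", "both"):
        seqs.append(("+", seq))
    if strands in ("reverse", "both"):
        seqs.append(("-", naive_revcomp(seq)))
    for strand, s in seqs:
        for spacers in spacer_sets:
            length = sum(len(f) for f in flanks) + sum(spacers)
            for pos in range(0, n - length + 1):
                mm = _naive_match_forward(s, pos, flanks, spacers, mask_policy)
                if mm is not None and mm <= max_mismatch:
                    start = pos if strand == "+" else n - pos - length
                    record((start, length, strand), mm)
    return found


def walk_extract(contig: str, strand: str, tss_1based: int, upstream, downstream):
    """Per-base walking extraction oracle.

    Walks the genome one base at a time in the direction of transcription
    from the most-upstream window position to the most-downstream one,
    complementing each base for minus-strand transcripts.
    """
    rels = list(range(upstream if upstream is not None else 1, 0)) + \
        list(range(1, downstream + 1))
    out = []
    for rel in rels:
        u = rel - 1 if rel > 0 else rel  # offset from the TSS base
        if strand == "+":
            g = tss_1based + u
            base = contig[g - 1]
        else:
            g = tss_1based - u
            base = _COMP[contig[g - 1]]
        out.append(base)
    return "".join(out)


def fisher_two_sided_exact(a, b, c, d) -> Fraction:
    """Two-sided Fisher p by exact rational enumeration (point-prob rule)."""
    n = a + b + c + d
    r1, k1 = a + b, a + c
    denom = comb(n, r1)
    pmf = {}
    for x in range(max(0, r1 + k1 - n), min(r1, k1) + 1):
        pmf[x] = Fraction(comb(k1, x) * comb(n - k1, r1 - x), denom)
    p_obs = pmf[a]
    return sum((p for p in pmf.values() if p <= p_obs), Fraction(0))


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up reference."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


def poisson_upper_tail(observed: int, mu: float) -> float:
    """P(X >= observed) by the complementary partial sum."""
    import math

    if observed <= 0:
        return 1.0
    total = 0.0
    for k in range(observed):
        total += math.exp(-mu) * mu**k / math.factorial(k)
    return 1.0 - total


def hypergeom_upper_tail(overlap, universe, n_a, n_b) -> Fraction:
    """P(X >= overlap) by exact rational enumeration."""
    denom = comb(universe, n_b)
    total = Fraction(0)
    for x in range(overlap, min(n_a, n_b) + 1):
        if n_b - x <= universe - n_a:
            total += Fraction(comb(n_a, x) * comb(universe - n_a, n_b - x), denom)
    return total
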