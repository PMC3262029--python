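"""Background models and exact enrichment statistics.

The middle part of a tandem motif is treated as governed by the genomic
background of the promoter, so analytic match probabilities multiply base
probabilities over flank positions only; spacer positions contribute factor
one.  Per-bin positional enrichment compares observed counts with the
analytic expectation under a Poisson upper tail (expected counts are small
relative to the number of scanned positions), with Benjamini-Hochberg
correction across bins.  Fisher's exact two-sided test uses the
point-probability rule (all tables with the observed margins whose
probability is at most that of the observed table, relative tie tolerance
1e-7), computed in log space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .coords import linear
from .motif import ScanConfig, TandemMotif

__all__ = [
    "BackgroundModel",
    "ContingencyTable",
    "estimate_background",
    "motif_probability",
    "expected_hits",
    "bin_enrichment",
    "fisher_exact_2x2",
    "bh_adjust",
    "set_overlap_test",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class BackgroundModel:
    """Base-composition model: i.i.d. (order 0) or first-order Markov.

    ``base_freqs`` is the A,C,G,T probability vector (for order 1 it is the
    stationary distribution used as the start distribution); ``transition``
    is the 4x4 row-stochastic matrix for order 1.
    """

    order: int
    base_freqs: tuple[float, float, float, float]
    transition: tuple | None = None

    def __post_init__(self):
        if self.order not in (0, 1):
            raise ValueError("order must be 0 or 1")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or (f > 1).any():
            raise ValueError("base_freqs must be 4 probabilities")
        if abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must sum to 1 within 1e-12")
        if self.order == 1:
            t = np.asarray(self.transition, dtype=float)
            if t.shape != (4, 4) or (t < 0).any():
                raise ValueError("transition must be a non-negative 4x4 matrix")
            if np.abs(t.sum(axis=1) - 1.0).max() > 1e-12:
                raise ValueError("transition rows must sum to 1 within 1e-12")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(0, (0.25, 0.25, 0.25, 0.25))

    @classmethod
    def from_gc(cls, gc: float) -> "BackgroundModel":
        """i.i.d. model with the given GC content, AT and GC split evenly."""
        at, s = (1.0 - gc) / 2.0, gc / 2.0
        return cls(0, (at, s, s, at))

    def freq(self, base: str) -> float:
        return self.base_freqs[_BASE_INDEX[base]]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 non-negative integer counts ``[[a, b], [c, d]]``."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")


def _stationary(transition: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(transition.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_background(
    sequences, order: int = 0, mask_policy: str = "ignore_mask"
) -> BackgroundModel:
    """Maximum-likelihood base composition with pseudo-count 1.

    ``N`` is always excluded; lowercase (soft-masked) bases are excluded
    under ``skip_masked`` and counted case-insensitively under
    ``ignore_mask``.  For order 1, transitions spanning an excluded base are
    skipped and the start distribution is the stationary distribution of the
    estimated transition matrix.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    counts = np.zeros(4, dtype=np.int64)
    trans = np.zeros((4, 4), dtype=np.int64)
    for seq in seqs:
        prev = -1
        for c in seq:
            if mask_policy == "skip_masked" and c.islower():
                prev = -1
                continue
            i = _BASE_INDEX.get(c.upper(), -1)
            if i < 0:  # N or other
                prev = -1
                continue
            counts[i] += 1
            if prev >= 0:
                trans[prev, i] += 1
            prev = i
    freqs = (counts + 1) / (counts.sum() + 4)
    if order == 0:
        return BackgroundModel(0, tuple(freqs))
    tmat = (trans + 1) / (trans.sum(axis=1, keepdims=True) + 4)
    return BackgroundModel(1, tuple(_stationary(tmat)), tuple(map(tuple, tmat)))


def motif_probability(
    motif: TandemMotif, spacer_choice, background: BackgroundModel
) -> float:
    """Probability of an exact match at one start position on one strand.

    Order 0: product of background probabilities over flank bases.  Order 1:
    stationary start at the first flank base, transition products within
    flanks, and ``(s+1)``-step transition probabilities across each free
    spacer of length ``s`` (summation over all spacer paths).
    """
    spacers = tuple(spacer_choice)
    motif._check_spacers(spacers)
    if background.order == 0:
        p = 1.0
        for f in motif.flanks:
            for b in f:
                p *= background.freq(b)
        return p
    tmat = np.asarray(background.transition, dtype=float)
    powers = {s: np.linalg.matrix_power(tmat, s + 1) for s in set(spacers)}
    p = background.freq(motif.flanks[0][0])
    for fi, flank in enumerate(motif.flanks):
        for a, b in zip(flank, flank[1:]):
            p *= tmat[_BASE_INDEX[a], _BASE_INDEX[b]]
        if fi < len(spacers):
            nxt = motif.flanks[fi + 1][0]
            p *= powers[spacers[fi]][_BASE_INDEX[flank[-1]], _BASE_INDEX[nxt]]
    return float(p)


def _strand_probs(motif, spacers, config, background):
    """Per-position match probabilities for the strands in scope."""
    total = 0.0
    if config.strands in ("forward", "both"):
        total += motif_probability(motif, spacers, background)
    if config.strands in ("reverse", "both"):
        rc = motif.reverse_complement()
        total += motif_probability(rc, tuple(reversed(spacers)), background)
    return total


def expected_hits(
    window_len: int,
    motif: TandemMotif,
    config: ScanConfig,
    background: BackgroundModel,
) -> float:
    """Expected exact-match count in a window of ``window_len`` bases."""
    if window_len < motif.min_length:
        raise ValueError("window shorter than minimal motif length")
    total = 0.0
    for spacers in motif.spacer_choices():
        n_starts = window_len - motif.realized_length(spacers) + 1
        if n_starts <= 0:
            continue
        total += n_starts * _strand_probs(motif, spacers, config, background)
    return total


def bin_enrichment(
    histogram,
    background: BackgroundModel,
    motif: TandemMotif,
    config: ScanConfig = ScanConfig(),
    n_sequences: int | None = None,
    tail: str = "poisson",
):
    """Per-bin observed vs analytically expected counts with exact tails.

    Expected count per bin = ``n_sequences`` x sum over start positions in
    the bin, spacer choices and in-scope strands of the per-position match
    probability, with starts near the downstream window edge contributing
    only spacer choices whose match still fits inside the window.  The
    upper-tail p is ``P(X >= observed)`` under Poisson(expected) (or an
    equivalent-mean binomial with ``tail='binomial'``); q-values are
    Benjamini-Hochberg across bins.  Returns a DataFrame.
    """
    import pandas as pd

    n_seq = histogram.n_sequences if n_sequences is None else n_sequences
    if n_seq <= 0:
        raise ValueError("n_sequences must be positive")
    hi_u = linear(histogram.window[1])
    per_spacer = {
        tuple(sp): (
            motif.realized_length(tuple(sp)),
            _strand_probs(motif, tuple(sp), config, background),
        )
        for sp in motif.spacer_choices()
    }
    rows = []
    for (b_lo, b_hi), obs_f, obs_r in zip(
        histogram.bins, histogram.counts_forward, histogram.counts_reverse
    ):
        per_pos = 0.0
        for u in range(linear(b_lo), linear(b_hi) + 1):
            for length, prob in per_spacer.values():
                if u + length - 1 <= hi_u:
                    per_pos += prob
        expected = n_seq * per_pos
        if config.strands == "forward":
            observed = int(obs_f)
        elif config.strands == "reverse":
            observed = int(obs_r)
        else:
            observed = int(obs_f) + int(obs_r)
        if expected <= 0:
            p = 1.0
        elif tail == "poisson":
            p = float(sps.poisson.sf(observed - 1, expected))
        elif tail == "binomial":
            n_trials = max(observed, int(np.ceil(expected)), n_seq)
            p = float(sps.binom.sf(observed - 1, n_trials, expected / n_trials))
        else:
            raise ValueError(f"unknown tail {tail!r}")
        rows.append(
            {
                "bin_low": b_lo,
                "bin_high": b_hi,
                "observed_fwd": int(obs_f),
                "observed_rev": int(obs_r),
                "expected": expected,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test for a 2x2 table.

    Sums, in log space, the hypergeometric probabilities of every table with
    the observed margins whose point probability is at most that of the
    observed table (relative tie tolerance 1e-7).  A zero margin makes the
    table degenerate: p = 1 with a warning.
    """
    if isinstance(table, ContingencyTable):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
    t = ContingencyTable(a, b, c, d)  # validates
    n = a + b + c + d
    r1, k1 = a + b, a + c
    if 0 in (r1, k1, n - r1, n - k1):
        warnings.warn("degenerate 2x2 table (zero margin); p = 1", stacklevel=2)
        return 1.0
    lo, hi = max(0, r1 + k1 - n), min(r1, k1)
    support = np.arange(lo, hi + 1)
    logpmf = sps.hypergeom.logpmf(support, n, k1, r1)
    log_obs = logpmf[a - lo]
    keep = logpmf <= log_obs + np.log1p(1e-7)
    p = float(np.exp(logpmf[keep]).sum())
    return min(p, 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def set_overlap_test(set_a, set_b, universe_size: int):
    """Overlap of two gene sets with a hypergeometric upper-tail p-value.

    ``p = P(X >= |A n B|)`` drawing ``|B|`` genes from a universe of
    ``universe_size`` containing ``|A|`` marked genes.
    """
    sa, sb = set(set_a), set(set_b)
    if universe_size < len(sa | sb):
        raise ValueError("universe smaller than the union of the sets")
    overlap = len(sa & sb)
    p = float(sps.hypergeom.sf(overlap - 1, universe_size, len(sa), len(sb)))
    return overlap, min(p, 1.0)
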