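"""Tandem DNA motifs and strand-aware scanning.

A tandem motif is an ordered list of short fixed flanks (e.g. ``ATC``, ``ATC``)
separated by gaps whose lengths are constrained to ranges but whose base
content is free.  The canonical promoter element handled by this package is
the LTSM, two ATC flanks separated by exactly seven unconstrained base pairs;
the tripartite variant is ATC-8-ATC-6-ATC.  Scanning is strand-aware: a
reverse-strand hit is a match of the motif on the reverse complement, reported
at the leftmost base it covers on the sense sequence.

Masking conventions follow genome-browser practice: lowercase bases are
soft-masked (repeat-derived, sequence preserved), ``N`` is hard-masked.  Under
``ignore_mask`` soft-masked bases compare case-insensitively; under
``skip_masked`` any masked base anywhere in the candidate span suppresses the
hit.  An ``N`` on a flank position always suppresses the hit — a hard-masked
base carries no evidence and may not spend mismatch budget.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TandemMotif",
    "ScanConfig",
    "MotifHit",
    "reverse_complement",
    "match_at",
    "scan_sequence",
    "CANONICAL_LTSM",
    "TRIPARTITE_LTSM",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_RE = re.compile(r"[^ACGTNacgtn]")
_FLANK_RE = re.compile(r"[^ACGT]")


def _check_sequence(seq: str) -> None:
    m = _VALID_RE.search(seq)
    if m is not None:
        raise ValueError(
            f"non-nucleotide character {m.group()!r} at position {m.start()}"
        )


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving case (soft masking) and ``N``.

    Raises ``ValueError`` naming the offending symbol and position for any
    character outside ``ACGTN`` (either case).
    """
    _check_sequence(seq)
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TandemMotif:
    """An ordered set of exact flanks with length-constrained free gaps.

    Parameters
    ----------
    name:
        Short label used in outputs.
    flanks:
        DNA strings over ``ACGT`` (uppercase), at least two.
    spacer_ranges:
        One ``(min_len, max_len)`` pair per gap between consecutive flanks.
    """

    name: str
    flanks: tuple[str, ...]
    spacer_ranges: tuple[tuple[int, int], ...]

    def __init__(self, name, flanks, spacer_ranges):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "flanks", tuple(str(f) for f in flanks))
        object.__setattr__(
            self, "spacer_ranges", tuple((int(a), int(b)) for a, b in spacer_ranges)
        )
        self._validate()

    def _validate(self) -> None:
        if len(self.flanks) < 2:
            raise ValueError("a tandem motif needs at least two flanks")
        if len(self.spacer_ranges) != len(self.flanks) - 1:
            raise ValueError(
                f"{len(self.flanks)} flanks require {len(self.flanks) - 1} "
                f"spacer ranges, got {len(self.spacer_ranges)}"
            )
        for f in self.flanks:
            if not f or _FLANK_RE.search(f):
                raise ValueError(f"flank {f!r} must be non-empty uppercase ACGT")
        for lo, hi in self.spacer_ranges:
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid spacer range ({lo}, {hi})")

    # -- geometry -----------------------------------------------------------

    @property
    def n_flank_bases(self) -> int:
        return sum(len(f) for f in self.flanks)

    def realized_length(self, spacers: tuple[int, ...]) -> int:
        """Total match length for one realized spacer assignment."""
        self._check_spacers(spacers)
        return self.n_flank_bases + sum(spacers)

    @property
    def min_length(self) -> int:
        return self.n_flank_bases + sum(lo for lo, _ in self.spacer_ranges)

    @property
    def max_length(self) -> int:
        return self.n_flank_bases + sum(hi for _, hi in self.spacer_ranges)

    def spacer_choices(self):
        """All realized spacer assignments, lexicographically ascending."""
        return itertools.product(
            *(range(lo, hi + 1) for lo, hi in self.spacer_ranges)
        )

    def flank_offsets(self, spacers: tuple[int, ...]) -> list[int]:
        """Start offset of each flank within a realized match."""
        self._check_spacers(spacers)
        offsets, pos = [], 0
        for i, f in enumerate(self.flanks):
            offsets.append(pos)
            pos += len(f)
            if i < len(spacers):
                pos += spacers[i]
        return offsets

    def flank_positions(self, spacers: tuple[int, ...]):
        """Yield ``(offset_in_match, expected_base)`` over all flank bases."""
        for off, flank in zip(self.flank_offsets(spacers), self.flanks):
            for k, base in enumerate(flank):
                yield off + k, base

    def _check_spacers(self, spacers) -> None:
        if len(spacers) != len(self.spacer_ranges):
            raise ValueError("wrong number of realized spacers")
        for s, (lo, hi) in zip(spacers, self.spacer_ranges):
            if not (lo <= s <= hi):
                raise ValueError(f"spacer {s} outside range ({lo}, {hi})")

    def reverse_complement(self) -> "TandemMotif":
        """The motif as it reads on the opposite strand."""
        return TandemMotif(
            self.name + "_rc",
            tuple(reverse_complement(f) for f in reversed(self.flanks)),
            tuple(reversed(self.spacer_ranges)),
        )


#: ATC-ATC with a fixed 7-bp spacer — the canonical promoter element.
CANONICAL_LTSM = TandemMotif("ltsm", ("ATC", "ATC"), ((7, 7),))

#: ATC-8-ATC-6-ATC — the tripartite variant.
TRIPARTITE_LTSM = TandemMotif("ltsm_tri", ("ATC", "ATC", "ATC"), ((8, 8), (6, 6)))


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``strands`` is one of ``forward``/``reverse``/``both``; mismatches are
    counted over flank positions only; ``position_window`` restricts matches
    to a TSS-relative interval (applied by the promoter-level scan, where the
    TSS is known) with ``containment`` deciding whether the whole match or
    only its start must fall inside.
    """

    strands: str = "both"
    max_mismatch: int = 0
    mask_policy: str = "ignore_mask"
    position_window: tuple[int, int] | None = None
    containment: str = "full"

    def __post_init__(self):
        if self.strands not in ("forward", "reverse", "both"):
            raise ValueError(f"unknown strands {self.strands!r}")
        if self.mask_policy not in ("ignore_mask", "skip_masked"):
            raise ValueError(f"unknown mask_policy {self.mask_policy!r}")
        if self.containment not in ("full", "start_only"):
            raise ValueError(f"unknown containment {self.containment!r}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be non-negative")
        if self.position_window is not None:
            lo, hi = self.position_window
            if lo == 0 or hi == 0:
                raise ValueError("position_window bounds use the no-zero axis")
            if _linear(lo) > _linear(hi):
                raise ValueError("inverted position_window")


def _linear(rel: int) -> int:
    # no-zero TSS-relative axis -> contiguous integers (+1 -> 0, -1 -> -1)
    if rel == 0:
        raise ValueError("0 is not a valid TSS-relative coordinate")
    return rel - 1 if rel > 0 else rel


@dataclass(frozen=True)
class MotifHit:
    """One motif match on a sense-oriented sequence.

    ``start`` is the 0-based index of the leftmost covered base on the sense
    sequence regardless of strand; ``rel_start`` is the TSS-relative
    coordinate of that base when the sequence has a known TSS.
    """

    sequence_id: str
    start: int
    length: int
    strand: str
    spacers: tuple[int, ...]
    mismatches: int
    matched_text: str
    rel_start: int | None = None

    def key(self) -> tuple[int, int, str]:
        return (self.start, self.length, self.strand)


def match_at(
    seq: str,
    pos: int,
    motif: TandemMotif,
    spacer_choice: tuple[int, ...],
    max_mismatch: int = 0,
    mask_policy: str = "ignore_mask",
    sequence_id: str = "",
) -> MotifHit | None:
    """Test a single (position, spacer assignment) on the forward strand.

    Returns a hit iff the flank mismatch count is within budget, or ``None``.
    Spacer bases are unconstrained.
    """
    spacer_choice = tuple(spacer_choice)
    length = motif.realized_length(spacer_choice)
    if pos < 0 or pos + length > len(seq):
        raise ValueError(
            f"position {pos} with match length {length} outside sequence "
            f"of length {len(seq)}"
        )
    span = seq[pos : pos + length]
    if mask_policy == "skip_masked":
        if any(c.islower() or c in "Nn" for c in span):
            return None
    elif mask_policy != "ignore_mask":
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    mismatches = 0
    for off, base in motif.flank_positions(spacer_choice):
        c = span[off].upper()
        if c == "N":
            return None  # hard-masked flank base: no evidence
        if c != base:
            mismatches += 1
            if mismatches > max_mismatch:
                return None
    return MotifHit(
        sequence_id=sequence_id,
        start=pos,
        length=length,
        strand="+",
        spacers=spacer_choice,
        mismatches=mismatches,
        matched_text=span,
    )


def _forward_candidates(seq: str, motif: TandemMotif, config: ScanConfig):
    """Vectorized forward-strand scan: yields (start, length, spacers, mm)."""
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    upper = arr & 0xDF
    is_n = upper == ord("N")
    if config.mask_policy == "skip_masked":
        bad = (arr >= ord("a")) | is_n
        cbad = np.concatenate(([0], np.cumsum(bad)))
    for spacers in motif.spacer_choices():
        length = motif.realized_length(spacers)
        m = n - length + 1
        if m <= 0:
            continue
        mm = np.zeros(m, dtype=np.int32)
        nflag = np.zeros(m, dtype=bool)
        for off, base in motif.flank_positions(spacers):
            mm += upper[off : off + m] != ord(base)
            nflag |= is_n[off : off + m]
        ok = (mm <= config.max_mismatch) & ~nflag
        if config.mask_policy == "skip_masked":
            ok &= (cbad[length:] - cbad[:m]) == 0
        for s in np.nonzero(ok)[0]:
            yield int(s), length, spacers, int(mm[s])


def scan_sequence(
    seq: str,
    motif: TandemMotif,
    config: ScanConfig = ScanConfig(),
    sequence_id: str = "",
) -> list[MotifHit]:
    """Enumerate all motif matches in a sequence.

    Every (start, spacer assignment, strand) triple allowed by ``config`` is
    tested; overlapping and nested matches are all reported, and exact
    duplicates — same (start, length, strand) — are merged keeping the
    lowest mismatch count (earliest spacer assignment on ties).  Output is
    sorted by ascending start, ``+`` before ``-`` at equal start, then
    ascending length.  A sequence shorter than the motif yields an empty
    list.  ``position_window`` is not applied here (no TSS context); see
    :func:`ltsmscan.promoters.scan_promoters`.
    """
    if not seq:
        raise ValueError("empty sequence")
    _check_sequence(seq)
    if config.max_mismatch >= motif.n_flank_bases:
        raise ValueError("max_mismatch must be smaller than the flank base count")

    best: dict[tuple[int, int, str], MotifHit] = {}

    def consider(hit: MotifHit) -> None:
        prev = best.get(hit.key())
        if prev is None or hit.mismatches < prev.mismatches:
            best[hit.key()] = hit

    n = len(seq)
    if config.strands in ("forward", "both"):
        for start, length, spacers, mm in _forward_candidates(seq, motif, config):
            consider(
                MotifHit(sequence_id, start, length, "+", spacers, mm,
                         seq[start : start + length])
            )
    if config.strands in ("reverse", "both"):
        rc = reverse_complement(seq)
        for start_rc, length, spacers, mm in _forward_candidates(rc, motif, config):
            start = n - start_rc - length
            consider(
                MotifHit(sequence_id, start, length, "-", spacers, mm,
                         seq[start : start + length])
            )
    return sorted(
        best.values(), key=lambda h: (h.start, 0 if h.strand == "+" else 1, h.length)
    )
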