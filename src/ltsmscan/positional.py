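"""TSS-relative positional summaries of motif hits.

Hits are localized by their start coordinate — the leftmost covered base on
the sense sequence — on the no-zero TSS-relative axis.  Histogram bins are
anchored at the TSS (``[+1,+20]``, ``[+21,+40]``, ... downstream and
``[-20,-1]``, ``[-40,-21]``, ... upstream for 20-bp bins) so no bin straddles
the TSS.  The preferred-window/orientation classification mirrors how
promoter elements of this kind are reported: oriented with transcription and
concentrated in a short interval downstream of the TSS, ``[+52,+82]`` for the
canonical element.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .coords import linear, window_bins

__all__ = [
    "PositionalHistogram",
    "build_histogram",
    "classify_hits",
    "collapse_to_genes",
    "PREFERRED_WINDOW",
    "read_hit_table",
]

#: TSS-relative interval in which canonical elements concentrate.
PREFERRED_WINDOW: tuple[int, int] = (52, 82)


@dataclass
class PositionalHistogram:
    """Per-strand binned counts of hit start positions relative to the TSS."""

    bin_width: int
    bins: list[tuple[int, int]]
    counts_forward: np.ndarray
    counts_reverse: np.ndarray
    n_sequences: int
    window: tuple[int, int]

    @property
    def total(self) -> int:
        return int(self.counts_forward.sum() + self.counts_reverse.sum())

    def argmax_bin(self, strand: str = "+") -> tuple[int, int]:
        """The bin with the highest count on one strand (first on ties)."""
        counts = self.counts_forward if strand == "+" else self.counts_reverse
        return self.bins[int(np.argmax(counts))]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_low": [b[0] for b in self.bins],
                "bin_high": [b[1] for b in self.bins],
                "count_forward": self.counts_forward,
                "count_reverse": self.counts_reverse,
            }
        )


def _rel_start(hit) -> int:
    if hit.rel_start is None:
        raise ValueError(
            f"hit on {hit.sequence_id!r} has no TSS-relative start; "
            "scan via scan_promoters or set rel_start"
        )
    return hit.rel_start


def build_histogram(
    hits,
    window: tuple[int, int],
    bin_width: int = 20,
    n_sequences: int = 0,
) -> PositionalHistogram:
    """Bin hit start coordinates per strand over a TSS-relative window.

    Hits whose start falls outside the window are not counted, so total
    histogram mass equals the number of in-window hits.
    """
    bins = window_bins(window, bin_width)
    edges_lo = np.array([linear(b[0]) for b in bins])
    edges_hi = np.array([linear(b[1]) for b in bins])
    fwd = np.zeros(len(bins), dtype=int)
    rev = np.zeros(len(bins), dtype=int)
    for hit in hits:
        u = linear(_rel_start(hit))
        idx = np.searchsorted(edges_lo, u, side="right") - 1
        if idx < 0 or u > edges_hi[idx]:
            continue
        (fwd if hit.strand == "+" else rev)[idx] += 1
    return PositionalHistogram(bin_width, bins, fwd, rev, n_sequences, window)


def classify_hits(hits, preferred_window: tuple[int, int] = PREFERRED_WINDOW):
    """Partition hits by orientation and location.

    Categories are exhaustive and mutually exclusive: forward-strand hits
    starting inside ``preferred_window`` (inclusive bounds) are
    ``preferred_forward``, other forward hits ``elsewhere_forward``, and all
    reverse-strand hits ``reverse``.  Returns ``(categories, totals)`` where
    ``categories`` is one label per hit and ``totals`` includes ``total``.
    """
    lo_u, hi_u = linear(preferred_window[0]), linear(preferred_window[1])
    categories = []
    totals = {"total": 0, "preferred_forward": 0, "elsewhere_forward": 0, "reverse": 0}
    for hit in hits:
        if hit.strand == "-":
            cat = "reverse"
        elif lo_u <= linear(_rel_start(hit)) <= hi_u:
            cat = "preferred_forward"
        else:
            cat = "elsewhere_forward"
        categories.append(cat)
        totals[cat] += 1
        totals["total"] += 1
    return categories, totals


def collapse_to_genes(hits, tx2gene: dict):
    """Collapse transcript-level hits to gene-level positivity.

    A gene is positive iff at least one of its transcripts has at least one
    hit.  Returns ``(n_positive_transcripts, n_positive_genes,
    per_gene_hits)``.
    """
    per_gene = defaultdict(list)
    positive_tx = set()
    for hit in hits:
        if hit.sequence_id not in tx2gene:
            raise KeyError(f"transcript {hit.sequence_id!r} has no gene mapping")
        per_gene[tx2gene[hit.sequence_id]].append(hit)
        positive_tx.add(hit.sequence_id)
    return len(positive_tx), len(per_gene), dict(per_gene)


def read_hit_table(path, tss_position: int | None = None):
    """Read a hit table TSV into lightweight hit records.

    Columns ``sequence_id``, ``strand`` and either ``rel_start`` (no-zero
    TSS-relative axis) or ``position`` are required; ``position`` is a
    coordinate on the scanned sequence whose TSS base sits at
    ``tss_position`` (e.g. 500 for a 1000-bp window with 500 bp upstream),
    and strand may be encoded as ``+``/``-`` or ``1``/``-1``.  Lines starting
    with ``#`` are metadata.
    """
    import pandas as pd

    from .motif import MotifHit

    df = pd.read_csv(path, sep="\t", comment="#")
    hits = []
    for _, row in df.iterrows():
        strand = str(row["strand"])
        strand = {"1": "+", "-1": "-"}.get(strand, strand)
        if "rel_start" in df.columns:
            rel = int(row["rel_start"])
        else:
            if tss_position is None:
                raise ValueError("tss_position required with 'position' column")
            p = int(row["position"])
            rel = p - tss_position + 1 if p >= tss_position else p - tss_position
        hits.append(
            MotifHit(
                sequence_id=str(row["sequence_id"]),
                start=int(row.get("start", 0)) if "start" in df.columns else 0,
                length=int(row["length"]) if "length" in df.columns else 0,
                strand=strand,
                spacers=tuple(
                    int(s) for s in str(row["spacers"]).split(",")
                ) if "spacers" in df.columns and not pd.isna(row["spacers"]) else (),
                mismatches=int(row["mismatches"]) if "mismatches" in df.columns else 0,
                matched_text=str(row["matched_text"]) if "matched_text" in df.columns else "",
                rel_start=rel,
            )
        )
    return hits
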