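"""TSS catalogs: representative tags, deduplication, and concordance scoring.

Tag-cluster catalogs (CAGE-style 5'-end sequencing) are reduced to one
representative TSS per cluster — the 5'-most tag.  cDNA-derived catalogs
(DBTSS-style) often record the same genomic TSS several times; deduplication
keeps exactly one record per identical (chrom, coordinate, strand) triple.
Concordance scoring compares candidate TSS annotations per gene against a
reference set by the minimum absolute distance, the analysis used to pick
the annotation source whose TSSs best match experimentally verified ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TSSRecord",
    "cage_representative_tss",
    "dedup_tss",
    "closest_tss_concordance",
    "ConcordanceReport",
]


@dataclass(frozen=True, order=True)
class TSSRecord:
    chrom: str
    coord: int
    strand: str
    record_id: str = ""

    def __post_init__(self):
        if self.coord < 1:
            raise ValueError("TSS coordinates are 1-based (>= 1)")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")


def cage_representative_tss(tags, strand: str, counts=None) -> int:
    """The 5'-most tag of a cluster: min coordinate on '+', max on '-'.

    With per-tag ``counts``, ties among equally 5'-most coordinates are
    broken by the highest tag count, then the lowest coordinate.
    """
    tags = list(tags)
    if not tags:
        raise ValueError("empty tag cluster")
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    if counts is None:
        return min(tags) if strand == "+" else max(tags)
    if len(counts) != len(tags):
        raise ValueError("counts must align with tags")
    # sort 5'-most first, then by descending count, then ascending coordinate
    sign = 1 if strand == "+" else -1
    order = sorted(zip(tags, counts), key=lambda tc: (sign * tc[0], -tc[1], tc[0]))
    return order[0][0]


def dedup_tss(records):
    """Keep one record per identical (chrom, coordinate, strand) triple.

    The kept record is the first in (chrom, coordinate, strand, id) sort
    order; output is sorted and deterministic.  Returns
    ``(unique_records, removed_count)``.
    """
    recs = sorted(records)
    seen = set()
    out = []
    for r in recs:
        key = (r.chrom, r.coord, r.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(r)
    return out, len(recs) - len(out)


@dataclass
class ConcordanceReport:
    """Per-gene closest-candidate distances against a reference TSS set."""

    distances: dict
    mean_distance: float
    coverage: float
    uncovered: list

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"gene_id": list(self.distances), "distance": list(self.distances.values())}
        )


def closest_tss_concordance(reference: dict, candidates: dict, signed: bool = False):
    """Score candidate TSS annotations against a reference, per gene.

    ``reference`` maps gene -> TSS coordinate (int) or ``(chrom, strand,
    coord)``; ``candidates`` maps gene -> list of the same.  For each gene
    with at least one (chrom/strand-compatible) candidate the distance is the
    minimum absolute candidate-reference offset; the mean is over covered
    genes only.  ``signed=True`` reports the signed offset of the closest
    candidate instead.
    """
    if not reference:
        raise ValueError("empty reference")

    def split(v):
        return v if isinstance(v, tuple) else (None, None, v)

    distances, uncovered = {}, []
    for gene, ref in reference.items():
        r_chrom, r_strand, r_pos = split(ref)
        best = None
        for cand in candidates.get(gene, []):
            c_chrom, c_strand, c_pos = split(cand)
            if (r_chrom is not None and c_chrom is not None and c_chrom != r_chrom) or (
                r_strand is not None and c_strand is not None and c_strand != r_strand
            ):
                logger.warning("gene %s: candidate on %s/%s ignored", gene, c_chrom, c_strand)
                continue
            off = c_pos - r_pos
            if best is None or abs(off) < abs(best):
                best = off
        if best is None:
            uncovered.append(gene)
        else:
            distances[gene] = best if signed else abs(best)
    mean = float(np.mean(list(distances.values()))) if distances else float("nan")
    coverage = len(distances) / len(reference)
    return ConcordanceReport(distances, mean, coverage, uncovered)
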