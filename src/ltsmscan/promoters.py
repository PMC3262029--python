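"""Strand-aware extraction of TSS-relative promoter windows.

The genome is any mapping from chromosome name to sequence (a plain dict of
strings, a ``pyfaidx.Fasta``, or a FASTA path).  Annotations supply one TSS
per transcript; windows are expressed on the no-zero TSS-relative axis (see
:mod:`ltsmscan.coords`) and stored sense-oriented, i.e. reverse-complemented
for minus-strand transcripts, with soft (lowercase) and hard (``N``) masking
preserved verbatim.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from pathlib import Path

from .coords import linear, unlinear, window_length
from .motif import MotifHit, ScanConfig, TandemMotif, reverse_complement, scan_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptAnnotation",
    "PromoterRegion",
    "parse_annotation",
    "extract_promoters",
    "rel_to_index",
    "index_to_rel",
    "scan_promoters",
    "hits_to_bed",
    "write_promoters_fasta",
    "read_promoters_fasta",
]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One transcript's TSS: the 1-based genomic coordinate of its first base."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss_genomic: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if self.tss_genomic < 1:
            raise ValueError(f"{self.transcript_id}: TSS must be >= 1 (1-based)")


@dataclass(frozen=True)
class PromoterRegion:
    """A sense-oriented TSS-relative window of one transcript.

    ``sequence`` reads 5'->3' in the direction of transcription; for
    minus-strand transcripts it is the reverse complement of the genomic
    plus-strand slice.  ``tss_scan_index`` is the 0-based index of the TSS
    base (coordinate +1) within ``sequence``.  Genomic provenance fields are
    optional and only needed for BED export.
    """

    transcript_id: str
    gene_id: str
    upstream_rel: int | None
    downstream_rel: int
    sequence: str
    tss_scan_index: int
    chrom: str | None = None
    strand: str | None = None
    tss_genomic: int | None = None

    @property
    def window(self) -> tuple[int, int]:
        return (self.upstream_rel if self.upstream_rel is not None else 1,
                self.downstream_rel)


def rel_to_index(rel: int, region: PromoterRegion) -> int:
    """TSS-relative coordinate -> 0-based index into ``region.sequence``."""
    idx = region.tss_scan_index + linear(rel)
    if not (0 <= idx < len(region.sequence)):
        raise ValueError(f"coordinate {rel:+d} outside window {region.window}")
    return idx


def index_to_rel(idx: int, region: PromoterRegion) -> int:
    """0-based scan index -> TSS-relative coordinate (inverse of rel_to_index)."""
    if not (0 <= idx < len(region.sequence)):
        raise ValueError(f"index {idx} outside sequence of length {len(region.sequence)}")
    return unlinear(idx - region.tss_scan_index)


# ---------------------------------------------------------------------------
# annotation parsing


def parse_annotation(path, format: str) -> list[TranscriptAnnotation]:
    """Read transcript TSSs from BED6, GTF or GFF3.

    For plus-strand features the TSS is the feature start; for minus-strand
    features the feature end.  BED's 0-based half-open coordinates are
    converted to 1-based.  Records without a strand are rejected.
    """
    fmt = format.lower()
    if fmt == "bed":
        return _parse_bed(path)
    if fmt in ("gtf", "gff3", "gff"):
        return _parse_gxf(path, fmt)
    raise ValueError(f"unknown annotation format {format!r}")


def _parse_bed(path) -> list[TranscriptAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 needs 6 columns (strand required), "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            if strand not in "+-":
                raise ValueError(f"{path}:{lineno}: missing/invalid strand {strand!r}")
            tss = start_i + 1 if strand == "+" else end_i
            out.append(TranscriptAnnotation(name, name, chrom, strand, tss))
    return out


def _parse_gxf(path, fmt: str) -> list[TranscriptAnnotation]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    out = []
    for ftype in ("transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            if f.strand not in "+-":
                raise ValueError(f"{path}: feature {f.id} has no strand")
            tid = f.attributes.get("transcript_id", [f.id])[0]
            gid_attr = f.attributes.get("gene_id") or f.attributes.get("Parent") or [tid]
            tss = f.start if f.strand == "+" else f.end
            out.append(TranscriptAnnotation(tid, gid_attr[0], f.seqid, f.strand, tss))
    if not out:
        raise ValueError(f"{path}: no transcript/mRNA features found")
    return out


# ---------------------------------------------------------------------------
# extraction


def _open_genome(genome):
    if isinstance(genome, (str, Path)) and os.path.exists(str(genome)):
        import pyfaidx

        return pyfaidx.Fasta(str(genome))
    return genome


def _contig(genome, chrom: str) -> str:
    try:
        rec = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not found in genome") from None
    return str(rec[:]) if hasattr(rec, "faidx") or not isinstance(rec, str) else rec


def extract_promoters(
    genome,
    annotations,
    upstream_rel: int | None,
    downstream_rel: int,
    clip_policy: str = "drop",
) -> list[PromoterRegion]:
    """Extract sense-oriented windows around each transcript's TSS.

    ``clip_policy`` controls windows overrunning a contig edge: ``drop``
    discards them (logged), ``pad`` fills the overhang with ``N``.
    """
    length = window_length(upstream_rel, downstream_rel)  # validates bounds
    if clip_policy not in ("drop", "pad"):
        raise ValueError(f"unknown clip_policy {clip_policy!r}")
    genome = _open_genome(genome)
    up = -upstream_rel if upstream_rel is not None else 0
    down = downstream_rel
    regions = []
    contig_cache: dict[str, str] = {}
    for ann in annotations:
        contig = contig_cache.get(ann.chrom)
        if contig is None:
            contig = contig_cache[ann.chrom] = _contig(genome, ann.chrom)
        t = ann.tss_genomic
        if ann.strand == "+":
            lo, hi = t - up, t + down - 1  # 1-based inclusive
        else:
            lo, hi = t - down + 1, t + up
        pad_left = max(0, 1 - lo)
        pad_right = max(0, hi - len(contig))
        if pad_left or pad_right:
            if clip_policy == "drop":
                logger.warning(
                    "dropping %s: window %d..%d overruns contig %s (len %d)",
                    ann.transcript_id, lo, hi, ann.chrom, len(contig),
                )
                continue
            slice_ = contig[max(lo, 1) - 1 : min(hi, len(contig))]
            seq = "N" * pad_left + slice_ + "N" * pad_right
        else:
            seq = contig[lo - 1 : hi]
        if ann.strand == "-":
            seq = reverse_complement(seq)
        assert len(seq) == length
        regions.append(
            PromoterRegion(
                transcript_id=ann.transcript_id,
                gene_id=ann.gene_id,
                upstream_rel=upstream_rel,
                downstream_rel=downstream_rel,
                sequence=seq,
                tss_scan_index=up,
                chrom=ann.chrom,
                strand=ann.strand,
                tss_genomic=t,
            )
        )
    return regions


# ---------------------------------------------------------------------------
# promoter-level scanning


def scan_promoters(
    regions,
    motif: TandemMotif,
    config: ScanConfig = ScanConfig(),
) -> list[MotifHit]:
    """Scan each promoter region, attach TSS-relative starts, apply the window.

    With ``config.position_window`` set, ``containment='full'`` keeps matches
    lying entirely inside the window (inclusive) while ``'start_only'`` tests
    only the start coordinate.
    """
    out = []
    win = config.position_window
    if win is not None:
        lo_u, hi_u = linear(win[0]), linear(win[1])
    for region in regions:
        for hit in scan_sequence(region.sequence, motif, config, region.transcript_id):
            rel = index_to_rel(hit.start, region)
            if win is not None:
                start_u = linear(rel)
                if start_u < lo_u:
                    continue
                if config.containment == "full":
                    if start_u + hit.length - 1 > hi_u:
                        continue
                elif start_u > hi_u:
                    continue
            out.append(replace(hit, rel_start=rel))
    return out


# ---------------------------------------------------------------------------
# BED export


def hits_to_bed(hits, regions) -> list[tuple]:
    """Map promoter-relative hits to genomic BED6 records.

    Returns ``(chrom, chromStart, chromEnd, name, score, strand)`` tuples
    with 0-based half-open coordinates.  The BED strand is the genomic strand
    of the matched motif (transcript strand composed with hit strand); name
    is ``sequence_id:motif-span`` and score the mismatch count.  Regions must
    carry genomic provenance.
    """
    by_id = {r.transcript_id: r for r in regions}
    records = []
    for hit in hits:
        region = by_id.get(hit.sequence_id)
        if region is None or region.chrom is None or region.tss_genomic is None:
            raise ValueError(f"hit {hit.sequence_id} lacks genomic provenance")
        t, k = region.tss_genomic, region.tss_scan_index
        if region.strand == "+":
            g_lo = t - k + hit.start  # 1-based
            g_hi = g_lo + hit.length - 1
        else:
            g_hi = t + k - hit.start
            g_lo = g_hi - hit.length + 1
        genomic_strand = "+" if region.strand == hit.strand else "-"
        records.append(
            (
                region.chrom,
                g_lo - 1,
                g_hi,
                f"{hit.sequence_id}:{hit.start}-{hit.start + hit.length}",
                hit.mismatches,
                genomic_strand,
            )
        )
    return records


# ---------------------------------------------------------------------------
# promoter-set FASTA round trip


def _window_str(region: PromoterRegion) -> str:
    lo = region.upstream_rel if region.upstream_rel is not None else 1
    return f"{lo:+d}..{region.downstream_rel:+d}"


def write_promoters_fasta(regions, fasta_path, sidecar_path=None) -> None:
    """Write a promoter set as FASTA (``>tx|gene|window=-500..+500``) plus an
    optional provenance sidecar TSV."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.transcript_id}|{r.gene_id}|window={_window_str(r)}",
            description="",
        )
        for r in regions
    ]
    seqio_write(recs, str(fasta_path), "fasta")
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            fh.write("transcript_id\tgene_id\tchrom\tstrand\ttss_genomic\n")
            for r in regions:
                fh.write(
                    f"{r.transcript_id}\t{r.gene_id}\t{r.chrom or '.'}\t"
                    f"{r.strand or '.'}\t{r.tss_genomic if r.tss_genomic else '.'}\n"
                )


def read_promoters_fasta(fasta_path, sidecar_path=None) -> list[PromoterRegion]:
    """Read a promoter set written by :func:`write_promoters_fasta`.

    Plain FASTA without the pipe-delimited header is accepted; such records
    are treated as windows starting at the TSS (+1..+len).
    """
    from Bio.SeqIO import parse as seqio_parse

    prov = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                prov[row["transcript_id"]] = row
    regions = []
    for rec in seqio_parse(str(fasta_path), "fasta"):
        seq = str(rec.seq)
        parts = rec.id.split("|")
        if len(parts) >= 3 and parts[2].startswith("window="):
            tid, gid = parts[0], parts[1]
            lo_s, hi_s = parts[2][len("window=") :].split("..")
            lo, hi = int(lo_s), int(hi_s)
            upstream = lo if lo < 0 else None
        else:
            tid = gid = parts[0]
            upstream, hi = None, len(seq)
        p = prov.get(tid, {})
        tssg = p.get("tss_genomic", ".")
        regions.append(
            PromoterRegion(
                transcript_id=tid,
                gene_id=gid,
                upstream_rel=upstream,
                downstream_rel=hi,
                sequence=seq,
                tss_scan_index=-upstream if upstream is not None else 0,
                chrom=None if p.get("chrom", ".") == "." else p["chrom"],
                strand=None if p.get("strand", ".") == "." else p["strand"],
                tss_genomic=None if tssg == "." else int(tssg),
            )
        )
    return regions
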