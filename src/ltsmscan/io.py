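"""Tab-separated interchange files with a '#'-prefixed provenance header.

Every TSV written by the pipeline starts with comment lines recording the
tool version and a SHA-256 hash of the run configuration, so an output can
be matched to the exact parameters that produced it.  No timestamps are
written: re-running an identical configuration reproduces files
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json

import pandas as pd

from . import __version__

__all__ = ["config_hash", "write_tsv", "read_tsv", "write_hits_tsv", "read_meta"]


def config_hash(config: dict) -> str:
    """SHA-256 over a canonical JSON rendering of the configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# ltsmscan_version={__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}={value}")
    return lines


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_meta(path) -> dict:
    """Parse the '#'-prefixed key=value header block of a pipeline TSV."""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, value = body.split("=", 1)
                meta[key.strip()] = value.strip()
    return meta


def hits_frame(hits) -> pd.DataFrame:
    rows = [
        {
            "sequence_id": h.sequence_id,
            "rel_start": h.rel_start if h.rel_start is not None else "",
            "start": h.start,
            "length": h.length,
            "strand": h.strand,
            "spacers": ",".join(map(str, h.spacers)),
            "mismatches": h.mismatches,
            "matched_text": h.matched_text,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "rel_start", "start", "length",
            "strand", "spacers", "mismatches", "matched_text",
        ],
    )


def write_hits_tsv(hits, path, meta: dict | None = None) -> None:
    write_tsv(hits_frame(hits), path, meta)
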