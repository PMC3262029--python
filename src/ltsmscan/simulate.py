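"""Synthetic promoter sets with planted motifs and known ground truth.

The generator emulates TSS-relative promoter windows: background bases are
drawn i.i.d. or from a first-order Markov chain, and a chosen fraction of
promoters receives one motif instance planted at a controlled TSS-relative
position and strand.  Planting overwrites bases (window lengths stay exact,
so positional coordinates remain valid); flanks are written exactly and
spacer bases are sampled from the background so planted instances do not
distort composition estimates.  A single root seed governs everything, with
per-promoter sub-streams so any subset of promoters is reproducible on its
own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coords import linear, window_length
from .motif import CANONICAL_LTSM, TandemMotif, reverse_complement
from .promoters import PromoterRegion
from .stats import BackgroundModel

__all__ = ["SyntheticSpec", "generate_promoters", "plant_masked_repeats"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic promoter set.

    ``plant_position`` is a single TSS-relative start coordinate (no-zero
    axis, default +62 — where the canonical element sits in ribosomal
    protein promoters) or a ``{position: probability}`` distribution;
    ``plant_strand`` likewise over ``+``/``-``.  ``transcripts_per_gene``
    groups consecutive promoters into genes for collapse tests.
    """

    n_promoters: int
    window: tuple[int | None, int] = (-500, 500)
    background: BackgroundModel = field(default_factory=BackgroundModel.uniform)
    plant_fraction: float = 0.0
    plant_position: int | dict = 62
    plant_strand: dict = field(default_factory=lambda: {"+": 1.0})
    motif: TandemMotif = CANONICAL_LTSM
    transcripts_per_gene: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_promoters < 1:
            raise ValueError("n_promoters must be >= 1")
        if not (0.0 <= self.plant_fraction <= 1.0):
            raise ValueError("plant_fraction must lie in [0, 1]")
        if abs(sum(self.plant_strand.values()) - 1.0) > 1e-9:
            raise ValueError("plant_strand probabilities must sum to 1")
        if isinstance(self.plant_position, dict):
            if abs(sum(self.plant_position.values()) - 1.0) > 1e-9:
                raise ValueError("plant_position probabilities must sum to 1")
        self.length = window_length(*self.window)
        self.tss_scan_index = -self.window[0] if self.window[0] is not None else 0
        # every supported plant position must fit the longest realization
        for rel in self._position_support():
            idx = self.tss_scan_index + linear(rel)
            if idx < 0 or idx + self.motif.max_length > self.length:
                raise ValueError(
                    f"planted motif at {rel:+d} does not fit window {self.window}"
                )

    def _position_support(self):
        if isinstance(self.plant_position, dict):
            return list(self.plant_position)
        return [self.plant_position]

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticSpec":
        kwargs = dict(raw)
        if "window" in kwargs:
            lo, hi = kwargs["window"]
            kwargs["window"] = (lo if lo is not None else None, hi)
        bg = kwargs.get("background")
        if isinstance(bg, dict):
            if "gc" in bg:
                kwargs["background"] = BackgroundModel.from_gc(float(bg["gc"]))
            else:
                kwargs["background"] = BackgroundModel(
                    bg.get("order", 0),
                    tuple(bg["base_freqs"]),
                    tuple(map(tuple, bg["transition"])) if "transition" in bg else None,
                )
        m = kwargs.get("motif")
        if isinstance(m, dict):
            kwargs["motif"] = TandemMotif(
                m.get("name", "motif"),
                tuple(m["flanks"]),
                tuple((int(a), int(b)) for a, b in m["spacers"]),
            )
        return cls(**kwargs)


def _sample_sequence(rng, length: int, bg: BackgroundModel) -> np.ndarray:
    if bg.order == 0:
        cum = np.cumsum(bg.base_freqs)
        idx = np.searchsorted(cum, rng.random(length), side="right")
        return _BASES[np.minimum(idx, 3)].copy()
    cum_t = np.cumsum(np.asarray(bg.transition, dtype=float), axis=1)
    cum_0 = np.cumsum(bg.base_freqs)
    u = rng.random(length)
    out = np.empty(length, dtype=np.uint8)
    state = int(np.searchsorted(cum_0, u[0], side="right").clip(max=3))
    out[0] = _BASES[state]
    for i in range(1, length):
        state = int(min(np.searchsorted(cum_t[state], u[i], side="right"), 3))
        out[i] = _BASES[state]
    return out


def _draw(rng, dist: dict):
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs))]


def generate_promoters(spec: SyntheticSpec):
    """Generate a promoter set and its truth table.

    Returns ``(regions, truth)`` where ``truth`` is a DataFrame with one row
    per promoter: ``promoter_id, gene_id, planted, position, strand,
    spacers``.  Fully reproducible from ``spec.seed``.
    """
    import pandas as pd

    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_promoters + 1)
    global_rng = np.random.default_rng(children[-1])

    n_plant = int(round(spec.plant_fraction * spec.n_promoters))
    planted_idx = set(
        int(i) for i in global_rng.permutation(spec.n_promoters)[:n_plant]
    )

    regions, rows = [], []
    for i in range(spec.n_promoters):
        rng = np.random.default_rng(children[i])
        arr = _sample_sequence(rng, spec.length, spec.background)
        tid = f"T{i:05d}"
        gid = f"G{i // spec.transcripts_per_gene:05d}"
        planted = i in planted_idx
        pos = strand = spacers = None
        if planted:
            if isinstance(spec.plant_position, dict):
                pos = int(_draw(rng, spec.plant_position))
            else:
                pos = int(spec.plant_position)
            strand = _draw(rng, spec.plant_strand)
            spacers = tuple(
                int(rng.integers(lo, hi + 1)) for lo, hi in spec.motif.spacer_ranges
            )
            instance = _build_instance(rng, spec.motif, spacers, spec.background)
            if strand == "-":
                instance = reverse_complement(instance)
            idx = spec.tss_scan_index + linear(pos)
            arr[idx : idx + len(instance)] = np.frombuffer(
                instance.encode("ascii"), dtype=np.uint8
            )
        regions.append(
            PromoterRegion(
                transcript_id=tid,
                gene_id=gid,
                upstream_rel=spec.window[0],
                downstream_rel=spec.window[1],
                sequence=arr.tobytes().decode("ascii"),
                tss_scan_index=spec.tss_scan_index,
            )
        )
        rows.append(
            {
                "promoter_id": tid,
                "gene_id": gid,
                "planted": planted,
                "position": pos if planted else pd.NA,
                "strand": strand if planted else pd.NA,
                "spacers": ",".join(map(str, spacers)) if planted else pd.NA,
            }
        )
    return regions, pd.DataFrame(rows)


def _build_instance(rng, motif: TandemMotif, spacers, bg: BackgroundModel) -> str:
    parts = []
    for i, flank in enumerate(motif.flanks):
        parts.append(flank)
        if i < len(spacers):
            parts.append(_sample_sequence(rng, spacers[i], bg).tobytes().decode())
    return "".join(parts)


def plant_masked_repeats(
    regions,
    seed: int = 0,
    n_segments: int = 1,
    segment_length: int = 50,
    mask_fraction: float | None = None,
):
    """Lowercase random stretches to emulate soft repeat masking.

    Either a fixed count/length of stretches per sequence, or — with
    ``mask_fraction`` — enough fixed-length stretches for roughly that
    fraction of each sequence.  Sequence content is unchanged.  Returns
    ``(masked_regions, mask_truth)`` with truth rows
    ``(promoter_id, start, end)`` as 0-based half-open scan intervals.
    """
    import pandas as pd
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    out, rows = [], []
    for region in regions:
        n = len(region.sequence)
        if segment_length >= n:
            raise ValueError("segment_length must be shorter than the sequence")
        k = n_segments
        if mask_fraction is not None:
            k = int(round(mask_fraction * n / segment_length))
        seq = list(region.sequence)
        for _ in range(k):
            start = int(rng.integers(0, n - segment_length + 1))
            end = start + segment_length
            seq[start:end] = [c.lower() for c in seq[start:end]]
            rows.append({"promoter_id": region.transcript_id, "start": start, "end": end})
        out.append(replace(region, sequence="".join(seq)))
    return out, pd.DataFrame(rows, columns=["promoter_id", "start", "end"])
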