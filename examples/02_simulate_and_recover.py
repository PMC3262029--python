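"""Plant motifs in synthetic promoters and recover them by scanning.

Generates 200 uniform-background kilobase promoters (-500..+500 around the
TSS) each carrying one canonical element planted at +62 on the forward
strand, scans them, and checks position, orientation and the histogram
peak against the generator's truth table.
"""

from ltsmscan import (
    CANONICAL_LTSM,
    ScanConfig,
    SyntheticSpec,
    build_histogram,
    classify_hits,
    generate_promoters,
    scan_promoters,
)

spec = SyntheticSpec(n_promoters=200, plant_fraction=1.0, plant_position=62,
                     seed=42)
regions, truth = generate_promoters(spec)
hits = scan_promoters(regions, CANONICAL_LTSM, ScanConfig(strands="both"))

recovered = {h.sequence_id for h in hits if h.rel_start == 62 and h.strand == "+"}
print(f"planted: {int(truth.planted.sum())}, recovered at +62 forward: "
      f"{len(recovered)}")

_, totals = classify_hits(hits)
print(f"classification: {totals}")

hist = build_histogram(hits, window=(-500, 500), n_sequences=len(regions))
peak = hist.argmax_bin("+")
print(f"forward histogram peak: bin [{peak[0]:+d},{peak[1]:+d}]")

# recovery is 200/200 by construction (exact scanning finds every planted
# instance); the handful of hits beyond the planted ones are chance matches
# at the uniform-background rate, and the peak bin [+61,+80] contains the
# planting position.
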