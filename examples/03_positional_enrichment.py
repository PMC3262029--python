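"""Test TSS-relative positional enrichment against the analytic background.

Simulates 5,000 promoters where 4% carry an element planted at +62, bins
hit starts in 20-bp bins, and compares each bin's count with the analytic
expectation under the background model (Poisson upper tail, BH-corrected
across bins).  Only the bin containing the planted position should be
significant.
"""

from ltsmscan import (
    CANONICAL_LTSM,
    BackgroundModel,
    ScanConfig,
    SyntheticSpec,
    bin_enrichment,
    build_histogram,
    generate_promoters,
    scan_promoters,
)

spec = SyntheticSpec(n_promoters=5000, plant_fraction=0.04, plant_position=62,
                     seed=7)
regions, truth = generate_promoters(spec)
config = ScanConfig(strands="forward")
hits = scan_promoters(regions, CANONICAL_LTSM, config)
hist = build_histogram(hits, window=(-500, 500), n_sequences=5000)

report = bin_enrichment(hist, BackgroundModel.uniform(), CANONICAL_LTSM, config)
significant = report[report.q < 0.05]

print(f"{len(hits)} forward hits in 5,000 promoters "
      f"({int(truth.planted.sum())} planted at +62)")
print("bins with BH-corrected q < 0.05:")
for row in significant.itertuples():
    print(f"  [{row.bin_low:+d},{row.bin_high:+d}]  observed {row.observed_fwd}"
          f"  expected {row.expected:.1f}  q = {row.q:.3g}")

# the [+61,+80] bin holds the ~200 planted instances on top of ~24 expected
# chance hits; every other bin stays at the background rate, so the
# correction leaves exactly one significant bin.
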