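# Methods

## The motif model

`ltsmscan` searches for *localized tandem sequence motifs*: ordered sets of
short exact DNA flanks separated by gaps whose lengths are constrained but
whose base content is free.  The canonical element — called the LTSM in the
regulatory-genomics literature — is two `ATC` flanks separated by exactly
seven unconstrained base pairs, 13 bp in total.  The first and second `T`
then sit 10 bp apart, about one turn of the B-DNA double helix, which is
why the two flanks present on the same helical face.  The tripartite
variant, `ATC-8-ATC-6-ATC`, is expressed in the same model as three flanks
with gap ranges `(8,8)` and `(6,6)`; bipartite variant-spacer searches
(6- or 8-bp gaps) are the same model with a different range.

The spacer is deliberately unconstrained: in promoters of different
GC content the bases between the flanks track the local genomic
background rather than any fixed consensus, so constraining them would
build composition bias into the scanner.  Consequently:

- **Mismatches are counted on flank positions only** (spacer bases are
  wildcards).  `max_mismatch` must stay below the total flank base count.
- **`N` never matches a flank base**, even when mismatch budget remains.  A
  hard-masked base carries no evidence, and letting it spend budget would
  make every `N`-containing window a near-match.  An `N` confined to the
  spacer is acceptable under `ignore_mask`.
- **Soft masking** (lowercase) is a switch: `ignore_mask` compares
  case-insensitively (a scan of the raw genome), `skip_masked` suppresses
  any candidate whose span touches a masked base (a scan of the
  repeat-masked genome).  The two policies reproduce the
  with/without-repeat-masking contrast as a configuration flag on
  identical input.

Scanning enumerates every (start, spacer assignment, strand) triple.
Reverse-strand hits are found by scanning the reverse complement and are
reported at the leftmost sense-strand base they cover, so both
orientations share one coordinate axis.  All overlapping and nested
matches are reported — a tripartite region must remain discoverable by its
two bipartite sub-scans — and only exact `(start, length, strand)`
duplicates are merged (keeping the lowest mismatch count, earliest spacer
assignment on ties; such duplicates require a flank whose prefix
reappears, impossible for `ATC/ATC` motifs but handled deterministically
for arbitrary ones).  The scan core is a vectorized per-offset byte
comparison; its contract is fixed by equality with a brute-force
all-candidates oracle, which the test suite enforces on random sequences
of both uniform and GC-skewed composition, with and without masking.

## Coordinates

TSS-relative positions use the no-zero convention standard in promoter
annotation: `+1` is the TSS base itself, `-1` the base immediately
upstream, increasing in the direction of transcription.  A `-500..+500`
window is therefore exactly 1000 bp with the TSS at 0-based index 500, and
`+1..+200` is 200 bp with the TSS at index 0.  Histogram bins are anchored
at the TSS (`[+1,+20]`, `[+21,+40]`, … downstream; `[-20,-1]`, `[-40,-21]`,
… upstream) so no bin straddles it and the named 20-bp bins of the
positional analysis exist exactly.

Minus-strand promoters are stored as the reverse complement of the genomic
plus-strand slice, so index 0 is always the most-upstream sense base.  BED
export inverts this mapping; its correctness is pinned by a re-extraction
round trip (exported interval → genomic slice → strand-oriented sequence =
matched text).

Three conventions were genuinely open and are fixed as follows:

- **Hits are localized by their start** (leftmost covered base), and the
  preferred window `[+52,+82]` is tested against the start with inclusive
  bounds.  An element whose canonical start is ~+62 is comfortably inside
  under any anchoring, but edge cases differ; the choice is recorded in
  output metadata (`anchor=start_inclusive`).
- **Genome-wide window scans (`+21..+100`) require full containment** of
  the match by default (`containment=full`, i.e. a 13-mer must start by
  +88); `start_only` is available as configuration.
- **Variant-spacer scans default to `max_mismatch=0`.**  Degenerate
  (1-mismatch) search is supported but off by default, since it is known
  to flood results with matches of no preferred location or orientation.

## Promoter extraction

Windows overrunning a contig edge are dropped (with a logged reason)
rather than N-padded by default: padding would deflate per-bin expectations
near the window edges.  `pad` is available where a fixed-size matrix
matters more than calibration.  Transcript-level windows are the primary
object; gene-level statements are made by collapsing transcript hits
through a transcript→gene map (a gene is positive iff any transcript is),
because alternative transcripts of one gene frequently share the same
element.  A `most_upstream` gene-TSS policy is deliberately not the
default: closest-transcript TSSs are known to track verified promoters far
better than most-5' gene annotations.

## Background model and enrichment

The background is an i.i.d. (order 0) or first-order Markov base model,
estimated by maximum likelihood with pseudo-count 1 per symbol or
transition (`N` always excluded; lowercase excluded under `skip_masked`).
The probability of an exact match at one position is the product of
background probabilities over flank bases (order 0), or for order 1 the
stationary probability of the first base times within-flank transition
products times `(s+1)`-step transition probabilities bridging each free
spacer of length `s` (an exact path summation, not an approximation).
Reverse-strand probabilities are computed on the complementary flank
content, so C/G- or A/T-skewed backgrounds correctly give asymmetric
strand expectations.

Per-bin expected counts sum the per-position probability over every start
in the bin, every spacer choice, and every in-scope strand, truncating
spacer choices whose match would overrun the scanned window (the last bins
of a window therefore have proportionally smaller expectations).  The
upper-tail p-value is Poisson, `P(X ≥ obs)` at the analytic mean: per-bin
expectations are small relative to the thousands of scanned positions per
promoter, which is the Poisson limit of the exact binomial; an
equivalent-mean binomial tail is available behind `tail="binomial"`.
Because Poisson p-values are discrete they are conservative near the null,
which matters only for very small expected counts.  Correction across bins
is Benjamini–Hochberg (step-up), delegated to
`statsmodels.stats.multitest` and pinned by a literal step-up reference in
the tests; q ≤ 0.05 is the reporting threshold.

Fisher's exact two-sided test is computed in log space over the full
hypergeometric support, summing all tables with the observed margins whose
point probability is at most the observed table's.  Tie detection uses a
relative tolerance of 1e-7 because floating-point log-probabilities of
exactly tied tables differ at machine precision, and tie handling is the
one place exact-test implementations disagree.  The implementation is
verified against exact rational-arithmetic enumeration (to 1e-10 over all
tables with margins ≤ 25) and cross-checked against `scipy.stats.
fisher_exact`.  Gene-set overlap uses the hypergeometric upper tail.

## TSS catalogs

Tag-cluster catalogs (CAGE-style) are reduced to the 5'-most tag per
cluster (minimum coordinate on `+`, maximum on `-`; tag counts break ties
among duplicated extreme coordinates).  cDNA-derived catalogs (DBTSS-style)
are deduplicated by identical `(chrom, coordinate, strand)` triple —
"overlapping" is read strictly as identical, and the kept record is the
first in sorted order rather than an arbitrary one, for reproducibility.
Concordance between a candidate annotation and a reference TSS set is the
per-gene minimum absolute distance, averaged over covered genes; unsigned
distances are the headline number, signed offsets sit behind a flag.

## The synthetic generator

`SyntheticSpec`/`generate_promoters` emulate exactly what the scanner
consumes: fixed-length TSS-relative windows of background sequence with
motif instances planted at controlled positions, strands and spacer
lengths, plus optional lowercase mask segments.  Defaults mirror the
canonical study conditions: a `-500..+500` window, uniform background,
planting at `+62` on the forward strand.  Planting overwrites rather than
inserts (coordinates stay valid), flanks are written exactly, and spacer
fill is drawn from the background so planted sets keep the background
composition.  One root seed drives a `SeedSequence` tree with one
sub-stream per promoter, so any subset of promoters is bit-reproducible.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: realistic repeat families (mask segments are
uniformly placed), promoter GC gradients and CpG islands, TSS annotation
error, correlated composition between promoters of one gene family, and
alternative-TSS structure beyond a simple transcripts-per-gene grouping.
Recovery and calibration results on synthetic sets validate the machinery,
not the biology.

## Problem sizes and numerical choices

The validation suite uses 500 random kilobase sequences for
scanner-vs-oracle equivalence, 20,000 kilobase promoters for null
calibration (forward-strand hit total within 4 binomial SDs of
`20,000 × 988 × 4⁻⁶ ≈ 4,824`; KS uniformity of per-bin p-values), 200
planted promoters for recovery, and exhaustive enumeration up to margin 25
for the exact tests — sizes at which every check is stable and the whole
suite runs in a few minutes on one core.  Tolerances: 1e-10 against exact
rational oracles (float64 summation error is ~1e-15 at these support
sizes), 1e-12 for BH against the literal reference, 3–4 Monte-Carlo SDs
for simulation consistency.  Degenerate inputs are defined rather than
left to chance: empty scan input is an error, a sequence shorter than the
motif yields an empty hit list, a zero-margin 2×2 table returns p = 1 with
a warning, an empty p-vector adjusts to itself, and an infeasible plant
position fails before any output is written.

## Known limitations

- Order-2+ background models are out of scope; promoter composition
  heterogeneity beyond first-order structure is not captured.
- The scanner's flanks are exact strings; IUPAC degeneracy and PWM scoring
  are out of scope (mismatch counting is the only relaxation).
- Poisson tails assume independent starts; self-overlapping motif
  geometries induce mild positive correlation between nearby positions,
  so per-bin variance is slightly underestimated for such motifs.
- Gene-level collapse trusts the provided transcript→gene map; no
  alternative-promoter inference is attempted.
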