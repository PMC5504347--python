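# Methods

This note records the model underlying each stage, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
and design decisions a maintainer would otherwise have to reverse-engineer.

## Reference model

All analyses run in transcript space: the reference universe is an explicit
set of mature sequences — mRNAs with 5′UTR/CDS/3′UTR boundaries, tRNA gene
bodies with a per-position cloverleaf element table, rRNA species — rather
than a genome. PAR-CLIP reads of a ribosome-associated protein are sense to
the bound RNA and positional along these molecules, so transcript
coordinates (1-based, inclusive) are the natural frame and reverse-strand or
spliced alignment is deliberately out of scope. Structural elements of tRNAs
are *asserted* in an input table (one code letter per position), not
predicted by folding: the analyses consume element identity, and folding
inference would add a model dependency without changing any downstream
quantity. Sequences are normalized to the DNA alphabet (U→T, upcased) at
load; codon arguments likewise accept RNA letters.

## Alignment and transition classes

Reads are placed at every offset of every reference and all placements with
the minimal Hamming distance ≤ 2 substitutions are kept. The implementation
seeds candidates with three disjoint exact 5-mers (a read with ≤ 2
mismatches must contain at least one intact seed, by pigeonhole) and
verifies candidates with vectorized comparisons; reads shorter than 15 nt or
containing N fall back to the full scan, so the result is always identical
to the brute-force definition — the test suite asserts exact hit-set
equality against an independently coded exhaustive oracle. N never matches
(it counts as a mismatch on either side).

A placement's transition class is the cross-link diagnostic: d0, d1TC
(exactly one reference-T → read-C), d1other, d2. When equally good
placements disagree on class the read is flagged ambiguous; it still counts
for composition but is excluded from the positional analyses, the
conservative choice for per-analysis extractions. Per-analysis filters: mRNA
and tRNA analyses keep d1TC reads ≥ 20 nt; the rRNA profile keeps
d0/d1TC/d1other reads ≥ 15 nt; composition keeps every mapped read ≥ 15 nt
(the global floor, the smallest length any analysis admits). d2 reads are a
single class and never contribute conversion positions.

Duplicate sequences are collapsed before alignment purely as an
optimization; copy numbers are carried through, and all downstream counters
weight by copies by default (`use_copies=False` switches every counter to
collapsed counting). Read-level weighting is the default because the
quantities of interest — class mixtures, enrichment factors — are defined on
reads, and distinct-sequence counts saturate for the highly stereotyped
32-nt tRNA reads, which would compress any true enrichment toward 1.

## Category and region assignment

A read whose best placements span several categories is resolved by priority
(default rRNA > tRNA > mRNA > other, the cellular-abundance order; any
consistent policy reproduces the per-category analyses since each analysis
extracts one category). Within the winning category one placement is drawn
reproducibly under the run seed. mRNA reads are assigned the region
containing their conversion position when they have one — the cross-link
site is the closest proxy for the protein contact — else the read midpoint
(floor of (start+end)/2). Boundaries: position ≤ utr5_len → 5′UTR,
≤ utr5_len+cds_len → CDS, else 3′UTR.

## Metagene

Each ranked transcript's per-nucleotide coverage is averaged into 10/60/20
bins over its 5′UTR/CDS/3′UTR. Binning uses fractional nucleotide–bin
overlap: a nucleotide contributes to each bin proportionally to the overlap
of its unit interval with the bin's real-valued span, so
Σ(bin value × span width) equals the region's total coverage exactly and
regions whose lengths do not divide the bin count are binned without bias
(nearest-bin rounding would alias short UTRs). Transcripts are ranked by
their d1TC read count (not summed coverage); the default keeps the top 2000,
with the alternative figure-style cutoff of 3000 available — both values
circulate for this analysis and the discrepancy is exposed rather than
resolved. Rows are normalized to sum 1 (row-max normalization is a display
alternative; row-sum is used because it makes rows comparable as
distributions). The aggregate is the per-bin mean of unnormalized bin
values, reported as log10(mean + 1) and as percent of the aggregate total.

## tRNA analyses

**Positional profile.** Read footprints are accumulated per gene, binned
(fractional overlap) over the gene's normalized [0,1] length in 10 bins by
default (the bin count for this display is conventional, not derived), and
normalized to sum 1. Five-prime-half-restricted libraries put ≥ 99 % of mass
in the 5′ bins.

**Conversion map.** Per position: coverage, conversion count, and ratio =
conversions/coverage (NA at zero coverage). Two denominators choices matter
and are deliberate:

1. Coverage counts d0 + d1TC reads only. A sequencing error on a *converted*
   read demotes it to d2 and censors it from the numerator, so keeping
   errored *unconverted* reads (d1other) in the denominator would bias the
   ratio low by a factor (1 − P(error on read)). With the symmetric
   exclusion the per-site ratio is an unbiased estimator of the conversion
   probability.
2. Element summaries average the ratio over reference-T positions with
   coverage only. Non-T positions cannot carry the 4SU diagnostic, so
   including them would dilute every element mean by its base composition.

**Enrichment.** Counts compare the cross-linked library (d1TC ≥ 20 nt reads)
against a total-cellular tRNA background (all mapped reads). A read is
gene-unique when every best placement lies in one gene; the family rollup
counts reads whose placements stay within one anticodon family (both levels
are reported because "unique to" a tRNA species can be read either way).
Normalization is trimmed-mean-of-M-values: per-gene M = log₂ ratio of
library proportions and A = average log₂ proportion on genes positive in
both libraries; 30 % of M extremes and 5 % of A extremes trimmed from each
tail (rank-based, midrank ties); factor = 2^(precision-weighted mean M) with
inverse delta-method variance weights, against the background library as
reference (it is the abundance baseline); factors rescaled to geometric mean
1. Significance is a two-sided Fisher exact test on the raw integer counts
with library totals as margins, BH-adjusted, flagged at q < 0.05 with
positive adjusted fold-change; TMM enters only the reported fold-change,
log₂[(c₁/(N₁f₁))/(c₂/(N₂f₂))], because the exact test requires integers —
this is one consistent composition of the two tools and it is stated rather
than hidden. Zero counts receive a 0.5 continuity pseudocount in the
fold-change only; significance never rests on the pseudocount. Features
absent from both libraries are NA and excluded from the BH test count.
Features are stratified at the cumulative top 85 % of background abundance.
A method-of-moments common-dispersion diagnostic is provided for replicate
count matrices; it reports overdispersion but does not gate significance —
negative-binomial exact testing with dispersion shrinkage is out of scope.

Note on the BH step-up: adjusted q-values are *not* idempotent
(q = BH((0.01, 0.5)) = (0.02, 0.5) but BH(q) = (0.04, 0.5)); the adjusted
values must therefore never be re-adjusted downstream. A test documents
this.

Because the Fisher test runs on raw proportions, planted enrichment of some
families mechanically depresses the raw proportions of all others, which can
make unenriched features "significant" with small positive TMM-adjusted
fold-changes at very high depth. This is a property of the stated
test/normalization composition, visible in the significance flags, and is
why fold-changes — not flag counts — are the recovery surface.

## rRNA profile

Footprint coverage (not read starts) per species and position, split by
class. Hotspots: positions ≥ 25 % of the species maximum form runs; runs
separated by ≤ 5 nt merge; runs < 10 nt wide are dropped; intervals are
1-based inclusive. The rule is explicit and all three parameters are exposed
because published contact intervals come without a calling rule; the
defaults reproduce rectangular-block geometry exactly and recover planted
Gaussian hotspots at desk-scale depth.

## Codon census

Maximal in-frame runs of a codon (or codon set) in CDS frame 0, counted once
at their full length — a (AAA)₃ run is one run of 3, not two overlapping
runs of 2. The alternative sliding-window convention (a k-run contributes
k−j+1 windows at each j) is available behind `mode="sliding"` since counting
conventions differ between reports. Trailing partial codons are trimmed with
a warning, and the census is invariant under appending 1–2 nucleotides.
Reporter spacers ((ACU AGC)₆, (AAA)₁₂, (AAG)₁₂, (AGA)₁₂) are emitted with a
translation check and serve as census fixtures. The toolkit does not bundle
a human CDS set: genome-scale census numbers depend on the annotation
version, so they are treated as inputs, not constants.

## Simulator

The generator emulates the *statistical* signature of a 4SU PAR-CLIP
library, with defaults fixed at the study conditions:

- class mixture tRNA:mRNA:rRNA = 4/7 : 2/7 : 1/7 (≈ 4:2:1);
- tRNA reads start at position 1 and span 32 nt (the 5′-half signature;
  optional start jitter), with the contact drawn from D-loop uridines in the
  footprint and any footprint T as fallback;
- mRNA reads (20–40 nt) anchor uniformly within a region drawn at weights
  (0.1, 0.8, 0.1) for 5′UTR/CDS/3′UTR — CDS-dominant cross-linking, as
  expected for a ribosome-riding protein;
- rRNA reads place their footprint centers at per-species Gaussian hotspots
  (defaults on the 5S/18S fixture species mirror the reported contact
  coordinates);
- exactly one contact per read, converted with p_conv = 0.7 (a realistic
  mid-range cross-linking efficiency; the retained read classes are d0/d1,
  so multi-conversion reads are not modeled);
- independent substitution errors at 10⁻³/base (Illumina-scale), no indels
  (the transition classes are substitution-defined); errors never overwrite
  a planted conversion (such reads would be unidentifiable anyway);
- tRNA gene abundance defaults to a geometric spectrum (0.85ᵍ, normalized) —
  skewed enough that the top-85 % stratum is meaningful — with family
  enrichment factors (default Lys-UUU 10×, Lys-CUU 2×) multiplying the
  PAR-CLIP sampling weights only;
- the background library draws genes from the *same* abundance vector
  without enrichment and emits hydrolysis-style fragments covering the 5′ or
  3′ half (fair coin), without conversions — the half-fragment geometry is
  the only hydro-chemistry feature modeled;
- constant quality strings; quality-aware processing is out of scope.

Every read is logged with origin, footprint, contact, conversion flag and
error positions, and the ledger round-trips through TSV.

The bundled synthetic universe holds 20 tRNA genes in 18 isoacceptor
families (two gene copies each for Lys-UUU and Lys-CUU), six mRNAs with
realistic region proportions, four rRNA species (5S and 5.8S at native
lengths, 18S at 1869 nt, 28S represented at 2000 nt), and one "other" RNA.
tRNA bodies follow a 76-nt cloverleaf template with conserved positions;
the D-loop carries a single uridine at the canonical position-16
dihydrouridine site and other D-loop positions are filled from {A,C,G}.
This concentration of the contact on one identifiable position per gene is
what makes the planted conversion probability readable from the
per-position ratio; real D-loops carry several uridines, over which the
signal would be split. Gene bodies are otherwise random, so reads place
uniquely with overwhelming probability — real tRNA isodecoders share far
more sequence, and multimapping within families is correspondingly
underrepresented (the family-unique rollup exists precisely for that
case).

What passing the simulation-recovery tests shows: the pipeline's estimators
are unbiased and correctly calibrated *under the generative model above*.
What it does not show: robustness to PCR-duplicate families, ligation bias,
tRNA modification-induced misincorporations or stops, expression-dependent
mRNA sampling, or reference incompleteness — none of which the generator
emulates.

## Determinism and problem sizes

One global seed drives everything; per-stage seeds derive from it via
`SeedSequence`, and re-running a config reproduces every output file
byte-identically. The test suite runs the recovery checks at 200k+200k reads
for the headline run and 6k–30k reads per replicate for the 20-replicate
null-FDR, D-loop-localization and hotspot-recovery checks — sizes at which
the planted effects are comfortably identified and the whole suite stays in
the minutes range on one core. `scripts/acceptance.py` re-derives the
headline quantities from scratch at the full default depth.

## Known limitations

- Exhaustive-equivalent alignment scales as O(candidate positions × read
  length); it is designed for curated transcript universes (≲ 10⁵ nt), not
  genomes.
- The Fisher/TMM composition issue described above: flag counts inflate at
  extreme depth under strong planted composition shifts.
- Single-contact reads only; conversion ratios near 1 with multi-uridine
  contacts are outside the model.
- The hotspot caller is a threshold rule on marginal coverage; it does not
  deconvolve overlapping hotspots closer than the merge gap.
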