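# Methods

## Problem setting

Long noisy reads systematically mis-sequence short tandem repeats: the
dominant failure mode is tract contraction (deletions), with rarer
expansions and substitutions, and the effect is strand-dependent for
A/T homopolymers. `tandemkit` treats STR genotyping as three decoupled
estimation steps — per-read allele correction, per-locus histogram
matching, and cross-sample comparison — each of which can be validated
separately.

## Catalog construction

Perfect repeats of a primitive unit (1–6 nt) are found by a linear scan for
maximal periodicity runs: an interval where `s[j] == s[j-p]` for period
`p`, truncated to whole unit copies at the leftmost phase. Runs are
reported when they reach the per-unit-size minimum total length (defaults
10/12/12/16/20/24 nt for 1–6 bp units; the 1-bp threshold matches the
standard catalog convention for homopolymers). Non-ACGT characters
terminate runs. For periods ≥ 2, two maximal runs can share up to `p−1`
characters; such overlaps are resolved greedily left-to-right so catalog
loci never overlap within a unit size. Coordinates are 0-based half-open.

### Flank complexity

Two metrics are computed per flank from sliding k-mer counts `F_i`
(defaults `k = 2`, flank window 12 nt):

* diversity `(L−(k−1)) / Σ F_i²`, bounded in `[1/(L−k+1), 1]`;
* effective k-mer count `(L−k+1)² / Σ F_i²`, the inverse-Simpson (Hill)
  number of the k-mer distribution, bounded in `[1, L−k+1]`.

The two differ by exactly the factor `L−k+1`. The catalog filter uses the
effective count by default with thresholds 2.5 / 2.0 / 5.0 for 1/2/3-bp
units (a flank at or below the threshold on either side removes the
locus): the diversity form cannot exceed 1, so thresholds above 1 are only
meaningful on the effective-count scale. The diversity form remains
selectable and both are emitted in the catalog TSV. Loci with
contig-truncated flanks are flagged and exempted from the complexity test
rather than judged on partial sequence.

A separate subset selector flags loci whose tract resembles a flank:
`min(lev(left, tract), lev(right, tract)) < 7` on 12-nt flanks. These are
the loci where tract boundaries are intrinsically ambiguous; they are
excluded from accuracy analyses (and re-includable via the invert flag).

The strand-specific coverage rule keeps a locus when **either** strand has
at least `min_strand_coverage` reads (default 20), because strand-selective
genotyping of A/T repeats only needs one well-covered orientation.

## Read handling

Primary alignments with MAPQ ≥ 60 are used; secondary and supplementary
records are dropped. Indexed BAMs are fetched per locus; plain SAM input
is handled by a single linear pass with interval assignment, which is what
the bundled simulator produces.

Tract extraction does not trust the aligner's gap placement inside the
repeat. Instead each reference flank (anchor window 30 nt per side,
deliberately wider than the 12-nt complexity window: short anchors are
fragile at long-read error rates) is located directly in the read by
semi-global (infix) edit-distance search (edlib). An anchor is accepted
when its edit distance is at most 30% of its length — i.e. at least ~70%
of anchor bases agree; among co-optimal hits the one nearest the coarse
CIGAR projection of the tract boundary is taken. The read bases strictly
between the left anchor's end and the right anchor's start form the
observed segment, reported in reference orientation. Reads that do not
span both anchor windows, or whose anchors fail the budget, are marked
unanchored and excluded from correction; no partial-allele inference is
attempted.

`as_sequenced_unit` records the unit the pore physically read — the
reference unit for forward-strand alignments, its reverse complement for
reverse-strand ones — enabling strand-aware aggregation (A-repeats are
sequenced far more accurately as A than as T).

## Allele correction

For each locus the candidate alleles are `0 … max_observed + 5`, where
`max_observed = floor(len(segment)/len(unit))` over the locus's reads (the
pre-correction repeat count) and the 5-repeat buffer absorbs outliers. The
read's corrected allele minimises the unit-cost Levenshtein distance
between its segment and `unit × n` (edlib). Ties are broken toward the
candidate whose tract length is closest to the observed length, then
toward the smaller allele, the deletion-dominant prior. Reads whose
minimum distance exceeds 4 are discarded as excessively erroneous; the
threshold is exposed. Correction is idempotent on perfect tracts and never
reports a distance above the brute-force minimum (both are tested).

## Genotyping

The observed histogram is matched against a synthetic histogram per
candidate allele. The synthetic generative form is a truncated two-sided
geometric kernel: mass ∝ `p_del^d` for a d-repeat contraction and
`p_ins^d` for a d-repeat expansion (defaults 0.3 / 0.05, `max_shift` 5),
truncated at allele 0 and renormalised; `p_del = p_ins = 0` degenerates to
a point mass (delta kernel). The distance is the L1 distance between
normalised histograms — bounded in [0, 2], symmetric, and mode-seeking:
under the delta kernel the estimator provably returns the histogram mode
(tested by enumeration). Ties go to the observed modal allele, then the
smaller allele; distances are rounded to 9 decimals before comparison so
float summation order cannot perturb exact ties.

Peak prominence is the confidence proxy: peaks of the count vector over
the contiguous support (zero-padded by one bin per side so edge bins and
single-bin histograms qualify) are located with `scipy.signal.find_peaks`;
the top peak's prominence is its height above the larger of its two
shoulder minima, each shoulder running to the nearest strictly higher bin
or the support edge (an empty shoulder contributes the zero padding, so a
single-bin histogram's prominence equals its count). This "height above
the immediate shoulders" convention was chosen over the raw
contour-line convention because it degrades gracefully for the narrow,
few-bin histograms typical of 30× loci.

Default `min_coverage` is 5 reads per locus; the MSI mode overrides it
with its own threshold (30).

## Comparative scoring and MSI

With a matched normal, each commonly covered locus gets
`score = distance(H_n, H_t) × prominence(H_n)` — deliberately asymmetric:
the prominence factor comes from the normal sample only, so a locus is
informative when the tumor departs from a confidently peaked normal.

Without a matched normal, the per-locus relative allele size
`Σ_i (A_i − R_i) f_i` is computed against the reference repeat count
`R_i`, with `f_i` the normalised allele frequencies (the weighted-mean
interpretation; it makes the statistic linear under histogram mixing,
which is tested). Locus selection before summarising: A-repeat loci with
reference length 10–14 (the range most vulnerable to mismatch-repair
deficiency), coverage ≥ 30, genotyped in at least `min_samples_covered`
cohort samples, no guanine immediately adjacent to the tract on either
side (G-flanked A-repeats sequence poorly), and a prominence-band rule
that removes loci whose prominence lies within `[μ − σ/2, μ + σ/2]` of
the sample's prominence distribution (μ, σ per sample). The band rule is
implemented exactly as stated — it removes mid-prominence loci and keeps
both extremes — with an `invert_band` flag for the complementary
interpretation; "coverage above 30" is read as ≥ 30 (configurable).

Cross-sample distribution overlap is computed on a fixed grid of
relative-size values (bin width 0.25 repeats) as `Σ min(p_a, p_b)`, a
deterministic alternative to bandwidth-dependent density overlap.

## Error profile

A read is errorless when its segment equals `unit × ref_repeat_count`
exactly; sequencing accuracy is the fraction of errorless reads.
Erroneous reads are typed from one optimal unit-cost global alignment
(in-house DP): segment gaps → deletion, reference gaps → insertion,
mismatches → substitution, recorded as presence flags per read. When
multiple alignments are co-optimal the traceback prefers deletions, then
insertions — consistent with the deletion dominance of the platform.
Class summaries average per-locus accuracies within (unit, length)
classes (pooled-read summaries can be derived from the emitted counts).
Motif tables group A-repeat loci by their 2-nt adjacent flanks and keep
only motifs present in more than 10 loci at every tract length 10–14, so
a motif's effect is comparable across lengths.

## Simulator

The generator implants `n_loci` repeats in random high-complexity flanks
(the base adjacent to the tract never extends the repeat's periodicity, so
implanted copy numbers are exact and maximal), separated by ≥ 2 flank
lengths of random spacer. Reads span locus ± flank; each read's tract
length is the true allele shifted by a draw from the same two-sided
geometric kernel family the genotyper assumes (matched by design so that
parameter recovery is well-posed; a mismatch can be induced by configuring
different rates per strand), plus independent per-base substitutions.
Reads are emitted as already-aligned SAM (correct POS/CIGAR/FLAG, MAPQ 60)
plus a strand-native FASTQ, so no external aligner is needed. All
randomness flows from one integer seed; identical configs give
byte-identical output.

Defaults — the study conditions used throughout the tests — are: unit A,
alleles 10–14, 60-nt flanks, coverage 30, balanced strands,
`p_del = 0.3`, `p_ins = 0.05`, `p_sub = 0.01`, `max_shift = 5`.

### What the simulator does not emulate

Real long-read data has position-dependent quality, context-dependent
error rates, chimeric and clipped reads, alignment ambiguity near
low-complexity regions, and tract errors that are not pure whole-unit
shifts. Passing the simulation-based tests therefore demonstrates the
pipeline's correctness and statistical behaviour under the stated error
model, not its end-to-end accuracy on real flow-cell data; the worked
examples and primitive-level oracles are model-independent.

## Problem sizes

The bundled test suite and acceptance checks run, per invocation: clean
round-trip at 50 loci × 30 reads; deletion-skew recovery at 200 loci × 30
and × 60 reads; MSI cohort separation at 60 loci × 30 reads × 2 samples;
error-fraction calibration at 10,000 reads; 1,000 random pairs for the
edit-distance oracle and 2-kb sequences for the repeat-finder oracle.

## Known limitations

* No phasing: heterozygous loci yield a single best-matching allele; the
  prominence value is the intended tripwire (bimodal histograms score low).
  Use the histogram itself when heterozygosity is expected.
* The error kernel is stationary per strand; no per-locus context model.
* Compound and imperfect repeats are out of scope; only perfect tandem
  repeats are cataloged.
* No MSI classification threshold is provided — the output is the
  relative-allele-size distribution and overlap statistics, not a
  clinical call.
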