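# Methods

## Variant normalization and the consensus key

Every matching step in the package joins on a canonical biallelic key
`(contig, 1-based position, ref, alt)`. Multiallelic records are first
decomposed positionally: each alternate allele becomes its own record with
AD reduced to `[ref_depth, that_alt_depth]` (the original reference depth is
kept without rescaling — the simplest defensible reading; DP, GQ and FILTER
are copied). Genotypes that name a different alternate allele are recoded as
heterozygous-for-this-allele with a `cross_alt` flag so zygosity analyses can
exclude them.

Normalization then applies the standard left-alignment/parsimony algorithm:
shared trailing bases are trimmed (extending both alleles leftward with the
preceding reference base whenever one allele would become empty, decrementing
the position), then shared leading bases are trimmed while both alleles are
longer than one base. The result is the unique minimal left-aligned
representation; the test suite checks it against a brute-force enumerator
that generates *every* equivalent representation by direct haplotype
comparison over repeat tracts up to 30 bp. Position-1 underflow during
left-extension and reference/allele mismatches raise errors rather than
guessing.

Coordinates are 1-based inclusive (VCF convention) everywhere except the
structural-variant module, which is 0-based half-open (BED convention);
SNV positions are converted internally (`pos - 1`) at that boundary, so a
1-based SNV at position `end` of a half-open interval `[start, end)` lies
*outside* it and position `start + 1` is the first base inside.

## Quality filtering

Calls fail with accumulated (not first-hit) reason codes when DP < 20,
GQ < 20, the call is heterozygous with allelic balance < 0.2, or FILTER is
not PASS. All boundaries are inclusive (a het call with AD = [16, 4], i.e.
AB exactly 0.2, passes). Allelic balance is computed from AD as
`alt / (ref + alt)` rather than `alt / DP`: DP can include reads assigned to
other alleles or filtered reads, so the AD-based ratio is the more robust
definition. AB applies to heterozygotes only; whether it should also bind
hom-alt calls is left off by design. Missing DP/GQ/AD is a filter failure
(`missing_field`) by default, with a lenient flag for shallow-coverage
dialects that omit fields. Filtering runs per caller *before* intersection;
a `filter_after` flag flips the order for sensitivity analysis.

## Cross-caller consensus

A key is retained for a sample iff at least `required_callers` caller sets
contain it exactly (default: all callers supplied, normally four; three-of-four
mirrors the shallow-sequencing operating point). Genotype is assigned by
majority vote over supporting callers; an exact tie keeps the variant but
flags `discordant_gt`, and such carriers are excluded from zygosity
stratification — discordance handling is otherwise undefined territory and
dropping data silently would be worse. Consensus at `required = all` is
provably a subset of every caller's filtered set and grows monotonically as
the requirement is relaxed; both properties are tested, along with a
brute-force set-intersection oracle.

## Annotation matching and the somatic rule

Clinical tables (ClinVar-, COSMIC-, dbVar-style TSVs) are matched by exact
`(contig, position, alt)` with a reference-allele consistency check; rsIDs
are never join keys (they drift across builds). Classification strings map
into a closed vocabulary {Pathogenic, Likely-pathogenic, Likely-benign,
Benign, VUS, Conflicting} through a synonym table ("Variant of Uncertain
Significance" ≡ "VUS", "Conflicting pathogenicity" → Conflicting, etc.);
duplicate keys with disagreeing classifications collapse to Conflicting.
A table row listing several alternate alleles separated by `/` is keyed by
the first allele, the remainder kept as provenance — this keeps one record
per table row, which is how the packaged 12-row table counts its classes
(the TP53 G>C/A row counts once, as VUS).

The cohort somatic call combines annotation origin with presence: somatic
requires somatic (or somatic+germline) origin *and* an empty intersection of
the carrier set with BPH samples; a somatic-annotated variant observed in a
BPH sample is demoted to unresolved rather than silently reclassified.
Loss-of-heterozygosity detection proper is out of scope — there are no
tumor-normal pairs — so origin + cohort presence is the entire rule.

## Rarity binning

Binning uses the gnomAD-style MAF only: extremely rare at MAF ≤ 0.001
(boundary inclusive), common at MAF ≥ 0.05, rare between, not-reported when
absent. The 0.05 common threshold is the conventional common-variant cutoff;
it is configurable. GenomeIndia-style AAF values are carried for context but
never drive binning, since published AAFs are alternative-allele, not
necessarily minor-allele, frequencies. GWAS-catalog matching is strict
four-field equality with no strand or ref/alt flipping.

## Stratification

Occurrence ranking sorts by descending carrier count with a deterministic
`(contig, position, alt)` tie-break; `shared` means ≥ 2 carriers. High grade
means Gleason patterns 4+4 and 4+3 exactly; 3+4 is "lower" despite the equal
score, because pattern dominance, not the sum, defines the group. Samples
are validated against the inclusion rule (score ≥ 6 ⇔ malignant). The
per-variant 2×2 table {hom_alt, het} × {high, lower/BPH} is called
concordant iff every high-grade carrier is homozygous-alt and every
lower/BPH carrier heterozygous; association uses the two-sided exact
conditional (Fisher) test, which the suite verifies against full
margin-fixed enumeration for all tables with n ≤ 30.

## Structural variants and the bona-fide filter

Intersection is any-overlap ≥ 1 bp on 0-based half-open intervals (the
default behavior of the standard interval-intersection tool), with optional
reciprocal-fraction and type-matching constraints; an interval tree provides
the index and a quadratic all-pairs oracle checks it. A cohort CNV is bona
fide when its best-overlapping (largest overlap) population SV is
demonstrably rare: with allele counts available, the upper bound of the
two-sided 90% Wilson score interval for the population allele frequency must
be < 0.02; with only a point frequency, the point itself must be < 0.02.
The Wilson bound is conservative, closed-form, and reduces to the point rule
as counts grow; population SVs with no frequency information cannot
demonstrate rarity and are excluded with reason `no_frequency`.

## CAG repeat profiling

Repeat length is measured by exact flank anchoring: a read spans the locus
iff it contains the configured left flank, then the right flank downstream,
and the enclosed segment is a whole number of exact `CAG` copies.
Interrupted tracts and partial reads become non-spanning observations with
reason codes and contribute nothing — deterministic and conservative, at the
cost of discarding reads a local aligner might rescue. An allele is
supported at ≥ 3 reads and ≥ 20% of spanning reads (suppressing single-read
stutter); a sample is mosaic at ≥ 2 supported alleles, uncallable below 10
spanning reads. Risk is high iff *any* supported allele is ≤ 18 repeats
(inclusive), since risk attaches to the presence of a short allele, not to a
genotype average. The cohort summary reports the mosaic fraction over both
callable and all samples, since the natural denominator is ambiguous. No
PCR-stutter deconvolution is attempted; the simulator can inject ±1-unit
noise to stress the thresholds.

## Synthetic cohort generator

The generator emulates the target cohort design: 49 samples (30 labeled malignant,
5 BPH, the unlabeled remainder treated as malignant by default or excluded
by flag); germline truth variants shared by 2..n samples with a configurable
sharing distribution (uniform by default); somatic truth variants confined
to malignant samples, homozygous-alt in Gleason 4+4/4+3 carriers and
heterozygous otherwise. Caller profiles control false-negative rate,
Poisson false-positive count, and representation style (minimal,
right-shifted indels, or merged multiallelics — the dialects real callers
differ in). Depth is negative-binomial (mean 110, dispersion 5 for the
exome-like preset; mean 3, dispersion 2 for the shallow-genome preset,
reflecting ~110× and 1.6–4× coverage respectively); GQ is normal
(mean 80, sd 10) truncated to [0, 99]. The noise-free preset additionally
floors depth and GQ at the filter thresholds and makes het allele depths an
even split, so that the end-to-end closure oracle — consensus equals planted
truth exactly — is a property of the pipeline, not of lucky draws.
Annotation, frequency, GWAS and SV tables are emitted with planted rows
keyed exactly by truth keys plus configurable decoys. CAG reads are
`left flank + (CAG)×L + right flank` with L drawn per read from the sample's
allele mixture; the cohort simulator plants a 36% mosaic fraction by default
with secondary alleles ≥ 3 units from the primary at 25–50% mixture.

All randomness flows from a single integer seed through named
`SeedSequence` channels, so identical configurations are byte-identical
across runs, re-orderings, and platforms.

What the generator does *not* model: exome capture, alignment, FFPE
deamination chemistry (only a uniform false-positive knob), PCR stutter in
the default read simulator, and linkage between variants. Passing tests on
synthetic data therefore demonstrate the correctness of the bookkeeping —
normalization, intersection, filtering, counting — not robustness to every
real-data artifact.

## Problem sizes and numerical choices

The test suite and acceptance script run the closure check at 49 samples ×
~1,020 truth variants × 4 callers, the normalization oracle at 500 random
indels, interval oracles at 50 instances of ≤ 200 intervals, the exact-test
enumeration to n = 30, and mosaicism recovery over 200 simulated samples in
tests (1,000 in the acceptance script, where a tighter standard error on
the recovered percentage is worth the extra seconds). Exact-test agreement
is asserted at relative tolerance 1e-7 (the conventional tie tolerance of
the two-sided definition); Wilson bounds at 1e-9 against a numeric
root-finder. Ties in occurrence ranking and in genotype votes are broken
deterministically as documented above, so all outputs are stable under
re-runs with a fixed seed.

## Known limitations

- The somatic/germline partition is only as good as the annotation origin
  column; with `unknown` origins everywhere, most variants land in
  `unresolved` or presence-based `germline`.
- Consensus requires exact key equality; near-miss representations that
  survive normalization differences between real callers (e.g. complex
  MNP decompositions) are not reconciled.
- The bona-fide bound targets the population SV's frequency, not the cohort
  carrier frequency; with neither counts nor frequency it excludes, which
  undercounts bona-fide CNVs on sparsely annotated population tables.
- Flank-anchored repeat counting requires reads spanning the entire tract;
  long alleles on short reads become systematically uncallable rather than
  estimated.
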