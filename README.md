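# varprio

Variant prioritization for a prostate-cancer cohort: strict multi-caller
consensus calling, clinical annotation matching, population-frequency rarity
binning, cohort stratification, structural-variant overlap, and androgen
receptor (AR) CAG-repeat mosaicism profiling — with a fully specified
synthetic cohort generator so every stage is testable without raw sequencing
data.

## The problem

Calling somatic and germline variants from archival FFPE prostate tissue is
noisy: formalin fixation inflates artifacts, and no single variant caller is
trustworthy on its own. The approach implemented here prioritizes *bona
fide* variants by brute consensus: a variant is kept for a sample only when
all required callers (four by default: Varscan-, BCFTools-, FreeBayes- and
Vt-style call sets) report the **identical normalized key**
`(contig, position, ref, alt)`. Because callers disagree about
representation — right-shifted indels inside repeat tracts, merged
multiallelic records — every call is first decomposed to biallelic records
and reduced to its minimal left-aligned form, so that all equivalent
encodings of one biological event collapse onto a single key.

Downstream, consensus variants are filtered on call quality
(depth DP ≥ 20, genotype quality GQ ≥ 20, allelic balance
AB = alt/(ref+alt) ≥ 0.2 for heterozygotes, FILTER == PASS), matched
against ClinVar/COSMIC-style tables by position and alternate allele,
partitioned somatic vs germline (somatic requires somatic annotation origin
*and* absence from every benign-hyperplasia sample), binned by gnomAD minor
allele frequency (extremely rare at MAF ≤ 0.001, common at MAF ≥ 0.05),
ranked by cohort occurrence, and tested for the zygosity-by-grade pattern
(homozygous pathogenic calls in high Gleason-grade 4+4/4+3 tumors vs
heterozygous in BPH) with an exact conditional test. Copy-number intervals
are intersected with population SV tables and kept as bona fide when the
90% Wilson upper confidence bound of the population allele frequency lies
below 0.02. Finally, CAG tract lengths in the AR gene are measured by exact
flank-anchored counting of spanning reads; two or more supported lengths in
one sample indicate somatic mosaicism, and any supported allele of ≤ 18
repeats flags elevated risk.

## Worked example

The package ships a 12-row table of consensus somatic variants (APC, BRAF,
ATM, TP53, SMAD4, CHK2) with ClinVar classifications and gnomAD/GenomeIndia
frequencies:

```python
from varprio.datasets import load_table1_annotations, load_table1_frequencies
from varprio.annotation import classification_counts, filter_by_classification
from varprio.rarity import rarity_report

records = load_table1_annotations()
print(len(records), classification_counts(records))
keep = {"Pathogenic", "Likely-pathogenic", "Likely-benign", "VUS", "Conflicting"}
print("non-benign:", len(filter_by_classification(records, keep=keep)))
report = rarity_report(load_table1_frequencies())
print(report["rarity"], "not reported:", report["gnomad_not_reported"])
```

prints

```
12 {'Pathogenic': 4, 'Likely-pathogenic': 1, 'Likely-benign': 1, 'Benign': 1, 'VUS': 4, 'Conflicting': 1}
non-benign: 11
{'extremely_rare': 4, 'rare': 0, 'common': 1, 'not_reported': 7} not reported: 7
```

i.e. 12 parsed records, 11 of which are not benign; four are extremely rare
(MAF ≤ 0.001), seven carry no gnomAD frequency, and the single common one is
the TP53 polymorphism at 17:7676154 G>C with MAF 0.38.

The full pipeline runs from the command line on a simulated cohort
(49 samples, noise-free caller profiles by default):

```bash
varprio all --seed 1 --out run/
```

which simulates per-sample, per-caller VCFs plus annotation/frequency/SV
tables and CAG-locus reads, then chains consensus → annotation → rarity →
stratification → CNV overlap → repeat profiling, ending with a validated
filter-funnel report, e.g.

```
funnel ok: [{"name": "quality_filter", "records_in": 6460, "records_out": 6460,
"reasons": {}}, {"name": "consensus_intersection", "records_in": 6460,
"records_out": 1615, "reasons": {"insufficient_caller_support": 4845}}]
```

(6460 caller records from four callers collapse to 1615 consensus
sample-variant pairs; under noise-free profiles this equals the planted
truth exactly). Every stage is also callable as a library function or as a
standalone subcommand on files (`varprio consensus --help`, etc.).

## Layout

| Module | Role |
| --- | --- |
| `varprio.variants` | normalized variant keys, left-alignment, multiallelic splitting, allelic balance |
| `varprio.consensus` | quality filters and cross-caller intersection |
| `varprio.annotation` | clinical table loading, key matching, somatic/germline partition |
| `varprio.rarity` | frequency joins, rarity binning, GWAS-catalog matching |
| `varprio.stratify` | occurrence ranking, zygosity-by-grade exact test |
| `varprio.svoverlap` | interval intersection, Wilson-bound bona-fide CNV filter |
| `varprio.repeats` | flank-anchored CAG counting, mosaicism and risk calls |
| `varprio.synthetic` | cohort/truth/VCF/table/read simulation |
| `varprio.cli` | subcommand orchestration and the filter funnel |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
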