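"""Synthetic cohort generator.

Emulates the target cohort design end to end so every downstream stage is testable
without raw sequencing data: a cohort of ~49 prostate samples (30 labeled
malignant, 5 BPH, remainder configurable), germline truth variants shared by
2..n samples, somatic truth variants confined to malignant samples
(homozygous-alt in Gleason 4+4/4+3 carriers, heterozygous otherwise),
per-caller VCFs with controlled false-negative/false-positive and
representation noise, annotation/frequency/GWAS/SV tables with planted
entries plus decoys, and flank-anchored CAG-locus reads with configurable
allele mixtures.

Everything is a pure function of (config, seed): the same inputs produce
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .stratify import SampleMeta
from .variants import NormalizedVariant, RawCall, normalize, right_shift

CALLER_IDS = ("varscan", "bcftools", "freebayes", "vt")

REPRESENTATION_STYLES = ("minimal", "right_shifted", "multiallelic_merged")

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


def _check_distribution(dist: Mapping, name: str) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"{name} probabilities sum to {total}, expected 1")
    if any(p < 0 for p in dist.values()):
        raise ConfigError(f"{name} contains negative probabilities")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the cohort: 49 samples of which 30 are labeled malignant
    and 5 BPH; the unlabeled remainder is treated as malignant (set
    ``unlabeled_as_malignant=False`` to exclude them instead). Germline
    sharing counts span 2..n_samples; somatic variants are carried by
    malignant samples only.
    """

    n_samples: int = 49
    n_malignant: int = 30
    n_bph: int = 5
    unlabeled_as_malignant: bool = True
    gleason_distribution: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {(3, 3): 0.35, (3, 4): 0.25, (4, 3): 0.20, (4, 4): 0.20}
    )
    bph_gleason_distribution: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: {(2, 3): 0.5, (3, 2): 0.5}
    )
    n_germline_truth: int = 60
    sharing_distribution: Mapping[int, float] | None = None  # None -> uniform 2..n
    n_somatic_truth: int = 12
    somatic_max_carriers: int = 5
    indel_fraction: float = 0.3
    annotated_germline_fraction: float = 0.3
    maf_reported_fraction: float = 0.6
    aaf_reported_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_malignant + self.n_bph > self.n_samples:
            raise ConfigError("n_malignant + n_bph exceeds n_samples")
        _check_distribution(self.gleason_distribution, "gleason_distribution")
        _check_distribution(self.bph_gleason_distribution, "bph_gleason_distribution")
        if self.sharing_distribution is not None:
            _check_distribution(self.sharing_distribution, "sharing_distribution")
            bad = [k for k in self.sharing_distribution if not 2 <= k <= self.n_samples]
            if bad:
                raise ConfigError(f"sharing counts outside 2..n_samples: {bad}")

    def sharing(self) -> dict[int, float]:
        if self.sharing_distribution is not None:
            return dict(self.sharing_distribution)
        counts = range(2, self.n_samples + 1)
        p = 1.0 / len(counts)
        return {k: p for k in counts}


@dataclass(frozen=True)
class CallerProfile:
    """Noise and representation behavior of one synthetic caller.

    Depth is negative-binomial (WES-like default mean 110, dispersion 5; an
    LP-WGS-like preset uses mean 3, dispersion 2); GQ is normal truncated to
    [0, 99]. ``depth_floor``/``gq_floor`` truncate below, used by the
    noise-free preset so every emitted record clears the default quality
    gates. ``ad_noise`` draws het allele depths binomially instead of an even
    split.
    """

    caller_id: str
    fn_rate: float = 0.0
    fp_rate: float = 0.0  # expected false calls per sample (Poisson mean)
    representation_style: str = "minimal"
    depth_mean: float = 110.0
    depth_dispersion: float = 5.0
    depth_floor: int = 0
    gq_mean: float = 80.0
    gq_sd: float = 10.0
    gq_floor: int = 0
    ad_noise: bool = True
    non_pass_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fn_rate <= 1.0:
            raise ConfigError(f"fn_rate {self.fn_rate} outside [0, 1]")
        if self.fp_rate < 0:
            raise ConfigError("fp_rate must be >= 0")
        if self.representation_style not in REPRESENTATION_STYLES:
            raise ConfigError(f"unknown representation_style {self.representation_style!r}")
        if not 0.0 <= self.non_pass_fraction <= 1.0:
            raise ConfigError("non_pass_fraction outside [0, 1]")


def noise_free_profiles(caller_ids: Sequence[str] = CALLER_IDS) -> list[CallerProfile]:
    """Four callers with no FN/FP, minimal representation, all-PASS, and
    qualities truncated above the default thresholds (the end-to-end oracle
    condition: consensus must equal truth exactly)."""
    return [
        CallerProfile(
            caller_id=c, fn_rate=0.0, fp_rate=0.0, representation_style="minimal",
            depth_floor=20, gq_floor=20, ad_noise=False,
        )
        for c in caller_ids
    ]


def default_profiles(caller_ids: Sequence[str] = CALLER_IDS) -> list[CallerProfile]:
    """Four distinct caller personalities with modest, caller-specific noise."""
    styles = ("minimal", "right_shifted", "multiallelic_merged", "minimal")
    fns = (0.05, 0.05, 0.08, 0.02)
    fps = (2.0, 1.0, 3.0, 0.5)
    return [
        CallerProfile(caller_id=c, fn_rate=fn, fp_rate=fp, representation_style=st)
        for c, st, fn, fp in zip(caller_ids, styles, fns, fps)
    ]


@dataclass(frozen=True)
class TruthVariant:
    key: NormalizedVariant
    origin: str  # 'germline' | 'somatic'
    carrier_samples: frozenset[str]
    genotype_by_sample: Mapping[str, str]  # sample -> 'het' | 'hom_alt'
    planted_classification: str | None = None
    planted_maf: float | None = None
    planted_aaf: float | None = None


# ---------------------------------------------------------------- reference


def make_reference_sequences(config: CohortConfig, contigs: Sequence[str] = ("chr1", "chr2")) -> dict[str, str]:
    """Deterministic random reference long enough for the configured truth set."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n_truth = config.n_germline_truth + config.n_somatic_truth
    per_contig = max(20_000, 40 * (n_truth // len(contigs) + 20))
    return {
        c: "".join(rng.choice(BASES, size=per_contig))
        for c in contigs
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


class _SeqView:
    """Adapter so plain strings support the reference interface normalize uses."""

    def __init__(self, seq: str):
        self._seq = seq

    def __getitem__(self, item):
        return self._seq[item]

    def __len__(self):
        return len(self._seq)


def as_reference(sequences: Mapping[str, str]) -> dict[str, _SeqView]:
    return {name: _SeqView(seq) for name, seq in sequences.items()}


# ------------------------------------------------------------------- truth


CLASS_POOL = ("Pathogenic", "Likely-pathogenic", "VUS", "Benign", "Likely-benign", "Conflicting")
SOMATIC_CLASS_P = (0.45, 0.15, 0.20, 0.10, 0.05, 0.05)
GERMLINE_CLASS_P = (0.25, 0.15, 0.30, 0.20, 0.05, 0.05)


def make_samples(config: CohortConfig) -> list[SampleMeta]:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    samples: list[SampleMeta] = []
    mal_patterns = list(config.gleason_distribution)
    mal_p = [config.gleason_distribution[k] for k in mal_patterns]
    bph_patterns = list(config.bph_gleason_distribution)
    bph_p = [config.bph_gleason_distribution[k] for k in bph_patterns]
    n_extra = config.n_samples - config.n_malignant - config.n_bph
    n_mal = config.n_malignant + (n_extra if config.unlabeled_as_malignant else 0)
    idx = 1
    for _ in range(n_mal):
        pat = mal_patterns[rng.choice(len(mal_patterns), p=mal_p)]
        samples.append(SampleMeta(f"S{idx:02d}", "malignant", *pat))
        idx += 1
    for _ in range(config.n_bph):
        pat = bph_patterns[rng.choice(len(bph_patterns), p=bph_p)]
        samples.append(SampleMeta(f"S{idx:02d}", "BPH", *pat))
        idx += 1
    return samples


def _draw_variant_shape(rng, sequences, contig, pos, indel: bool):
    """(ref, alt) anchored at 1-based pos within the given reference contig."""
    seq = sequences[contig]
    base = seq[pos - 1]
    if not indel:
        alt = str(rng.choice([b for b in "ACGT" if b != base]))
        return base, alt
    if rng.random() < 0.5:  # insertion
        ins = "".join(rng.choice(BASES, size=int(rng.integers(1, 4))))
        return base, base + ins
    dlen = int(rng.integers(1, 4))
    return seq[pos - 1 : pos + dlen], base


def simulate_truth(config: CohortConfig) -> tuple[list[TruthVariant], list[SampleMeta]]:
    """Generate the truth variant set and cohort metadata.

    Germline sharing counts are drawn from the sharing distribution; somatic
    carriers are a subset of malignant samples with genotype hom_alt for
    Gleason 4+4/4+3 carriers and het otherwise. Deterministic given the seed.
    """
    samples = make_samples(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    sequences = make_reference_sequences(config)
    reference = as_reference(sequences)
    contigs = list(sequences)
    sample_ids = [s.sample_id for s in samples]
    malignant = [s for s in samples if s.tissue == "malignant"]
    high_grade = {s.sample_id for s in samples if s.grade_group == "high"}

    n_total = config.n_germline_truth + config.n_somatic_truth
    # disjoint 1-based slots, spaced widely enough that left-alignment cannot
    # move one variant into another's slot
    slots: list[tuple[str, int]] = []
    per = math.ceil(n_total / len(contigs))
    for ci, contig in enumerate(contigs):
        for j in range(per):
            slots.append((contig, 25 + j * 35))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order[:n_total]]

    sharing = config.sharing()
    share_counts = list(sharing)
    share_p = [sharing[k] for k in share_counts]

    truths: list[TruthVariant] = []
    seen: set[NormalizedVariant] = set()
    for i in range(n_total):
        somatic = i >= config.n_germline_truth
        contig, pos = slots[i]
        indel = bool(rng.random() < config.indel_fraction)
        ref, alt = _draw_variant_shape(rng, sequences, contig, pos, indel)
        call = RawCall(contig, pos, ref, [alt], "PASS", "truth", "truth")
        key = normalize(call, reference)
        if key in seen:
            continue
        seen.add(key)
        if somatic:
            n_car = int(rng.integers(1, config.somatic_max_carriers + 1))
            carriers = list(
                rng.choice([s.sample_id for s in malignant], size=min(n_car, len(malignant)), replace=False)
            )
            gts = {
                s: ("hom_alt" if s in high_grade else "het") for s in carriers
            }
            cls = CLASS_POOL[rng.choice(len(CLASS_POOL), p=SOMATIC_CLASS_P)]
        else:
            n_car = share_counts[rng.choice(len(share_counts), p=share_p)]
            carriers = list(rng.choice(sample_ids, size=n_car, replace=False))
            gts = {
                s: ("het" if rng.random() < 0.7 else "hom_alt") for s in sorted(carriers)
            }
            cls = (
                CLASS_POOL[rng.choice(len(CLASS_POOL), p=GERMLINE_CLASS_P)]
                if rng.random() < config.annotated_germline_fraction
                else None
            )
        maf = (
            float(10 ** rng.uniform(-7, math.log10(0.5)))
            if rng.random() < config.maf_reported_fraction
            else None
        )
        aaf = (
            float(10 ** rng.uniform(-6, math.log10(0.6)))
            if rng.random() < config.aaf_reported_fraction
            else None
        )
        truths.append(
            TruthVariant(
                key=key,
                origin="somatic" if somatic else "germline",
                carrier_samples=frozenset(carriers),
                genotype_by_sample=gts,
                planted_classification=cls,
                planted_maf=maf,
                planted_aaf=aaf,
            )
        )
    truths.sort(key=lambda t: t.key)
    return truths, samples


# ------------------------------------------------------------ VCF emission


def _draw_depth(rng, profile: CallerProfile) -> int:
    n = profile.depth_dispersion
    p = n / (n + profile.depth_mean)
    dp = int(rng.negative_binomial(n, p))
    return max(dp, profile.depth_floor, 1)


def _draw_gq(rng, profile: CallerProfile) -> int:
    gq = rng.normal(profile.gq_mean, profile.gq_sd)
    return int(min(99, max(profile.gq_floor, 0, round(gq))))


def _format_fields(rng, profile: CallerProfile, genotype: str) -> tuple[str, int, int, tuple[int, int]]:
    dp = _draw_depth(rng, profile)
    gq = _draw_gq(rng, profile)
    if genotype == "hom_alt":
        alt_d = dp if not profile.ad_noise else int(rng.binomial(dp, 0.98))
        gt = "1/1"
    else:
        alt_d = dp // 2 if not profile.ad_noise else int(rng.binomial(dp, 0.5))
        gt = "0/1"
    return gt, dp, gq, (dp - alt_d, alt_d)


VCF_HEADER = """##fileformat=VCFv4.2
##source=varprio-synthetic
{contigs}##FILTER=<ID=PASS,Description="All filters passed">
##FILTER=<ID=q10,Description="Synthetic low-quality flag">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


@dataclass
class _Rec:
    contig: str
    pos: int
    ref: str
    alts: list[str]
    filter: str
    gt: str
    dp: int
    gq: int
    ad: tuple[int, ...]

    def line(self) -> str:
        ad = ",".join(str(d) for d in self.ad)
        return (
            f"{self.contig}\t{self.pos}\t.\t{self.ref}\t{','.join(self.alts)}\t"
            f"99\t{self.filter}\t.\tGT:DP:GQ:AD\t{self.gt}:{self.dp}:{self.gq}:{ad}"
        )


def _merge_multiallelic(records: list[_Rec]) -> list[_Rec]:
    """Merge co-located records sharing (contig, pos, ref) into one
    multiallelic record (the merged-representation caller dialect)."""
    grouped: dict[tuple[str, int, str], list[_Rec]] = {}
    for r in records:
        grouped.setdefault((r.contig, r.pos, r.ref), []).append(r)
    out: list[_Rec] = []
    for group in grouped.values():
        if len(group) == 1:
            out.append(group[0])
            continue
        alts = [a for r in group for a in r.alts]
        ad = (max(r.ad[0] for r in group),) + tuple(r.ad[1] for r in group)
        gt = "1/2" if len(group) >= 2 else group[0].gt
        out.append(
            _Rec(
                contig=group[0].contig,
                pos=group[0].pos,
                ref=group[0].ref,
                alts=alts,
                filter=group[0].filter,
                gt=gt,
                dp=max(r.dp for r in group),
                gq=min(r.gq for r in group),
                ad=ad,
            )
        )
    return out


def emit_caller_vcfs(
    truths: Sequence[TruthVariant],
    samples: Sequence[SampleMeta],
    profiles: Sequence[CallerProfile],
    sequences: Mapping[str, str],
    seed: int,
    out_dir: str | Path,
) -> dict[tuple[str, str], Path]:
    """Write one VCF per (sample, caller): ``<sample>.<caller>.vcf``.

    Per caller: each truth variant carried by the sample is dropped with
    probability fn_rate; Poisson(fp_rate) false het SNVs are added at
    positions away from any truth slot; records are rendered in the caller's
    representation style; FORMAT fields come from the caller's depth/GQ
    models; a non_pass_fraction of records is flagged q10.
    """
    if len({p.caller_id for p in profiles}) != len(profiles):
        raise ConfigError("caller_ids must be distinct")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reference = as_reference(sequences)
    for t in truths:
        if t.key.contig not in sequences or t.key.position + len(t.key.ref) - 1 > len(
            sequences[t.key.contig]
        ):
            raise ConfigError(f"truth position outside reference: {t.key}")
    truth_positions = {(t.key.contig, t.key.position) for t in truths}
    contig_header = "".join(
        f"##contig=<ID={name},length={len(seq)}>\n" for name, seq in sequences.items()
    )
    paths: dict[tuple[str, str], Path] = {}
    for si, sample in enumerate(samples):
        carried = [t for t in truths if sample.sample_id in t.carrier_samples]
        for pi, profile in enumerate(profiles):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, 404, si, pi])
            )
            records: list[_Rec] = []
            for t in carried:
                if profile.fn_rate > 0 and rng.random() < profile.fn_rate:
                    continue
                gt_label = t.genotype_by_sample[sample.sample_id]
                contig, pos, ref, alt = (
                    t.key.contig, t.key.position, t.key.ref, t.key.alt,
                )
                if profile.representation_style == "right_shifted" and not t.key.is_snv:
                    pos, ref, alt = right_shift(contig, pos, ref, alt, reference)
                gt, dp, gq, ad = _format_fields(rng, profile, gt_label)
                filt = "q10" if rng.random() < profile.non_pass_fraction else "PASS"
                records.append(_Rec(contig, pos, ref, [alt], filt, gt, dp, gq, ad))
            n_fp = int(rng.poisson(profile.fp_rate))
            for _ in range(n_fp):
                contig = list(sequences)[int(rng.integers(len(sequences)))]
                seq = sequences[contig]
                for _attempt in range(50):
                    pos = int(rng.integers(20, len(seq) - 20))
                    if all(
                        abs(pos - tp) > 8
                        for (tc, tp) in truth_positions
                        if tc == contig
                    ):
                        break
                base = seq[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != base]))
                gt, dp, gq, ad = _format_fields(rng, profile, "het")
                filt = "q10" if rng.random() < profile.non_pass_fraction else "PASS"
                records.append(_Rec(contig, pos, base, [alt], filt, gt, dp, gq, ad))
            if profile.representation_style == "multiallelic_merged":
                records = _merge_multiallelic(records)
            records.sort(key=lambda r: (r.contig, r.pos, r.ref, r.alts[0]))
            path = out_dir / f"{sample.sample_id}.{profile.caller_id}.vcf"
            with open(path, "w") as fh:
                fh.write(
                    VCF_HEADER.format(contigs=contig_header, sample=sample.sample_id)
                )
                for r in records:
                    fh.write(r.line() + "\n")
            paths[(sample.sample_id, profile.caller_id)] = path
    return paths


# ------------------------------------------------------- annotation tables


def _random_decoy_key(rng, sequences) -> NormalizedVariant:
    contig = list(sequences)[int(rng.integers(len(sequences)))]
    seq = sequences[contig]
    pos = int(rng.integers(10, len(seq) - 10))
    base = seq[pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != base]))
    return NormalizedVariant(contig, pos, base, alt)


def emit_annotation_tables(
    truths: Sequence[TruthVariant],
    config: CohortConfig,
    sequences: Mapping[str, str],
    out_dir: str | Path,
    decoy_fraction: float = 0.2,
    include_table1: bool = False,
) -> dict[str, Path]:
    """Write ClinVar-like, COSMIC-like, gnomAD-like, GIP-like and GWAS-like
    TSVs with planted rows keyed exactly by truth keys plus decoy rows with
    non-matching keys. With ``include_table1`` the packaged 12-row fixture is
    copied out verbatim as ``table1.tsv``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth_keys = {t.key for t in truths}

    def decoys(n: int) -> list[NormalizedVariant]:
        out = []
        while len(out) < n:
            k = _random_decoy_key(rng, sequences)
            if k not in truth_keys:
                out.append(k)
        return out

    paths: dict[str, Path] = {}

    annotated = [t for t in truths if t.planted_classification is not None]
    n_decoy = int(round(decoy_fraction * len(annotated)))
    clinvar = out_dir / "clinvar_like.tsv"
    with open(clinvar, "w") as fh:
        fh.write("contig\tposition\tref\talt\trsid\tgene\tclassification\torigin\n")
        for t in annotated:
            fh.write(
                f"{t.key.contig}\t{t.key.position}\t{t.key.ref}\t{t.key.alt}\t"
                f".\tGENE\t{t.planted_classification}\t{t.origin}\n"
            )
        for k in decoys(n_decoy):
            cls = CLASS_POOL[int(rng.integers(len(CLASS_POOL)))]
            fh.write(f"{k.contig}\t{k.position}\t{k.ref}\t{k.alt}\t.\tGENE\t{cls}\tunknown\n")
    paths["clinvar"] = clinvar

    cosmic = out_dir / "cosmic_like.tsv"
    with open(cosmic, "w") as fh:
        fh.write("contig\tposition\tref\talt\trsid\tgene\tclassification\torigin\n")
        for t in truths:
            if t.origin == "somatic":
                cls = t.planted_classification or "VUS"
                fh.write(
                    f"{t.key.contig}\t{t.key.position}\t{t.key.ref}\t{t.key.alt}\t"
                    f".\tGENE\t{cls}\tsomatic\n"
                )
    paths["cosmic"] = cosmic

    for name, attr in (("gnomad", "planted_maf"), ("gip", "planted_aaf")):
        path = out_dir / f"{name}_like.tsv"
        with_freq = [t for t in truths if getattr(t, attr) is not None]
        with open(path, "w") as fh:
            fh.write("contig\tposition\tref\talt\tfrequency\n")
            for t in with_freq:
                fh.write(
                    f"{t.key.contig}\t{t.key.position}\t{t.key.ref}\t{t.key.alt}\t"
                    f"{getattr(t, attr):.6g}\n"
                )
            for k in decoys(int(round(decoy_fraction * len(with_freq)))):
                fh.write(
                    f"{k.contig}\t{k.position}\t{k.ref}\t{k.alt}\t{rng.uniform(0, 0.5):.6g}\n"
                )
        paths[name] = path

    gwas = out_dir / "gwas_like.tsv"
    hits = [t for t in truths if rng.random() < 0.25]
    with open(gwas, "w") as fh:
        fh.write("contig\tposition\tref\talt\tp_value\ttrait\n")
        for t in hits:
            fh.write(
                f"{t.key.contig}\t{t.key.position}\t{t.key.ref}\t{t.key.alt}\t"
                f"{rng.uniform(1e-8, 0.05):.3g}\tPCa\n"
            )
        for k in decoys(int(round(decoy_fraction * max(len(hits), 1)))):
            fh.write(f"{k.contig}\t{k.position}\t{k.ref}\t{k.alt}\t{rng.uniform(1e-8, 0.05):.3g}\tPCa\n")
    paths["gwas"] = gwas

    if include_table1:
        from .datasets import table1_path

        target = out_dir / "table1.tsv"
        target.write_text(table1_path().read_text())
        paths["table1"] = target
    return paths


def emit_sv_tables(
    config: CohortConfig,
    sequences: Mapping[str, str],
    out_dir: str | Path,
    n_cohort: int = 40,
    n_population: int = 60,
    rare_fraction: float = 0.6,
) -> dict[str, Path]:
    """Cohort and population SV interval tables (BED-like TSV, 0-based
    half-open). A ``rare_fraction`` of population SVs get allele frequencies
    below the bona-fide threshold; the rest are common."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 606]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = list(sequences)
    types = ("DEL", "DUP", "INS", "INV")

    def random_interval(seq_len):
        start = int(rng.integers(0, seq_len - 2_000))
        length = int(rng.integers(200, 2_000))
        return start, min(start + length, seq_len)

    cohort_path = out_dir / "cohort_sv.tsv"
    cohort_rows = []
    with open(cohort_path, "w") as fh:
        fh.write("contig\tstart\tend\tsv_type\tpop_maf\tallele_count\tallele_number\n")
        for _ in range(n_cohort):
            contig = contigs[int(rng.integers(len(contigs)))]
            start, end = random_interval(len(sequences[contig]))
            svt = types[int(rng.integers(len(types)))]
            cohort_rows.append((contig, start, end, svt))
            fh.write(f"{contig}\t{start}\t{end}\t{svt}\tNR\tNR\tNR\n")

    pop_path = out_dir / "population_sv.tsv"
    with open(pop_path, "w") as fh:
        fh.write("contig\tstart\tend\tsv_type\tpop_maf\tallele_count\tallele_number\n")
        for i in range(n_population):
            if i < len(cohort_rows):  # guarantee overlaps with cohort intervals
                contig, cstart, cend, svt = cohort_rows[i]
                shift = int(rng.integers(-150, 150))
                start = max(0, cstart + shift)
                end = max(start + 50, cend + int(rng.integers(-150, 150)))
            else:
                contig = contigs[int(rng.integers(len(contigs)))]
                start, end = random_interval(len(sequences[contig]))
                svt = types[int(rng.integers(len(types)))]
            an = 10_000
            if rng.random() < rare_fraction:
                ac = int(rng.integers(0, 100))  # AF < 0.01
            else:
                ac = int(rng.integers(500, 5_000))
            fh.write(f"{contig}\t{start}\t{end}\t{svt}\t{ac / an:.6g}\t{ac}\t{an}\n")
    return {"cohort": cohort_path, "population": pop_path}


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_id\ttissue\tgleason_primary\tgleason_secondary\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.tissue}\t{s.gleason_primary}\t{s.gleason_secondary}\n")
    return path


def write_truth_tsv(truths: Sequence[TruthVariant], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\talt\torigin\tcarriers\n")
        for t in truths:
            carriers = ",".join(sorted(t.carrier_samples))
            fh.write(
                f"{t.key.contig}\t{t.key.position}\t{t.key.ref}\t{t.key.alt}\t{t.origin}\t{carriers}\n"
            )
    return path


# ------------------------------------------------------------ repeat reads


@dataclass(frozen=True)
class RepeatTruth:
    sample: str
    allele_lengths: Mapping[int, float]  # repeat count -> mixture fraction
    n_reads: int = 50
    read_error_rate: float = 0.0
    non_spanning_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.allele_lengths:
            raise ConfigError("allele_lengths must be non-empty")
        _check_distribution(self.allele_lengths, "allele_lengths")
        if any(l < 1 for l in self.allele_lengths):
            raise ConfigError("allele lengths must be >= 1")


DEFAULT_LOCUS_FLANKS = (
    "GTGCGCGAAGTGATCCAGAACCCGGG",  # upstream of the AR polyglutamine tract
    "CAAGAGACTAGCCCCAGGCAGCAG",
)


def simulate_repeat_reads(
    truth: RepeatTruth,
    locus,
    seed: int,
) -> list[tuple[str, str]]:
    """(read_id, sequence) reads over the repeat locus.

    Each spanning read is left_flank + unit*L + right_flank with L drawn from
    the allele mixture; substitution errors are injected per base at
    read_error_rate; a non_spanning_fraction of reads is truncated before the
    right flank.
    """
    import zlib

    sample_tag = zlib.crc32(truth.sample.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([seed, 707, sample_tag]))
    lengths = list(truth.allele_lengths)
    probs = [truth.allele_lengths[l] for l in lengths]
    reads: list[tuple[str, str]] = []
    for i in range(truth.n_reads):
        L = lengths[rng.choice(len(lengths), p=probs)]
        seq = locus.left_flank + locus.unit * L + locus.right_flank
        if truth.non_spanning_fraction > 0 and rng.random() < truth.non_spanning_fraction:
            cut = len(locus.left_flank) + len(locus.unit) * max(0, L - 1)
            seq = seq[: max(10, cut)]
        if truth.read_error_rate > 0:
            chars = list(seq)
            for j in range(len(chars)):
                if rng.random() < truth.read_error_rate:
                    chars[j] = str(rng.choice([b for b in "ACGT" if b != chars[j]]))
            seq = "".join(chars)
        reads.append((f"{truth.sample}.r{i}", seq))
    return reads


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


def simulate_repeat_cohort(
    samples: Sequence[SampleMeta],
    seed: int,
    mosaic_fraction: float = 0.36,
    n_reads: int = 60,
    read_error_rate: float = 0.0,
) -> list[RepeatTruth]:
    """Per-sample CAG allele mixtures: every sample has a primary allele in
    14..30 units; a mosaic_fraction of samples carries a second allele at
    least 3 units away mixed at 25-50%."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 808]))
    truths: list[RepeatTruth] = []
    for s in samples:
        primary = int(rng.integers(14, 31))
        if rng.random() < mosaic_fraction:
            offset = int(rng.integers(3, 9)) * (1 if rng.random() < 0.5 else -1)
            secondary = max(5, primary + offset)
            if secondary == primary:
                secondary = primary + 3
            frac = float(rng.uniform(0.25, 0.5))
            alleles = {primary: 1.0 - frac, secondary: frac}
        else:
            alleles = {primary: 1.0}
        truths.append(
            RepeatTruth(
                sample=s.sample_id,
                allele_lengths=alleles,
                n_reads=n_reads,
                read_error_rate=read_error_rate,
            )
        )
    return truths
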