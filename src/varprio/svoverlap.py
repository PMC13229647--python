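"""Structural-variant interval overlap and the bona-fide CNV filter.

Cohort SVs are intersected with a population SV table (gnomAD/dbVar style) on
0-based half-open intervals, any-overlap >= 1 bp by default with an optional
reciprocal-overlap requirement — the behavior of ``bedtools intersect``. A
cohort CNV is construed bona fide when its best-overlapping population SV is
demonstrably rare: if allele counts are available, the upper bound of the
90% Wilson score confidence interval for the population allele frequency must
lie below 0.02; with only a point frequency, that point must be below 0.02.
SVs carrying no frequency information at all cannot demonstrate rarity and
are excluded with reason ``no_frequency``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import norm

from .variants import NormalizedVariant

SV_TYPES = ("DEL", "DUP", "INS", "INV", "CNV-other")


@dataclass(frozen=True)
class SVInterval:
    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    sv_type: str = "CNV-other"
    source: str = "cohort"  # 'cohort' | 'population'
    pop_maf: float | None = None
    allele_count: int | None = None
    allele_number: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed interval {self.contig}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class BonaFideConfig:
    maf_threshold: float = 0.02
    ci_level: float = 0.90
    min_overlap_bp: int = 1
    reciprocal_fraction: float | None = None
    match_sv_type: bool = False

    def __post_init__(self) -> None:
        for name, v in (("maf_threshold", self.maf_threshold), ("ci_level", self.ci_level)):
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class OverlapPair:
    cohort: SVInterval
    population: SVInterval
    overlap_bp: int
    reciprocal_cohort: float  # overlap / cohort length
    reciprocal_population: float


def intersect_svs(
    cohort: Sequence[SVInterval],
    population: Sequence[SVInterval],
    config: BonaFideConfig = BonaFideConfig(),
) -> list[OverlapPair]:
    """All (cohort, population) pairs overlapping >= min_overlap_bp, with the
    reciprocal fraction enforced on both sides when configured."""
    trees: dict[str, IntervalTree] = {}
    for sv in population:
        trees.setdefault(sv.contig, IntervalTree()).addi(sv.start, sv.end, sv)
    pairs: list[OverlapPair] = []
    for c in cohort:
        tree = trees.get(c.contig)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(c.start, c.end)):
            p: SVInterval = hit.data
            ov = min(c.end, p.end) - max(c.start, p.start)
            if ov < config.min_overlap_bp:
                continue
            if config.match_sv_type and c.sv_type != p.sv_type:
                continue
            rc, rp = ov / c.length, ov / p.length
            if config.reciprocal_fraction is not None and (
                rc < config.reciprocal_fraction or rp < config.reciprocal_fraction
            ):
                continue
            pairs.append(OverlapPair(c, p, ov, rc, rp))
    return pairs


def wilson_upper(count: int, total: int, ci_level: float = 0.90) -> float:
    """Upper bound of the two-sided Wilson score interval for count/total."""
    if total <= 0:
        raise ValueError("total must be positive")
    z = norm.ppf(1 - (1 - ci_level) / 2)
    phat = count / total
    denom = 1 + z * z / total
    centre = phat + z * z / (2 * total)
    half = z * math.sqrt(phat * (1 - phat) / total + z * z / (4 * total * total))
    return (centre + half) / denom


def population_rarity_bound(sv: SVInterval, config: BonaFideConfig) -> float | None:
    """The frequency bound compared against maf_threshold, or None if no
    frequency evidence exists."""
    if sv.allele_count is not None and sv.allele_number:
        return wilson_upper(sv.allele_count, sv.allele_number, config.ci_level)
    if sv.pop_maf is not None and sv.allele_number:
        ac = round(sv.pop_maf * sv.allele_number)
        return wilson_upper(ac, sv.allele_number, config.ci_level)
    if sv.pop_maf is not None:
        return sv.pop_maf
    return None


def bona_fide_filter(
    pairs: Sequence[OverlapPair],
    config: BonaFideConfig = BonaFideConfig(),
) -> tuple[list[SVInterval], dict[SVInterval, str]]:
    """Bona-fide cohort CNVs plus per-CNV exclusion reasons.

    A cohort CNV qualifies when its best-overlapping (largest-overlap)
    population SV has a rarity bound below maf_threshold. CNVs whose best
    overlap carries no frequency evidence are excluded as ``no_frequency``.
    """
    best: dict[SVInterval, OverlapPair] = {}
    for pair in pairs:
        cur = best.get(pair.cohort)
        if cur is None or pair.overlap_bp > cur.overlap_bp:
            best[pair.cohort] = pair
    bona_fide: list[SVInterval] = []
    reasons: dict[SVInterval, str] = {}
    for cnv, pair in best.items():
        bound = population_rarity_bound(pair.population, config)
        if bound is None:
            reasons[cnv] = "no_frequency"
        elif bound < config.maf_threshold:
            bona_fide.append(cnv)
        else:
            reasons[cnv] = "too_common"
    bona_fide.sort(key=lambda s: (s.contig, s.start, s.end))
    return bona_fide, reasons


def snv_in_cnv(
    snvs: Sequence[NormalizedVariant],
    cnvs: Sequence[SVInterval],
) -> list[tuple[NormalizedVariant, SVInterval]]:
    """Co-localized (SNV, CNV) pairs: the 1-based SNV position converted to
    0-based must fall inside the half-open CNV interval."""
    trees: dict[str, IntervalTree] = {}
    for sv in cnvs:
        trees.setdefault(sv.contig, IntervalTree()).addi(sv.start, sv.end, sv)
    out: list[tuple[NormalizedVariant, SVInterval]] = []
    for snv in snvs:
        tree = trees.get(snv.contig)
        if tree is None:
            continue
        pos0 = snv.position - 1
        for hit in sorted(tree.at(pos0)):
            out.append((snv, hit.data))
    return out


def per_chromosome_counts(cnvs: Sequence[SVInterval]) -> pd.DataFrame:
    """Per-chromosome CNV count table (the tabular stand-in for an ideogram)."""
    counts: dict[str, int] = {}
    for sv in cnvs:
        counts[sv.contig] = counts.get(sv.contig, 0) + 1
    return pd.DataFrame(
        sorted(counts.items()), columns=["contig", "n_cnvs"]
    )


def load_sv_table(path: str | Path, source: str) -> list[SVInterval]:
    """BED-like TSV: contig, start, end, sv_type, pop_maf, allele_count,
    allele_number (trailing columns optional, 'NR'/'.'/empty -> absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    out: list[SVInterval] = []

    def opt(row, col, conv):
        v = getattr(row, col, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        s = str(v).strip()
        if s in ("", "NR", "NA", "."):
            return None
        return conv(s)

    for row in df.itertuples(index=False):
        out.append(
            SVInterval(
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                sv_type=str(getattr(row, "sv_type", "CNV-other")),
                source=source,
                pop_maf=opt(row, "pop_maf", float),
                allele_count=opt(row, "allele_count", lambda s: int(float(s))),
                allele_number=opt(row, "allele_number", lambda s: int(float(s))),
            )
        )
    return out
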