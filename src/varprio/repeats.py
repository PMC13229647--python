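"""AR CAG-repeat profiling from flank-anchored reads.

The androgen receptor gene carries a polymorphic CAG tract; shorter tracts
(<= 18 units) are associated with higher-grade prostate cancer, and multiple
distinct tract lengths within one sample indicate somatic mosaicism. Repeat
length is measured by an exact, deterministic rule: a read spans the locus iff
it contains the left flank followed downstream by the right flank, and the
enclosed segment is a whole number of exact repeat-unit copies. Interrupted
tracts, missing flanks, and out-of-order flanks yield non-spanning
observations with reason codes; they never contribute a length.

An allele is *supported* when enough spanning reads (count and fraction
thresholds) agree on its length; a sample is *mosaic* when two or more alleles
are supported, and *uncallable* below a minimum spanning-read depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .stratify import SampleMeta


@dataclass(frozen=True)
class RepeatLocus:
    contig: str = "AR"
    unit: str = "CAG"
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if len(self.unit) < 1:
            raise ValueError("repeat unit must be non-empty")
        if len(self.left_flank) < 10 or len(self.right_flank) < 10:
            raise ValueError("flanks must be >= 10 bases")
        if self.left_flank.endswith(self.unit) or self.right_flank.startswith(self.unit):
            raise ValueError("flank ends must not carry a full copy of the repeat unit")


@dataclass(frozen=True)
class RepeatObservation:
    sample: str
    read_id: str
    spanning: bool
    repeat_count: int | None = None
    reason: str | None = None  # no_left_flank | no_right_flank | interrupted

    def __post_init__(self) -> None:
        if self.spanning and self.repeat_count is None:
            raise ValueError("spanning observation requires a repeat count")


@dataclass(frozen=True)
class MosaicismParams:
    min_reads_per_allele: int = 3
    min_allele_fraction: float = 0.2
    short_threshold: int = 18
    min_total_spanning: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.min_allele_fraction < 1.0):
            raise ValueError("min_allele_fraction must be in (0, 1)")
        if min(self.min_reads_per_allele, self.short_threshold, self.min_total_spanning) < 1:
            raise ValueError("count thresholds must be >= 1")


@dataclass
class RepeatProfile:
    sample: str
    histogram: dict[int, int]
    supported_alleles: list[int]
    mosaic: bool
    risk: str  # 'high' | 'not-elevated' | 'uncallable'

    @property
    def n_spanning(self) -> int:
        return sum(self.histogram.values())


def count_repeat_units(
    read: str, locus: RepeatLocus, sample: str = "", read_id: str = ""
) -> RepeatObservation:
    """Measure one read against the locus.

    Exact search: first occurrence of the left flank, then the first
    occurrence of the right flank downstream of it; the enclosed segment must
    be ``unit`` repeated a whole number of times (zero allowed).
    """
    seq = read.upper()
    li = seq.find(locus.left_flank.upper())
    if li < 0:
        return RepeatObservation(sample, read_id, spanning=False, reason="no_left_flank")
    start = li + len(locus.left_flank)
    ri = seq.find(locus.right_flank.upper(), start)
    if ri < 0:
        return RepeatObservation(sample, read_id, spanning=False, reason="no_right_flank")
    segment = seq[start:ri]
    unit = locus.unit.upper()
    n, rem = divmod(len(segment), len(unit))
    if rem != 0 or segment != unit * n:
        return RepeatObservation(sample, read_id, spanning=False, reason="interrupted")
    return RepeatObservation(sample, read_id, spanning=True, repeat_count=n)


def build_profile(
    observations: Iterable[RepeatObservation],
    params: MosaicismParams = MosaicismParams(),
) -> RepeatProfile:
    """Histogram spanning reads, call supported alleles, mosaicism and risk."""
    hist: Counter[int] = Counter()
    sample = ""
    for obs in observations:
        sample = obs.sample or sample
        if obs.spanning:
            hist[obs.repeat_count] += 1
    total = sum(hist.values())
    if total < params.min_total_spanning:
        return RepeatProfile(sample, dict(hist), [], mosaic=False, risk="uncallable")
    supported = sorted(
        length
        for length, n in hist.items()
        if n >= params.min_reads_per_allele and n / total >= params.min_allele_fraction
    )
    mosaic = len(supported) >= 2
    if not supported:
        risk = "uncallable"
    elif any(a <= params.short_threshold for a in supported):
        risk = "high"
    else:
        risk = "not-elevated"
    return RepeatProfile(sample, dict(sorted(hist.items())), supported, mosaic, risk)


def classify_risk(profile: RepeatProfile, params: MosaicismParams = MosaicismParams()) -> str:
    """High risk iff any supported allele is <= the short threshold (inclusive)."""
    if profile.risk == "uncallable" or not profile.supported_alleles:
        return "uncallable"
    if any(a <= params.short_threshold for a in profile.supported_alleles):
        return "high"
    return "not-elevated"


def profiles_from_reads(
    reads_by_sample: Mapping[str, Sequence[str]],
    locus: RepeatLocus,
    params: MosaicismParams = MosaicismParams(),
) -> list[RepeatProfile]:
    profiles = []
    for sample in sorted(reads_by_sample):
        obs = [
            count_repeat_units(seq, locus, sample=sample, read_id=f"{sample}.r{i}")
            for i, seq in enumerate(reads_by_sample[sample])
        ]
        profiles.append(build_profile(obs, params))
    return profiles


def read_fastx(path: str | Path) -> list[tuple[str, str]]:
    """(read_id, sequence) pairs from FASTA or FASTQ, plain text."""
    pairs: list[tuple[str, str]] = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        return pairs
    if lines[0].startswith("@"):
        for i in range(0, len(lines) - 1, 4):
            pairs.append((lines[i][1:].split()[0], lines[i + 1]))
    else:
        name, chunks = None, []
        for line in lines:
            if line.startswith(">"):
                if name is not None:
                    pairs.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line.strip())
        if name is not None:
            pairs.append((name, "".join(chunks)))
    return pairs


def cohort_mosaicism_summary(
    profiles: Sequence[RepeatProfile],
    samples: Sequence[SampleMeta] | None = None,
) -> dict:
    """Mosaic fraction among callable samples (and among all samples), with an
    optional per-grade-group breakdown."""
    callable_profiles = [p for p in profiles if p.risk != "uncallable"]
    n_mosaic = sum(p.mosaic for p in callable_profiles)
    summary: dict = {
        "n_samples": len(profiles),
        "n_callable": len(callable_profiles),
        "n_mosaic": n_mosaic,
        "mosaic_fraction_callable": (n_mosaic / len(callable_profiles)) if callable_profiles else None,
        "mosaic_fraction_all": (n_mosaic / len(profiles)) if profiles else None,
        "empty": not callable_profiles,
    }
    if samples is not None:
        grade = {s.sample_id: s.grade_group for s in samples}
        breakdown: dict[str, dict[str, int]] = {}
        for p in callable_profiles:
            g = grade.get(p.sample, "unknown")
            d = breakdown.setdefault(g, {"callable": 0, "mosaic": 0, "high_risk": 0})
            d["callable"] += 1
            d["mosaic"] += int(p.mosaic)
            d["high_risk"] += int(p.risk == "high")
        summary["by_grade_group"] = breakdown
    return summary
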