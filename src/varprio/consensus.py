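"""Cross-caller consensus extraction.

Per-caller VCFs are read, split to biallelic records, normalized to canonical
keys, quality-filtered (DP >= 20, GQ >= 20, het AB >= 0.2, FILTER == PASS by
default), and intersected: a key is retained for a sample only when at least
``required_callers`` callers (default: all of them) report the identical
normalized (contig, position, ref, alt). Genotype is assigned by majority vote
across supporting callers; a tie is retained but flagged discordant and is
excluded from downstream zygosity stratification.

Filtering happens per caller *before* the intersection (``filter_after=True``
flips the order for sensitivity analysis).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from .variants import (
    NormalizedVariant,
    RawCall,
    VariantError,
    compute_ab,
    normalize,
    split_multiallelic,
)


@dataclass(frozen=True)
class QualityThresholds:
    """Call-level quality gates applied per caller."""

    min_dp: int = 20
    min_gq: float = 20.0
    min_het_ab: float = 0.2
    require_pass: bool = True
    # lenient mode for shallow-coverage dialects that omit DP/GQ
    missing_field_passes: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_het_ab <= 0.5):
            raise ValueError(f"min_het_ab must be in [0, 0.5], got {self.min_het_ab}")


@dataclass
class FilterResult:
    passed: bool
    reasons: frozenset[str]


@dataclass
class ConsensusVariant:
    key: NormalizedVariant
    sample: str
    supporting_callers: frozenset[str]
    genotype: str  # 'het' | 'hom_alt'
    discordant_gt: bool
    evidence: dict[str, dict]  # caller -> {DP, GQ, AB}

    @property
    def min_dp(self) -> int | None:
        vals = [e["DP"] for e in self.evidence.values() if e.get("DP") is not None]
        return min(vals) if vals else None

    @property
    def min_gq(self) -> float | None:
        vals = [e["GQ"] for e in self.evidence.values() if e.get("GQ") is not None]
        return min(vals) if vals else None


def apply_quality_filters(call: RawCall, thresholds: QualityThresholds) -> FilterResult:
    """Pass/fail with *all* failing reason codes accumulated, not just the first.

    Reason codes: low_dp, low_gq, low_ab, not_pass, missing_field.
    AB is checked for heterozygous genotypes only, as the thresholds are stated.
    """
    reasons: set[str] = set()
    if call.dp is None:
        if not thresholds.missing_field_passes:
            reasons.add("missing_field")
    elif call.dp < thresholds.min_dp:
        reasons.add("low_dp")
    if call.gq is None:
        if not thresholds.missing_field_passes:
            reasons.add("missing_field")
    elif call.gq < thresholds.min_gq:
        reasons.add("low_gq")
    if call.zygosity() == "het":
        ab = compute_ab(call)
        if ab is None:
            if not thresholds.missing_field_passes:
                reasons.add("missing_field")
        elif ab < thresholds.min_het_ab:
            reasons.add("low_ab")
    if thresholds.require_pass and call.filter not in ("PASS", ".", ""):
        reasons.add("not_pass")
    return FilterResult(passed=not reasons, reasons=frozenset(reasons))


def read_caller_vcf(path: str | Path, caller: str, sample: str | None = None) -> list[RawCall]:
    """Read a single-sample VCF (v4.2, plain text or bgzipped) into RawCalls."""
    calls: list[RawCall] = []
    with pysam.VariantFile(str(path)) as vf:
        vcf_samples = list(vf.header.samples)
        if sample is None:
            if len(vcf_samples) != 1:
                raise ValueError(f"{path}: expected single-sample VCF, found {vcf_samples}")
            sample = vcf_samples[0]
        for rec in vf:
            if not rec.alts:
                continue
            fmt = rec.samples[sample]
            gt = fmt.get("GT")
            if gt is not None and (len(gt) != 2 or any(a is None for a in gt)):
                gt = None
            ad = fmt.get("AD")
            filt = ";".join(rec.filter.keys()) if list(rec.filter.keys()) else "."
            calls.append(
                RawCall(
                    contig=rec.contig,
                    position=rec.pos,
                    ref=rec.ref,
                    alts=list(rec.alts),
                    filter=filt,
                    caller=caller,
                    sample=sample,
                    gt=tuple(gt) if gt is not None else None,
                    dp=fmt.get("DP"),
                    gq=fmt.get("GQ"),
                    ad=list(ad) if ad is not None else None,
                )
            )
    return calls


def normalize_calls(
    calls: Iterable[RawCall], reference
) -> list[tuple[NormalizedVariant, RawCall]]:
    """Split multiallelics, drop hom-ref decompositions, normalize each key."""
    out: list[tuple[NormalizedVariant, RawCall]] = []
    for call in calls:
        for bi in split_multiallelic(call):
            if bi.zygosity() == "hom_ref" and not bi.cross_alt:
                continue
            out.append((normalize(bi, reference), bi))
    return out


def consensus_across_callers(
    caller_calls: Mapping[str, Sequence[tuple[NormalizedVariant, RawCall]]],
    required_callers: int | None = None,
) -> list[ConsensusVariant]:
    """Strict coordinate- and allele-based intersection across callers.

    ``caller_calls`` maps caller label -> normalized (key, call) pairs for one
    sample. A key is retained iff supported by >= required_callers distinct
    callers (default: every caller present). Output is sorted by key.
    """
    n_callers = len(caller_calls)
    if required_callers is None:
        required_callers = n_callers
    if required_callers > n_callers:
        raise ValueError(
            f"required_callers={required_callers} exceeds the {n_callers} caller sets given"
        )

    by_key: dict[NormalizedVariant, dict[str, RawCall]] = {}
    for caller, pairs in caller_calls.items():
        for key, call in pairs:
            by_key.setdefault(key, {})[caller] = call

    sample = next(
        (c.sample for pairs in caller_calls.values() for _, c in pairs), None
    )
    out: list[ConsensusVariant] = []
    for key in sorted(by_key):
        support = by_key[key]
        if len(support) < required_callers:
            continue
        votes = Counter(
            c.zygosity() for c in support.values() if c.zygosity() in ("het", "hom_alt")
        )
        if not votes:
            genotype, discordant = "het", True
        else:
            top = votes.most_common()
            genotype = top[0][0]
            discordant = len(top) > 1 and top[0][1] == top[1][1]
            if discordant:
                genotype = "het"  # deterministic placeholder; flagged and excluded downstream
        evidence = {
            caller: {"DP": c.dp, "GQ": c.gq, "AB": compute_ab(c)}
            for caller, c in support.items()
        }
        out.append(
            ConsensusVariant(
                key=key,
                sample=sample if sample is not None else "",
                supporting_callers=frozenset(support),
                genotype=genotype,
                discordant_gt=discordant,
                evidence=evidence,
            )
        )
    return out


def sample_consensus(
    vcf_paths: Mapping[str, str | Path],
    reference,
    thresholds: QualityThresholds | None = None,
    required_callers: int | None = None,
    sample: str | None = None,
    filter_after: bool = False,
    funnel=None,
) -> list[ConsensusVariant]:
    """End-to-end consensus for one sample from per-caller VCF paths.

    Pipeline order: read -> split/normalize -> quality filter -> intersect
    (``filter_after`` applies quality gates to the intersection instead).
    ``funnel`` is an optional FunnelReport collecting per-stage counts.
    """
    thresholds = thresholds or QualityThresholds()
    normalized: dict[str, list[tuple[NormalizedVariant, RawCall]]] = {}
    n_in = n_filtered = 0
    reason_counts: Counter[str] = Counter()
    for caller, path in vcf_paths.items():
        pairs = normalize_calls(read_caller_vcf(path, caller, sample), reference)
        n_in += len(pairs)
        if not filter_after:
            kept = []
            for key, call in pairs:
                res = apply_quality_filters(call, thresholds)
                if res.passed:
                    kept.append((key, call))
                else:
                    # funnel conservation: one primary reason per dropped record
                    reason_counts[min(res.reasons)] += 1
            n_filtered += len(kept)
            normalized[caller] = kept
        else:
            n_filtered += len(pairs)
            normalized[caller] = list(pairs)
    result = consensus_across_callers(normalized, required_callers)
    if filter_after:
        kept_res = []
        for cv in result:
            fails = set()
            for caller in cv.supporting_callers:
                call = dict(normalized[caller])[cv.key]
                r = apply_quality_filters(call, thresholds)
                fails |= set(r.reasons)
            if not fails:
                kept_res.append(cv)
            else:
                reason_counts[min(fails)] += 1
        result = kept_res
    if funnel is not None:
        if not filter_after:
            funnel.add("quality_filter", n_in, n_filtered, dict(reason_counts))
            funnel.add(
                "consensus_intersection",
                n_filtered,
                len(result),
                {"insufficient_caller_support": n_filtered - len(result)},
            )
        else:
            n_intersected = len(result) + sum(reason_counts.values())
            funnel.add(
                "consensus_intersection",
                n_in,
                n_intersected,
                {"insufficient_caller_support": n_in - n_intersected},
            )
            funnel.add("quality_filter", n_intersected, len(result), dict(reason_counts))
    return result
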