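"""Variant representation: raw calls, normalization, splitting, allelic balance.

The canonical join key used throughout the package is a :class:`NormalizedVariant`
— a biallelic (contig, 1-based position, ref, alt) tuple in minimal left-aligned
form. Every matching step (cross-caller consensus, clinical annotation, population
frequency, GWAS catalog) joins on this key and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

VALID_BASES = frozenset("ACGTN")


class VariantError(ValueError):
    """Malformed record, reference mismatch, or boundary underflow."""


@dataclass(frozen=True, order=True)
class NormalizedVariant:
    """Canonical biallelic variant key after left-alignment and allele trimming.

    Coordinates are 1-based inclusive (VCF convention). Two variants are the
    same biological event iff their keys compare equal.
    """

    contig: str
    position: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        for allele in (self.ref, self.alt):
            if not allele or set(allele) - VALID_BASES:
                raise VariantError(f"invalid allele {allele!r} at {self.contig}:{self.position}")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt at {self.contig}:{self.position}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class RawCall:
    """One caller's record for one sample, possibly multiallelic."""

    contig: str
    position: int
    ref: str
    alts: list[str]
    filter: str
    caller: str
    sample: str
    gt: tuple[int, int] | None = None
    dp: int | None = None
    gq: float | None = None
    ad: list[int] | None = None
    # set by split_multiallelic when the source genotype carried another alt
    cross_alt: bool = False

    def zygosity(self) -> str | None:
        """'het' / 'hom_alt' / 'hom_ref' for a biallelic call, None if no GT."""
        if self.gt is None:
            return None
        a, b = self.gt
        if a == b == 0:
            return "hom_ref"
        if a == b:
            return "hom_alt"
        return "het"


def split_multiallelic(call: RawCall) -> list[RawCall]:
    """Decompose a multiallelic record into one biallelic record per alt.

    AD is decomposed positionally as [ref_depth, that_alt_depth]; the original
    ref depth is kept without rescaling. DP, GQ and FILTER are copied. Genotypes
    naming another alt are recoded as het-carrying-this-alt with ``cross_alt``
    set, so downstream zygosity logic can exclude them.
    """
    if not call.alts:
        raise VariantError(f"no alt alleles at {call.contig}:{call.position}")
    if call.ad is not None and len(call.ad) != 1 + len(call.alts):
        raise VariantError(
            f"AD length {len(call.ad)} != 1 + {len(call.alts)} alts at "
            f"{call.contig}:{call.position}"
        )
    if len(call.alts) == 1:
        return [call]
    out: list[RawCall] = []
    for i, alt in enumerate(call.alts, start=1):
        ad = [call.ad[0], call.ad[i]] if call.ad is not None else None
        gt = call.gt
        cross = False
        if gt is not None:
            carried = [a for a in gt if a == i]
            others = [a for a in gt if a not in (0, i)]
            if carried and others:
                gt, cross = (0, 1), True  # e.g. GT=1/2 seen from either alt
            elif carried:
                gt = (0, 1) if len(carried) == 1 else (1, 1)
            else:
                gt, cross = (0, 0), bool(others)
        out.append(
            replace(call, alts=[alt], ad=ad, gt=gt, cross_alt=cross)
        )
    return out


def compute_ab(call: RawCall) -> float | None:
    """Allelic balance AB = alt_depth / (ref_depth + alt_depth) from AD.

    Returns None when AD is absent or the AD total depth is zero; the caller
    decides whether that constitutes a filter failure.
    """
    if call.ad is None or len(call.ad) < 2:
        return None
    ref_d, alt_d = call.ad[0], call.ad[1]
    total = ref_d + alt_d
    if total <= 0:
        return None
    return alt_d / total


def _trim_and_shift(
    contig: str, pos: int, ref: str, alt: str, fetch
) -> tuple[int, str, str]:
    """Minimal left-aligned representation (shared-suffix trim, left shift,
    shared-prefix trim). ``fetch(start0, end0)`` returns reference sequence
    over a 0-based half-open window."""
    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            # one allele would empty out: extend left with the preceding base
            if pos == 1:
                raise VariantError(
                    f"left-alignment underflow at {contig}:{pos} {ref}>{alt}"
                )
            prev = fetch(pos - 2, pos - 1).upper()
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize(call: RawCall, reference) -> NormalizedVariant:
    """Return the unique minimal left-aligned key for a biallelic call.

    ``reference`` is a pyfaidx.Fasta (or any mapping of contig -> indexable
    sequence). The reference is consulted both to verify the stated ref allele
    and to extend alleles leftward during left-alignment, so the result is
    invariant to the input representation.

    Raises VariantError on reference mismatch or position-1 underflow.
    """
    if len(call.alts) != 1:
        raise VariantError("normalize requires a biallelic call; split first")
    contig, pos = call.contig, call.position
    ref, alt = call.ref.upper(), call.alts[0].upper()

    seq = reference[contig]

    def fetch(start0: int, end0: int) -> str:
        return str(seq[start0:end0])

    observed = fetch(pos - 1, pos - 1 + len(ref)).upper()
    if observed != ref:
        raise VariantError(
            f"reference mismatch at {contig}:{pos}: expected {ref}, found {observed}"
        )
    pos, ref, alt = _trim_and_shift(contig, pos, ref, alt, fetch)
    return NormalizedVariant(contig=contig, position=pos, ref=ref, alt=alt)


def right_shift(contig: str, pos: int, ref: str, alt: str, reference) -> tuple[int, str, str]:
    """Right-most equivalent representation of an indel (the mirror of
    left-alignment). Used by the synthetic caller emitter to exercise the
    normalizer; real callers differ in exactly this way inside repeat tracts."""
    seq = reference[contig]
    contig_len = len(seq)

    def fetch(start0: int, end0: int) -> str:
        return str(seq[start0:end0]).upper()

    ref, alt = ref.upper(), alt.upper()
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        elif ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
            end0 = pos - 1 + len(ref)
            if end0 >= contig_len:
                break
            nxt = fetch(end0, end0 + 1)
            ref, alt = ref[1:] + nxt, alt[1:] + nxt
            pos += 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    return pos, ref, alt
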