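"""Clinical annotation matching and somatic/germline partitioning.

Consensus variants are matched against local ClinVar-/COSMIC-/dbVar-style TSV
tables by exact (contig, position, alternate allele) with a ref consistency
check — rsIDs are never used as join keys. Classification strings are mapped
into a closed vocabulary via a documented synonym table. The cohort-level
somatic call combines annotation origin with the presence rule: somatic
variants must be absent from every BPH sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .consensus import ConsensusVariant
from .variants import NormalizedVariant

logger = logging.getLogger(__name__)

CLASSIFICATIONS = (
    "Pathogenic",
    "Likely-pathogenic",
    "Likely-benign",
    "Benign",
    "VUS",
    "Conflicting",
)

#: raw classification string (case-folded) -> closed vocabulary
CLASSIFICATION_SYNONYMS = {
    "pathogenic": "Pathogenic",
    "likely-pathogenic": "Likely-pathogenic",
    "likely pathogenic": "Likely-pathogenic",
    "likely_pathogenic": "Likely-pathogenic",
    "likely-benign": "Likely-benign",
    "likely benign": "Likely-benign",
    "benign": "Benign",
    "vus": "VUS",
    "variant of uncertain significance": "VUS",
    "uncertain significance": "VUS",
    "conflicting": "Conflicting",
    "conflicting pathogenicity": "Conflicting",
    "conflicting interpretations of pathogenicity": "Conflicting",
}

ORIGINS = ("somatic", "germline", "both", "unknown")


class AnnotationSchemaError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationRecord:
    key: NormalizedVariant
    classification: str
    origin: str = "unknown"
    source: str = "clinvar-like"
    rsid: str | None = None
    gene: str | None = None
    # extra alts listed on the same table row (kept for provenance, never a join key)
    alt_secondary: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"unknown classification {self.classification!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")


@dataclass
class ClassifiedVariant:
    consensus: ConsensusVariant
    annotation: AnnotationRecord | None
    cohort_origin_call: str = "unresolved"  # somatic | germline | unresolved

    @property
    def key(self) -> NormalizedVariant:
        return self.consensus.key

    @property
    def classification(self) -> str | None:
        return self.annotation.classification if self.annotation else None


def map_classification(raw: str) -> str:
    norm = CLASSIFICATION_SYNONYMS.get(raw.strip().casefold())
    if norm is None:
        raise ValueError(f"unmappable classification string {raw!r}")
    return norm


REQUIRED_COLUMNS = ("contig", "position", "ref", "alt", "classification")


def load_annotation_table(path: str | Path, source: str = "clinvar-like") -> list[AnnotationRecord]:
    """Parse an annotation TSV into validated records.

    Required columns: contig, position, ref, alt, classification; optional:
    rsid, gene, origin. A row whose alt field lists several alleles separated
    by '/' is keyed by the first allele (the remainder is retained in
    ``alt_secondary``). Duplicate keys with conflicting classifications are
    collapsed to a single Conflicting record. Unknown classification strings
    raise with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationSchemaError(f"{path}: missing required column(s) {missing}")
    records: list[AnnotationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            cls = map_classification(row.classification)
        except ValueError as exc:
            raise AnnotationSchemaError(f"{path} row {i}: {exc}") from exc
        alts = str(row.alt).split("/")
        origin = getattr(row, "origin", None)
        origin = origin.strip().casefold() if isinstance(origin, str) else "unknown"
        if origin not in ORIGINS:
            raise AnnotationSchemaError(f"{path} row {i}: unknown origin {origin!r}")
        rsid = getattr(row, "rsid", None)
        gene = getattr(row, "gene", None)
        records.append(
            AnnotationRecord(
                key=NormalizedVariant(
                    contig=str(row.contig),
                    position=int(str(row.position).replace(",", "")),
                    ref=str(row.ref),
                    alt=alts[0],
                ),
                classification=cls,
                origin=origin,
                source=source,
                rsid=rsid if isinstance(rsid, str) else None,
                gene=gene if isinstance(gene, str) else None,
                alt_secondary=tuple(alts[1:]),
            )
        )
    # collapse duplicate keys with disagreeing classifications
    by_key: dict[NormalizedVariant, AnnotationRecord] = {}
    for rec in records:
        prev = by_key.get(rec.key)
        if prev is None:
            by_key[rec.key] = rec
        elif prev.classification != rec.classification:
            by_key[rec.key] = AnnotationRecord(
                key=rec.key,
                classification="Conflicting",
                origin=prev.origin if prev.origin == rec.origin else "unknown",
                source=source,
                rsid=prev.rsid,
                gene=prev.gene,
            )
    # preserve input order
    seen: set[NormalizedVariant] = set()
    out = []
    for rec in records:
        if rec.key not in seen:
            seen.add(rec.key)
            out.append(by_key[rec.key])
    return out


def match_variants(
    consensus: Sequence[ConsensusVariant],
    annotations: Sequence[AnnotationRecord],
) -> list[ClassifiedVariant]:
    """Exact (contig, position, alt) match with a ref consistency check.

    A position+alt match whose ref disagrees is reported as a data
    inconsistency and NOT matched. Unmatched consensus variants are carried
    forward with annotation=None.
    """
    index: dict[tuple[str, int, str], AnnotationRecord] = {
        (a.key.contig, a.key.position, a.key.alt): a for a in annotations
    }
    out: list[ClassifiedVariant] = []
    for cv in consensus:
        ann = index.get((cv.key.contig, cv.key.position, cv.key.alt))
        if ann is not None and ann.key.ref != cv.key.ref:
            warnings.warn(
                f"ref disagreement at {cv.key.contig}:{cv.key.position} "
                f"alt {cv.key.alt}: consensus {cv.key.ref} vs annotation {ann.key.ref}",
                stacklevel=2,
            )
            ann = None
        out.append(ClassifiedVariant(consensus=cv, annotation=ann))
    return out


def filter_by_classification(classified: Sequence, keep: Iterable[str]) -> list:
    """Retain records whose mapped classification is in ``keep``.

    Accepts ClassifiedVariant or bare AnnotationRecord sequences. Records with
    no annotation are dropped (their classification is unknowable).
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must not be empty")
    unknown = keep - set(CLASSIFICATIONS)
    if unknown:
        raise ValueError(f"unknown classification(s) in keep set: {sorted(unknown)}")
    out = []
    for rec in classified:
        cls = rec.classification if isinstance(rec, (AnnotationRecord, ClassifiedVariant)) else None
        if cls in keep:
            out.append(rec)
    return out


def classification_counts(classified: Sequence) -> dict[str, int]:
    counts = {c: 0 for c in CLASSIFICATIONS}
    for rec in classified:
        cls = rec.classification
        if cls is not None:
            counts[cls] += 1
    return counts


def partition_somatic_germline(
    classified: Sequence[ClassifiedVariant],
    samples: Sequence,
) -> tuple[list[ClassifiedVariant], list[ClassifiedVariant], list[ClassifiedVariant]]:
    """Partition classified variants into (somatic, germline, unresolved).

    A variant key's carrier set is the set of samples whose consensus carries
    the key. somatic: annotation origin supports somatic AND no BPH carrier;
    a somatic-annotated variant seen in a BPH sample is demoted to unresolved;
    germline: annotation origin germline, or (origin unknown and a BPH carrier
    exists). Everything else is unresolved. The three lists are disjoint and
    exhaustive.
    """
    bph = {getattr(s, "sample_id", s) for s in samples if getattr(s, "tissue", None) == "BPH"}
    carriers: dict[NormalizedVariant, set[str]] = {}
    for cv in classified:
        carriers.setdefault(cv.key, set()).add(cv.consensus.sample)
    somatic, germline, unresolved = [], [], []
    for cv in classified:
        origin = cv.annotation.origin if cv.annotation else "unknown"
        has_bph = bool(carriers[cv.key] & bph)
        if origin in ("somatic", "both"):
            if not has_bph:
                cv.cohort_origin_call = "somatic"
                somatic.append(cv)
            else:
                cv.cohort_origin_call = "unresolved"
                unresolved.append(cv)
        elif origin == "germline" or has_bph:
            cv.cohort_origin_call = "germline"
            germline.append(cv)
        else:
            cv.cohort_origin_call = "unresolved"
            unresolved.append(cv)
    return somatic, germline, unresolved
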