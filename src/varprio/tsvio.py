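"""Flat-file round-tripping for pipeline stage outputs (TSV with headers)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import AnnotationRecord, ClassifiedVariant
from .consensus import ConsensusVariant
from .variants import NormalizedVariant

CONSENSUS_COLUMNS = [
    "sample", "contig", "position", "ref", "alt",
    "callers", "genotype", "discordant_gt", "min_dp", "min_gq", "ab",
]


def write_consensus_tsv(variants, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for cv in variants:
        abs_ = [e.get("AB") for e in cv.evidence.values() if e.get("AB") is not None]
        rows.append(
            {
                "sample": cv.sample,
                "contig": cv.key.contig,
                "position": cv.key.position,
                "ref": cv.key.ref,
                "alt": cv.key.alt,
                "callers": ",".join(sorted(cv.supporting_callers)),
                "genotype": cv.genotype,
                "discordant_gt": int(cv.discordant_gt),
                "min_dp": cv.min_dp if cv.min_dp is not None else "",
                "min_gq": cv.min_gq if cv.min_gq is not None else "",
                "ab": f"{sum(abs_) / len(abs_):.4f}" if abs_ else "",
            }
        )
    pd.DataFrame(rows, columns=CONSENSUS_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_consensus_tsv(path: str | Path) -> list[ConsensusVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str})
    out: list[ConsensusVariant] = []
    for row in df.itertuples(index=False):
        callers = frozenset(str(row.callers).split(",")) if isinstance(row.callers, str) else frozenset()
        dp = None if pd.isna(row.min_dp) else int(row.min_dp)
        gq = None if pd.isna(row.min_gq) else float(row.min_gq)
        ab = None if pd.isna(row.ab) else float(row.ab)
        out.append(
            ConsensusVariant(
                key=NormalizedVariant(str(row.contig), int(row.position), str(row.ref), str(row.alt)),
                sample=str(row.sample),
                supporting_callers=callers,
                genotype=str(row.genotype),
                discordant_gt=bool(row.discordant_gt),
                evidence={"summary": {"DP": dp, "GQ": gq, "AB": ab}},
            )
        )
    return out


CLASSIFIED_COLUMNS = [
    "sample", "contig", "position", "ref", "alt", "genotype", "discordant_gt",
    "classification", "annotation_origin", "cohort_origin_call",
]


def write_classified_tsv(classified, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for cv in classified:
        rows.append(
            {
                "sample": cv.consensus.sample,
                "contig": cv.key.contig,
                "position": cv.key.position,
                "ref": cv.key.ref,
                "alt": cv.key.alt,
                "genotype": cv.consensus.genotype,
                "discordant_gt": int(cv.consensus.discordant_gt),
                "classification": cv.classification or "",
                "annotation_origin": cv.annotation.origin if cv.annotation else "",
                "cohort_origin_call": cv.cohort_origin_call,
            }
        )
    pd.DataFrame(rows, columns=CLASSIFIED_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_classified_tsv(path: str | Path) -> list[ClassifiedVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "contig": str})
    out: list[ClassifiedVariant] = []
    for row in df.itertuples(index=False):
        key = NormalizedVariant(str(row.contig), int(row.position), str(row.ref), str(row.alt))
        cls = None if pd.isna(row.classification) else str(row.classification)
        origin = "unknown" if pd.isna(row.annotation_origin) else str(row.annotation_origin)
        annotation = (
            AnnotationRecord(key=key, classification=cls, origin=origin)
            if cls
            else None
        )
        cv = ConsensusVariant(
            key=key,
            sample=str(row.sample),
            supporting_callers=frozenset(),
            genotype=str(row.genotype),
            discordant_gt=bool(row.discordant_gt),
            evidence={},
        )
        call = "unresolved" if pd.isna(row.cohort_origin_call) else str(row.cohort_origin_call)
        out.append(ClassifiedVariant(consensus=cv, annotation=annotation, cohort_origin_call=call))
    return out
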