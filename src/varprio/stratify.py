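"""Cohort stratification: occurrence ranking and zygosity-by-grade association.

Variants are ranked by how many samples carry them (unique = 1 carrier,
shared >= 2). For classified pathogenic variants, a per-variant 2x2 table of
{hom_alt, het} x {high-grade, lower/BPH} is built — high grade meaning Gleason
patterns 4+4 and 4+3 exactly — with concordance defined as every high-grade
carrier homozygous-alt and every lower-grade/BPH carrier heterozygous, the
pattern reported for pathogenic somatic variants in this cohort. Association
is tested with the two-sided exact conditional (Fisher) test on the table.
Carriers with discordant genotype votes are excluded from the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .annotation import ClassifiedVariant
from .variants import NormalizedVariant

HIGH_GRADE_PATTERNS = {(4, 4), (4, 3)}
MALIGNANT_MIN_SCORE = 6


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    tissue: str  # 'malignant' | 'BPH'
    gleason_primary: int
    gleason_secondary: int

    def __post_init__(self) -> None:
        if self.tissue not in ("malignant", "BPH"):
            raise ValueError(f"tissue must be malignant or BPH, got {self.tissue!r}")
        for g in (self.gleason_primary, self.gleason_secondary):
            if not 1 <= g <= 5:
                raise ValueError(f"Gleason pattern {g} outside 1..5 for {self.sample_id}")
        # inclusion rule: score >= 6 is malignant, below is BPH
        if (self.score >= MALIGNANT_MIN_SCORE) != (self.tissue == "malignant"):
            raise ValueError(
                f"{self.sample_id}: tissue {self.tissue} inconsistent with "
                f"Gleason score {self.score} (malignant iff score >= {MALIGNANT_MIN_SCORE})"
            )

    @property
    def score(self) -> int:
        return self.gleason_primary + self.gleason_secondary

    @property
    def grade_group(self) -> str:
        pat = (self.gleason_primary, self.gleason_secondary)
        return "high" if pat in HIGH_GRADE_PATTERNS else "lower"


def load_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = ["sample_id", "tissue", "gleason_primary", "gleason_secondary"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        SampleMeta(
            sample_id=str(r.sample_id),
            tissue=str(r.tissue),
            gleason_primary=int(r.gleason_primary),
            gleason_secondary=int(r.gleason_secondary),
        )
        for r in df.itertuples(index=False)
    ]


@dataclass(frozen=True)
class OccurrenceRecord:
    key: NormalizedVariant
    carrier_count: int
    carriers: frozenset[str]
    category: str  # 'unique' | 'shared'


def rank_occurrence(
    presence: Mapping[NormalizedVariant, set[str]],
    shared_threshold: int = 2,
) -> list[OccurrenceRecord]:
    """Rank descending by carrier count; ties by (contig, position, alt)."""
    records = [
        OccurrenceRecord(
            key=key,
            carrier_count=len(carriers),
            carriers=frozenset(carriers),
            category="shared" if len(carriers) >= shared_threshold else "unique",
        )
        for key, carriers in presence.items()
    ]
    records.sort(key=lambda r: (-r.carrier_count, r.key.contig, r.key.position, r.key.alt))
    return records


@dataclass
class ZygosityGradeTable:
    key: NormalizedVariant
    # rows: genotype; columns: grade group
    hom_high: int
    hom_lower: int
    het_high: int
    het_lower: int
    concordant: bool
    p_value: float

    @property
    def n(self) -> int:
        return self.hom_high + self.hom_lower + self.het_high + self.het_lower


def exact_2x2_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact conditional p for the table [[a, b], [c, d]]."""
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def zygosity_grade_association(
    classified: Sequence[ClassifiedVariant],
    samples: Sequence[SampleMeta],
) -> tuple[list[ZygosityGradeTable], dict]:
    """Per-variant 2x2 zygosity-by-grade tables plus a cohort summary.

    Zero-carrier variants are skipped; discordant-genotype carriers are left
    out of the counts, so cells sum to the concordantly genotyped carriers.
    """
    grade = {s.sample_id: s.grade_group for s in samples}
    by_key: dict[NormalizedVariant, list[ClassifiedVariant]] = {}
    for cv in classified:
        by_key.setdefault(cv.key, []).append(cv)
    tables: list[ZygosityGradeTable] = []
    for key in sorted(by_key):
        cells = {("hom_alt", "high"): 0, ("hom_alt", "lower"): 0,
                 ("het", "high"): 0, ("het", "lower"): 0}
        for cv in by_key[key]:
            if cv.consensus.discordant_gt:
                continue
            g = grade.get(cv.consensus.sample)
            if g is None:
                continue
            cells[(cv.consensus.genotype, g)] += 1
        total = sum(cells.values())
        if total == 0:
            continue
        concordant = (
            cells[("het", "high")] == 0
            and cells[("hom_alt", "lower")] == 0
            and (cells[("hom_alt", "high")] + cells[("het", "lower")]) == total
        )
        p = exact_2x2_p(
            cells[("hom_alt", "high")], cells[("hom_alt", "lower")],
            cells[("het", "high")], cells[("het", "lower")],
        )
        tables.append(
            ZygosityGradeTable(
                key=key,
                hom_high=cells[("hom_alt", "high")],
                hom_lower=cells[("hom_alt", "lower")],
                het_high=cells[("het", "high")],
                het_lower=cells[("het", "lower")],
                concordant=concordant,
                p_value=p,
            )
        )
    summary = {
        "n_variants": len(tables),
        "n_concordant": sum(t.concordant for t in tables),
    }
    return tables, summary
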