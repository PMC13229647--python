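"""Population-frequency joins and rarity binning.

Variants are joined to a gnomAD-style MAF table and a GenomeIndia-style AAF
table by the full normalized key. Rarity is binned on the gnomAD MAF alone:
extremely_rare at MAF <= 0.001 (boundary inclusive), common at MAF >= 0.05,
rare in between, not_reported when the table has no entry. The GIP AAF is
carried for context but never drives binning — the published GIP values are
alternative-allele frequencies, not necessarily minor-allele frequencies.
A GWAS catalog (PRACTICAL-style) is matched by the same strict four-field key
with no allele flipping.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import NormalizedVariant

logger = logging.getLogger(__name__)

EXTREMELY_RARE_MAX = 0.001
COMMON_MIN = 0.05

RARITY_CLASSES = ("extremely_rare", "rare", "common", "not_reported")


@dataclass(frozen=True)
class FrequencyRecord:
    key: NormalizedVariant
    gnomad_maf: float | None = None
    gip_aaf: float | None = None

    def __post_init__(self) -> None:
        for name, v in (("gnomad_maf", self.gnomad_maf), ("gip_aaf", self.gip_aaf)):
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1] for {self.key}")


@dataclass(frozen=True)
class GwasCatalogRow:
    key: NormalizedVariant
    p_value: float
    trait: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def _parse_freq(raw, row_label: str) -> float | None:
    """'NR', empty, or NaN -> None; multi-valued 'a/b' keyed to the first."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    s = str(raw).strip()
    if "/" in s:
        s = s.split("/")[0].strip()
    if s in ("", "NR", "NA", "."):
        return None
    value = float(s)
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{row_label}: frequency {value} outside [0, 1]")
    return value


def load_frequency_table(path: str | Path, column: str = "frequency") -> dict[NormalizedVariant, float | None]:
    """Read a TSV keyed by (contig, position, ref, alt) into a frequency map.

    Malformed frequencies (outside [0, 1]) reject the row with a warning
    rather than aborting the whole table.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["contig", "position", "ref", "alt", column]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    table: dict[NormalizedVariant, float | None] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = NormalizedVariant(str(row.contig), int(str(row.position).replace(",", "")), str(row.ref), str(row.alt).split("/")[0])
        try:
            table[key] = _parse_freq(getattr(row, column), f"{path} row {i}")
        except ValueError as exc:
            logger.warning("rejecting row: %s", exc)
    return table


def join_frequencies(
    variants: Sequence[NormalizedVariant],
    gnomad: Mapping[NormalizedVariant, float | None],
    gip: Mapping[NormalizedVariant, float | None],
) -> list[FrequencyRecord]:
    """Independent left joins against both tables; absent keys -> not-reported."""
    return [
        FrequencyRecord(key=v, gnomad_maf=gnomad.get(v), gip_aaf=gip.get(v))
        for v in variants
    ]


def classify_rarity(
    record: FrequencyRecord,
    extremely_rare_max: float = EXTREMELY_RARE_MAX,
    common_min: float = COMMON_MIN,
) -> str:
    """Bin on gnomAD MAF: <=0.001 extremely_rare (inclusive), >=0.05 common."""
    maf = record.gnomad_maf
    if maf is None:
        return "not_reported"
    if maf <= extremely_rare_max:
        return "extremely_rare"
    if maf >= common_min:
        return "common"
    return "rare"


def match_gwas(
    variants: Sequence[NormalizedVariant],
    catalog: Sequence[GwasCatalogRow],
) -> list[tuple[NormalizedVariant, GwasCatalogRow]]:
    """Exact four-field key match; no strand or ref/alt flipping is attempted."""
    index = {row.key: row for row in catalog}
    return [(v, index[v]) for v in variants if v in index]


def rarity_report(
    records: Sequence[FrequencyRecord],
    classifications: Mapping[NormalizedVariant, str] | None = None,
    **thresholds,
) -> dict:
    """Summary counts: total, per rarity bin, gnomAD not-reported, per clinical class."""
    bins = {c: 0 for c in RARITY_CLASSES}
    for rec in records:
        bins[classify_rarity(rec, **thresholds)] += 1
    per_class: dict[str, int] = {}
    if classifications:
        for cls in classifications.values():
            per_class[cls] = per_class.get(cls, 0) + 1
    return {
        "total": len(records),
        "rarity": bins,
        "gnomad_not_reported": sum(1 for r in records if r.gnomad_maf is None),
        "clinical_class": per_class,
    }
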