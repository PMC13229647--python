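"""Packaged reference tables.

The 12-row consensus somatic variant table (APC, BRAF, ATM, TP53, SMAD4, CHK2
variants with ClinVar classifications and gnomAD/GenomeIndia frequencies)
ships with the package and anchors the worked examples and acceptance checks.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .annotation import AnnotationRecord, load_annotation_table
from .rarity import FrequencyRecord, _parse_freq
from .variants import NormalizedVariant


def table1_path() -> Path:
    """Filesystem path of the packaged 12-row somatic variant table."""
    return Path(resources.files("varprio") / "fixtures" / "table1.tsv")


def load_table1_annotations() -> list[AnnotationRecord]:
    return load_annotation_table(table1_path(), source="clinvar-like")


def load_table1_frequencies() -> list[FrequencyRecord]:
    """Frequency records for the packaged table (first-listed allele per row)."""
    df = pd.read_csv(table1_path(), sep="\t", dtype=str)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = NormalizedVariant(
            str(row.contig), int(row.position), str(row.ref), str(row.alt).split("/")[0]
        )
        out.append(
            FrequencyRecord(
                key=key,
                gnomad_maf=_parse_freq(row.gnomad_maf, f"table1 row {i}"),
                gip_aaf=_parse_freq(row.gip_aaf, f"table1 row {i}"),
            )
        )
    return out
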