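"""Annotation loading, the packaged 12-variant table, key matching against a
quadratic oracle, and the somatic/germline cohort partition rule."""

import pytest

from varprio.annotation import (
    AnnotationRecord,
    AnnotationSchemaError,
    classification_counts,
    filter_by_classification,
    load_annotation_table,
    map_classification,
    match_variants,
    partition_somatic_germline,
)
from varprio.consensus import ConsensusVariant
from varprio.datasets import load_table1_annotations
from varprio.stratify import SampleMeta
from varprio.variants import NormalizedVariant


def _cv(contig, pos, ref, alt, sample="S01", genotype="het"):
    return ConsensusVariant(
        key=NormalizedVariant(contig, pos, ref, alt),
        sample=sample,
        supporting_callers=frozenset({"c1", "c2", "c3", "c4"}),
        genotype=genotype,
        discordant_gt=False,
        evidence={},
    )


class TestTable1Fixture:
    def test_parses_twelve_records(self):
        records = load_table1_annotations()
        assert len(records) == 12

    def test_classification_counts(self):
        counts = classification_counts(load_table1_annotations())
        assert counts == {
            "Pathogenic": 4,
            "Likely-pathogenic": 1,
            "Likely-benign": 1,
            "Benign": 1,
            "VUS": 4,
            "Conflicting": 1,
        }

    def test_synonyms_mapped(self):
        recs = {r.rsid: r for r in load_table1_annotations()}
        assert recs["rs202160435"].classification == "Conflicting"
        assert recs["rs121913364"].classification == "Likely-pathogenic"

    def test_multiallelic_row_keyed_by_first_alt(self):
        recs = {r.rsid: r for r in load_table1_annotations()}
        row = recs["rs1800371"]
        assert row.key.alt == "C"
        assert row.alt_secondary == ("A",)

    def test_non_benign_count_is_eleven(self):
        records = load_table1_annotations()
        kept = filter_by_classification(
            records, keep={"Pathogenic", "Likely-pathogenic", "Likely-benign", "VUS", "Conflicting"}
        )
        assert len(kept) == 11

    def test_vus_count_is_four(self):
        assert len(filter_by_classification(load_table1_annotations(), keep={"VUS"})) == 4


class TestLoading:
    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("contig\tposition\tref\n1\t5\tA\n")
        with pytest.raises(AnnotationSchemaError, match="missing required column"):
            load_annotation_table(p)

    def test_unknown_classification_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "contig\tposition\tref\talt\tclassification\n1\t5\tA\tG\tSpooky\n"
        )
        with pytest.raises(AnnotationSchemaError, match="row 2"):
            load_annotation_table(p)

    def test_empty_table_with_header(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("contig\tposition\tref\talt\tclassification\n")
        assert load_annotation_table(p) == []

    def test_conflicting_duplicates_collapse(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text(
            "contig\tposition\tref\talt\tclassification\n"
            "1\t5\tA\tG\tPathogenic\n1\t5\tA\tG\tBenign\n"
        )
        (rec,) = load_annotation_table(p)
        assert rec.classification == "Conflicting"

    def test_unmappable_string_raises(self):
        with pytest.raises(ValueError):
            map_classification("wibble")


class TestMatching:
    def test_table1_key_match(self):
        cvs = [_cv("17", 7676154, "G", "C")]
        (res,) = match_variants(cvs, load_table1_annotations())
        assert res.annotation is not None
        assert res.annotation.rsid == "rs1042522"
        assert res.classification == "Benign"

    def test_alt_mismatch_no_match(self):
        (res,) = match_variants([_cv("17", 7676154, "G", "T")], load_table1_annotations())
        assert res.annotation is None

    def test_ref_disagreement_warns_and_skips(self):
        ann = AnnotationRecord(
            key=NormalizedVariant("1", 10, "A", "G"), classification="Benign"
        )
        with pytest.warns(UserWarning, match="ref disagreement"):
            (res,) = match_variants([_cv("1", 10, "C", "G")], [ann])
        assert res.annotation is None

    def test_matches_equal_bruteforce_all_pairs(self, rng):
        cvs, anns = [], []
        for _ in range(80):
            cvs.append(_cv("1", int(rng.integers(1, 60)), "A",
                           str(rng.choice(["G", "T", "C"]))))
        seen = set()
        for _ in range(80):
            key = ("1", int(rng.integers(1, 60)), str(rng.choice(["G", "T", "C"])))
            if key in seen:
                continue
            seen.add(key)
            anns.append(
                AnnotationRecord(
                    key=NormalizedVariant(key[0], key[1], "A", key[2]),
                    classification="VUS",
                )
            )
        result = {
            (r.key.contig, r.key.position, r.key.alt)
            for r in match_variants(cvs, anns)
            if r.annotation is not None
        }
        oracle = set()
        for cv in cvs:
            for a in anns:
                if (cv.key.contig, cv.key.position, cv.key.alt) == (
                    a.key.contig, a.key.position, a.key.alt
                ):
                    oracle.add((cv.key.contig, cv.key.position, cv.key.alt))
        assert result == oracle


class TestPartition:
    @pytest.fixture
    def cohort(self):
        return [
            SampleMeta("M1", "malignant", 4, 4),
            SampleMeta("M2", "malignant", 3, 3),
            SampleMeta("B1", "BPH", 2, 3),
        ]

    def _classified(self, origin, samples):
        key = NormalizedVariant("1", 100, "A", "G")
        ann = AnnotationRecord(key=key, classification="Pathogenic", origin=origin)
        return [
            match_variants([_cv("1", 100, "A", "G", sample=s)], [ann])[0]
            for s in samples
        ]

    def test_somatic_malignant_only(self, cohort):
        classified = self._classified("somatic", ["M1", "M2"])
        som, germ, unres = partition_somatic_germline(classified, cohort)
        assert len(som) == 2 and not germ and not unres

    def test_somatic_with_bph_carrier_demoted(self, cohort):
        classified = self._classified("somatic", ["M1", "B1"])
        som, germ, unres = partition_somatic_germline(classified, cohort)
        assert not som and not germ and len(unres) == 2

    def test_germline_annotation(self, cohort):
        classified = self._classified("germline", ["M1", "M2", "B1"])
        som, germ, unres = partition_somatic_germline(classified, cohort)
        assert len(germ) == 3 and not som and not unres

    def test_partition_exhaustive_disjoint(self, cohort, rng):
        classified = []
        for i in range(30):
            origin = str(rng.choice(["somatic", "germline", "unknown", "both"]))
            sample = str(rng.choice(["M1", "M2", "B1"]))
            key = NormalizedVariant("1", int(rng.integers(1, 10)) * 10, "A", "G")
            ann = AnnotationRecord(key=key, classification="VUS", origin=origin)
            cv = _cv(key.contig, key.position, key.ref, key.alt, sample=sample)
            classified.append(match_variants([cv], [ann])[0])
        som, germ, unres = partition_somatic_germline(classified, cohort)
        assert len(som) + len(germ) + len(unres) == len(classified)
        calls = {id(c): c.cohort_origin_call for c in classified}
        assert set(calls.values()) <= {"somatic", "germline", "unresolved"}
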