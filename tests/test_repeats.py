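"""Flank-anchored CAG counting, allele support thresholds, the short-allele
risk boundary, and mosaic-fraction recovery on simulated read mixtures."""

import pytest

from varprio.repeats import (
    MosaicismParams,
    RepeatLocus,
    RepeatObservation,
    RepeatProfile,
    build_profile,
    classify_risk,
    cohort_mosaicism_summary,
    count_repeat_units,
    profiles_from_reads,
    read_fastx,
)
from varprio.synthetic import RepeatTruth, simulate_repeat_reads, write_fastq


def _read(locus, n, prefix="", suffix=""):
    return prefix + locus.left_flank + locus.unit * n + locus.right_flank + suffix


class TestCounting:
    def test_exact_count_recovered(self, locus):
        obs = count_repeat_units(_read(locus, 18), locus)
        assert obs.spanning and obs.repeat_count == 18

    def test_missing_right_flank_non_spanning(self, locus):
        seq = locus.left_flank + locus.unit * 12
        obs = count_repeat_units(seq, locus)
        assert not obs.spanning and obs.reason == "no_right_flank"

    def test_missing_left_flank_non_spanning(self, locus):
        seq = locus.unit * 12 + locus.right_flank
        obs = count_repeat_units(seq, locus)
        assert not obs.spanning and obs.reason == "no_left_flank"

    def test_interrupted_tract_rejected(self, locus):
        seq = locus.left_flank + "CAGCAACAG" + locus.right_flank
        obs = count_repeat_units(seq, locus)
        assert not obs.spanning and obs.reason == "interrupted"

    def test_zero_repeats_is_spanning(self, locus):
        obs = count_repeat_units(_read(locus, 0), locus)
        assert obs.spanning and obs.repeat_count == 0

    def test_roundtrip_constructed_reads(self, locus, rng):
        """Generator round trip: planted counts 5..40 recovered exactly at
        error rate zero, independent of flanking garbage."""
        for _ in range(100):
            n = int(rng.integers(5, 41))
            pre = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 20)))
            post = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 20)))
            obs = count_repeat_units(_read(locus, n, pre, post), locus)
            assert obs.spanning and obs.repeat_count == n

    def test_flank_validation(self):
        with pytest.raises(ValueError, match="10 bases"):
            RepeatLocus(left_flank="ACGT", right_flank="ACGTACGTACGT")
        with pytest.raises(ValueError, match="repeat unit"):
            RepeatLocus(left_flank="ACGTACGTACCAG", right_flank="ACGTACGTACGT", unit="CAG")


class TestProfile:
    def _obs(self, hist):
        out = []
        i = 0
        for length, n in hist.items():
            for _ in range(n):
                out.append(RepeatObservation("S", f"r{i}", spanning=True, repeat_count=length))
                i += 1
        return out

    def test_single_allele_not_mosaic(self):
        prof = build_profile(self._obs({18: 10}))
        assert prof.supported_alleles == [18] and not prof.mosaic
        assert prof.risk == "high"

    def test_two_supported_alleles_mosaic(self):
        prof = build_profile(self._obs({18: 10, 24: 8}))
        assert prof.supported_alleles == [18, 24] and prof.mosaic

    def test_minor_allele_below_read_support_dropped(self):
        prof = build_profile(self._obs({18: 10, 19: 1}))
        assert prof.supported_alleles == [18] and not prof.mosaic

    def test_uncallable_below_min_spanning(self):
        prof = build_profile(self._obs({18: 4}))
        assert prof.risk == "uncallable"

    def test_raising_min_reads_never_adds_alleles(self):
        obs = self._obs({16: 12, 22: 5, 30: 3})
        ns = [
            len(build_profile(obs, MosaicismParams(min_reads_per_allele=k)).supported_alleles)
            for k in (1, 3, 5, 8)
        ]
        assert ns == sorted(ns, reverse=True)

    def test_order_invariance(self, rng):
        obs = self._obs({16: 8, 25: 9})
        shuffled = list(obs)
        rng.shuffle(shuffled)
        assert build_profile(obs).supported_alleles == build_profile(shuffled).supported_alleles


class TestRisk:
    @pytest.mark.parametrize(
        "alleles,expected",
        [([18], "high"), ([19], "not-elevated"), ([16, 24], "high"), ([25, 30], "not-elevated")],
    )
    def test_short_allele_boundary(self, alleles, expected):
        prof = RepeatProfile("S", {a: 10 for a in alleles}, alleles, len(alleles) > 1, "high")
        assert classify_risk(prof) == expected

    def test_uncallable_propagates(self):
        prof = RepeatProfile("S", {}, [], False, "uncallable")
        assert classify_risk(prof) == "uncallable"


class TestSimulatedMixtures:
    def test_pure_allele_all_reads_exact(self, locus):
        truth = RepeatTruth(sample="S", allele_lengths={18: 1.0}, n_reads=50)
        reads = simulate_repeat_reads(truth, locus, seed=5)
        assert len(reads) == 50
        counts = [count_repeat_units(seq, locus).repeat_count for _, seq in reads]
        assert counts == [18] * 50

    def test_mixture_fraction_within_binomial_bounds(self, locus):
        truth = RepeatTruth(sample="S", allele_lengths={18: 0.6, 24: 0.4}, n_reads=1000)
        reads = simulate_repeat_reads(truth, locus, seed=11)
        counts = [count_repeat_units(seq, locus).repeat_count for _, seq in reads]
        frac18 = counts.count(18) / len(counts)
        # 99% binomial bounds at n=1000, p=0.6
        assert abs(frac18 - 0.6) < 2.576 * (0.6 * 0.4 / 1000) ** 0.5

    def test_zero_reads_empty_output(self, locus):
        truth = RepeatTruth(sample="S", allele_lengths={18: 1.0}, n_reads=0)
        assert simulate_repeat_reads(truth, locus, seed=1) == []

    def test_fastq_roundtrip(self, locus, tmp_path):
        truth = RepeatTruth(sample="S", allele_lengths={20: 1.0}, n_reads=5)
        reads = simulate_repeat_reads(truth, locus, seed=2)
        path = write_fastq(reads, tmp_path / "s.fastq")
        assert read_fastx(path) == reads


class TestCohortSummary:
    def _profile(self, sample, mosaic, risk="not-elevated"):
        alleles = [20, 26] if mosaic else [20]
        return RepeatProfile(sample, {a: 10 for a in alleles}, alleles, mosaic, risk)

    def test_fraction_arithmetic(self):
        profiles = [self._profile(f"S{i}", i < 4) for i in range(11)]
        summary = cohort_mosaicism_summary(profiles)
        assert summary["mosaic_fraction_callable"] == pytest.approx(4 / 11)

    def test_no_mosaics(self):
        profiles = [self._profile(f"S{i}", False) for i in range(5)]
        assert cohort_mosaicism_summary(profiles)["mosaic_fraction_callable"] == 0.0

    def test_zero_callable_marked_empty(self):
        profiles = [RepeatProfile("S", {}, [], False, "uncallable")]
        summary = cohort_mosaicism_summary(profiles)
        assert summary["empty"] and summary["mosaic_fraction_callable"] is None
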