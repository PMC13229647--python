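"""Synthetic-cohort generator: determinism, planted structure, noise
calibration, and the noise-free end-to-end closure oracle."""

import filecmp
import math
from pathlib import Path

import numpy as np
import pytest

from varprio import synthetic as syn
from varprio.annotation import load_annotation_table
from varprio.consensus import sample_consensus
from varprio.datasets import table1_path
from varprio.rarity import load_frequency_table


class TestTruth:
    def test_no_somatic_requested_none_emitted(self):
        cfg = syn.CohortConfig(n_somatic_truth=0, n_germline_truth=20, seed=1)
        truths, _ = syn.simulate_truth(cfg)
        assert all(t.origin == "germline" for t in truths)

    def test_same_seed_identical_truth(self):
        cfg = syn.CohortConfig(n_germline_truth=30, n_somatic_truth=5, seed=9)
        t1, s1 = syn.simulate_truth(cfg)
        t2, s2 = syn.simulate_truth(cfg)
        assert t1 == t2 and s1 == s2

    def test_invalid_distribution_rejected(self):
        with pytest.raises(syn.ConfigError, match="sum"):
            syn.CohortConfig(gleason_distribution={(4, 4): 0.5})
        with pytest.raises(syn.ConfigError, match="n_samples"):
            syn.CohortConfig(n_malignant=48, n_bph=5)

    def test_uniform_sharing_mean(self):
        """With uniform sharing on 2..49, the mean carrier count of germline
        variants approaches (2+49)/2 within three standard errors."""
        cfg = syn.CohortConfig(n_germline_truth=10_000, n_somatic_truth=0, seed=4)
        truths, _ = syn.simulate_truth(cfg)
        counts = [len(t.carrier_samples) for t in truths if t.origin == "germline"]
        mean = np.mean(counts)
        expected = (2 + 49) / 2
        var = (48 ** 2 - 1) / 12  # discrete uniform on 48 values
        se = math.sqrt(var / len(counts))
        assert abs(mean - expected) < 3 * se

    def test_somatic_zygosity_rule(self):
        cfg = syn.CohortConfig(n_germline_truth=5, n_somatic_truth=30, seed=6)
        truths, samples = syn.simulate_truth(cfg)
        malignant = {s.sample_id for s in samples if s.tissue == "malignant"}
        high = {s.sample_id for s in samples if s.grade_group == "high"}
        for t in truths:
            if t.origin != "somatic":
                continue
            assert t.carrier_samples <= malignant
            for sample, gt in t.genotype_by_sample.items():
                assert gt == ("hom_alt" if sample in high else "het")

    def test_cohort_composition(self):
        cfg = syn.CohortConfig(seed=2)
        _, samples = syn.simulate_truth(cfg)
        assert len(samples) == 49
        assert sum(s.tissue == "BPH" for s in samples) == 5
        assert sum(s.tissue == "malignant" for s in samples) == 44


class TestVcfEmission:
    @pytest.fixture
    def small(self):
        cfg = syn.CohortConfig(
            n_samples=6, n_malignant=4, n_bph=2, unlabeled_as_malignant=True,
            n_germline_truth=40, n_somatic_truth=6, seed=12,
        )
        truths, samples = syn.simulate_truth(cfg)
        return cfg, truths, samples, syn.make_reference_sequences(cfg)

    def test_noise_free_vcfs_contain_exactly_truth(self, small, tmp_path):
        cfg, truths, samples, seqs = small
        syn.emit_caller_vcfs(truths, samples, syn.noise_free_profiles(), seqs, 12, tmp_path)
        ref = syn.as_reference(seqs)
        truth_pairs = {(s, t.key) for t in truths for s in t.carrier_samples}
        got = set()
        for s in samples:
            paths = {c: tmp_path / f"{s.sample_id}.{c}.vcf" for c in syn.CALLER_IDS}
            for cv in sample_consensus(paths, ref):
                got.add((cv.sample, cv.key))
        assert got == truth_pairs

    def test_same_seed_byte_identical_vcfs(self, small, tmp_path):
        cfg, truths, samples, seqs = small
        a, b = tmp_path / "a", tmp_path / "b"
        syn.emit_caller_vcfs(truths, samples, syn.default_profiles(), seqs, 3, a)
        syn.emit_caller_vcfs(truths, samples, syn.default_profiles(), seqs, 3, b)
        for f in sorted(a.glob("*.vcf")):
            assert filecmp.cmp(f, b / f.name, shallow=False), f.name
        # and a different seed changes at least one file
        c = tmp_path / "c"
        syn.emit_caller_vcfs(truths, samples, syn.default_profiles(), seqs, 4, c)
        assert any(
            not filecmp.cmp(f, c / f.name, shallow=False) for f in sorted(a.glob("*.vcf"))
        )

    def test_truth_outside_reference_rejected(self, small, tmp_path):
        cfg, truths, samples, seqs = small
        tiny = {name: seq[:30] for name, seq in seqs.items()}
        with pytest.raises(syn.ConfigError, match="outside reference"):
            syn.emit_caller_vcfs(truths, samples, syn.noise_free_profiles(), tiny, 12, tmp_path)

    def test_non_pass_fraction_within_binomial_bounds(self, tmp_path):
        cfg = syn.CohortConfig(
            n_samples=4, n_malignant=3, n_bph=1, n_germline_truth=300,
            n_somatic_truth=0, sharing_distribution={4: 1.0}, seed=8,
        )
        truths, samples = syn.simulate_truth(cfg)
        seqs = syn.make_reference_sequences(cfg)
        profiles = [
            syn.CallerProfile(caller_id=c, non_pass_fraction=0.1, depth_floor=20, gq_floor=20)
            for c in syn.CALLER_IDS
        ]
        syn.emit_caller_vcfs(truths, samples, profiles, seqs, 8, tmp_path)
        flagged = total = 0
        for f in tmp_path.glob("*.vcf"):
            for line in f.read_text().splitlines():
                if line.startswith("#"):
                    continue
                total += 1
                flagged += "\tq10\t" in line
        p = 0.1
        bound = 2.576 * math.sqrt(p * (1 - p) / total)
        assert abs(flagged / total - p) < bound

    def test_fn_rate_drops_variants(self, small, tmp_path):
        cfg, truths, samples, seqs = small
        profiles = syn.noise_free_profiles()
        lossy = syn.CallerProfile(
            caller_id="varscan", fn_rate=0.5, depth_floor=20, gq_floor=20, ad_noise=False
        )
        profiles[0] = lossy
        syn.emit_caller_vcfs(truths, samples, profiles, seqs, 12, tmp_path)
        n_varscan = sum(
            1 for f in tmp_path.glob("*.varscan.vcf")
            for l in f.read_text().splitlines() if not l.startswith("#")
        )
        n_vt = sum(
            1 for f in tmp_path.glob("*.vt.vcf")
            for l in f.read_text().splitlines() if not l.startswith("#")
        )
        assert n_varscan < n_vt


class TestAnnotationTables:
    def test_zero_decoys_all_rows_match_truth(self, tmp_path):
        cfg = syn.CohortConfig(n_germline_truth=30, n_somatic_truth=5, seed=3)
        truths, _ = syn.simulate_truth(cfg)
        seqs = syn.make_reference_sequences(cfg)
        paths = syn.emit_annotation_tables(truths, cfg, seqs, tmp_path, decoy_fraction=0.0)
        truth_keys = {t.key for t in truths}
        for rec in load_annotation_table(paths["clinvar"]):
            assert rec.key in truth_keys
        gnomad = load_frequency_table(paths["gnomad"], "frequency")
        assert set(gnomad) <= truth_keys

    def test_unreported_maf_has_no_row(self, tmp_path):
        cfg = syn.CohortConfig(n_germline_truth=40, n_somatic_truth=0, seed=3)
        truths, _ = syn.simulate_truth(cfg)
        seqs = syn.make_reference_sequences(cfg)
        paths = syn.emit_annotation_tables(truths, cfg, seqs, tmp_path, decoy_fraction=0.0)
        gnomad = load_frequency_table(paths["gnomad"], "frequency")
        for t in truths:
            assert (t.key in gnomad) == (t.planted_maf is not None)

    def test_table1_emitted_verbatim(self, tmp_path):
        cfg = syn.CohortConfig(n_germline_truth=5, n_somatic_truth=0, seed=1)
        truths, _ = syn.simulate_truth(cfg)
        seqs = syn.make_reference_sequences(cfg)
        paths = syn.emit_annotation_tables(
            truths, cfg, seqs, tmp_path, include_table1=True
        )
        assert paths["table1"].read_text() == table1_path().read_text()
        assert len(load_annotation_table(paths["table1"])) == 12
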