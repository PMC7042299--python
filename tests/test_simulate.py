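"""Synthetic cohort generator: determinism, calibration, file round trips."""

from __future__ import annotations

import statistics

import numpy as np
import pytest
from scipy import stats

from famprio.discovery import run_discovery_pipeline
from famprio.pedigree import Affection, parse_pedigree_file
from famprio.simulate import (
    CausalGeneSpec,
    SimulationConfig,
    SimulationConfigError,
    _truncated_nb,
    evaluate_recovery,
    inject_chip_contaminant,
    sample_family_map,
    simulate_cohort,
    write_annotation_tsv,
    write_genotype_matrix,
    write_manifest,
    write_pedigree_files,
    write_vcf,
)
from famprio.variants import load_variant_table

SMALL = SimulationConfig(
    n_families=6,
    causal_genes=[CausalGeneSpec("CANDA", 2, "lof")],
    n_chip=1,
)


@pytest.fixture(scope="module")
def small_sim():
    return simulate_cohort(SMALL, seed=7)


class TestConfigValidation:
    def test_causal_families_must_fit_cohort(self):
        cfg = SimulationConfig(
            n_families=2, causal_genes=[CausalGeneSpec("G", 5, "lof")]
        )
        with pytest.raises(SimulationConfigError):
            simulate_cohort(cfg, seed=0)

    def test_consequence_mix_must_sum_to_one(self):
        cfg = SimulationConfig()
        cfg.consequence_mix = {"missense": 0.9, "indel": 0.2,
                               "nonsense": 0.0, "splice": 0.0}
        with pytest.raises(SimulationConfigError):
            cfg.validate()


class TestDeterminism:
    def test_same_seed_gives_byte_identical_outputs(self, tmp_path):
        for run in ("a", "b"):
            sim = simulate_cohort(SMALL, seed=3)
            d = tmp_path / run
            d.mkdir()
            write_vcf(sim, d / "c.vcf")
            write_annotation_tsv(sim, d / "a.tsv")
            write_pedigree_files(sim, d / "c.ped", d / "p.tsv")
            write_genotype_matrix(sim, d / "g.tsv")
            write_manifest(sim, d / "m.json")
        for name in ("c.vcf", "a.tsv", "c.ped", "p.tsv", "g.tsv", "m.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_cohort(SMALL, seed=1)
        b = simulate_cohort(SMALL, seed=2)
        assert len(a.variants) != len(b.variants) or a.variants[0].key != (
            b.variants[0].key
        )


class TestCalibration:
    def test_background_count_distribution(self):
        """Mean per-patient rare-variant count within 3 SE of the configured
        311 over 1000 draws, all inside the truncation range."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(99)
        counts = [_truncated_nb(rng, cfg) for _ in range(1000)]
        lo, hi = cfg.background_range
        assert all(lo <= c <= hi for c in counts)
        se = statistics.stdev(counts) / len(counts) ** 0.5
        assert abs(statistics.mean(counts) - cfg.background_mean) < 3 * se

    def test_germline_vaf_median_in_expected_band(self):
        sim = simulate_cohort(SimulationConfig(causal_genes=[], n_chip=0), seed=5)
        vafs = [v.vaf for v in sim.variants if v.vaf is not None]
        assert 0.47 <= statistics.median(vafs) <= 0.53

    def test_vaf_distribution_matches_binomial_model(self):
        """KS sanity check of deep-coverage VAFs against the binomial
        read-sampling model at allele fraction 0.5."""
        cfg = SimulationConfig(causal_genes=[], n_chip=0, n_families=10)
        pvals = []
        rng = np.random.default_rng(2024)
        for seed in range(20):
            sim = simulate_cohort(cfg, seed=seed)
            obs = np.array(
                [v.vaf for v in sim.variants if v.depth >= 60][:2000]
            )
            depths = np.array(
                [v.depth for v in sim.variants if v.depth >= 60][:2000]
            )
            model = rng.binomial(depths, 0.5) / depths
            pvals.append(stats.ks_2samp(obs, model).pvalue)
        # with 20 replicates at alpha=0.01, systematic failure would show as
        # most p-values collapsing; allow isolated small ones
        assert sum(p < 0.01 for p in pvals) <= 2

    def test_consequence_mix_proportions(self):
        from famprio.variants import Consequence

        sim = simulate_cohort(
            SimulationConfig(causal_genes=[], n_chip=0, synonymous_mean=0.0),
            seed=8,
        )
        n = len(sim.variants)
        missense = sum(
            v.consequence.value is Consequence.MISSENSE for v in sim.variants
        )
        assert missense / n == pytest.approx(0.863, abs=0.02)


class TestInjection:
    def test_recoverable_flag_reflects_thresholds(self):
        cfg = SimulationConfig(
            n_families=8,
            causal_genes=[
                CausalGeneSpec("TWO_LOF", 2, "lof"),
                CausalGeneSpec("ONE_LOF", 1, "lof"),
                CausalGeneSpec("TWO_MIS", 2, "missense"),
                CausalGeneSpec("THREE_MIS", 3, "missense"),
            ],
            n_chip=0,
        )
        sim = simulate_cohort(cfg, seed=4)
        assert sim.manifest.expected_recoverable_genes == {"TWO_LOF", "THREE_MIS"}

    def test_injected_variants_shared_by_affected_relatives(self, small_sim):
        for entry in small_sim.manifest.entries:
            if entry.chip:
                continue
            fam = small_sim.cohort.family(entry.family_id)
            affected_sampled = {
                m.individual_id
                for m in fam.members
                if m.sampled and m.affection is Affection.AFFECTED
            }
            assert affected_sampled <= set(entry.carrier_ids)

    def test_spoiled_variant_not_recovered(self):
        cfg = SimulationConfig(
            n_families=6,
            causal_genes=[CausalGeneSpec("SPOILT", 2, "lof", spoil="low_vaf")],
            n_chip=0,
        )
        sim = simulate_cohort(cfg, seed=9)
        assert sim.manifest.expected_recoverable_genes == set()
        report = run_discovery_pipeline(
            sim.cohort, sim.variants, genotype_calls=sim.genotype_calls
        )
        assert "SPOILT" not in report.included_genes
        metrics = evaluate_recovery(report, sim.manifest)
        assert metrics.sensitivity is None
        assert metrics.per_gene["SPOILT"] == "not_expected"

    def test_empty_manifest_sensitivity_is_null(self):
        sim = simulate_cohort(
            SimulationConfig(n_families=4, causal_genes=[], n_chip=0), seed=2
        )
        report = run_discovery_pipeline(
            sim.cohort, sim.variants, genotype_calls=sim.genotype_calls
        )
        assert evaluate_recovery(report, sim.manifest).sensitivity is None

    def test_run_id_mismatch_rejected(self, small_sim):
        report = run_discovery_pipeline(
            small_sim.cohort, small_sim.variants,
            genotype_calls=small_sim.genotype_calls,
        )
        with pytest.raises(ValueError, match="run id"):
            evaluate_recovery(report, small_sim.manifest, run_id="sim-999")


class TestChipContaminants:
    def test_chip_variant_private_to_one_individual(self, small_sim):
        from famprio.segregation import GenotypeStatus

        chip_entries = [e for e in small_sim.manifest.entries if e.chip]
        assert chip_entries
        for entry in chip_entries:
            key = (entry.family_id, entry.chrom, entry.pos, entry.ref, entry.alt)
            calls = small_sim.genotype_calls[key]
            carriers = [
                c.individual_id for c in calls
                if c.status is GenotypeStatus.CARRIER
            ]
            assert carriers == entry.carrier_ids
            assert len(carriers) == 1

    def test_vaf_outside_configured_range_rejected(self, small_sim):
        from famprio.simulate import _SiteCounter

        rng = np.random.default_rng(0)
        fam = small_sim.cohort.pedigrees[0]
        with pytest.raises(SimulationConfigError):
            inject_chip_contaminant(
                rng, SMALL, fam, "II.1", "TET2", _SiteCounter(), vaf=0.8
            )

    def test_non_chip_gene_rejected(self, small_sim):
        from famprio.simulate import _SiteCounter

        rng = np.random.default_rng(0)
        fam = small_sim.cohort.pedigrees[0]
        with pytest.raises(SimulationConfigError):
            inject_chip_contaminant(
                rng, SMALL, fam, "II.1", "GATA2", _SiteCounter()
            )


class TestFileRoundTrip:
    def test_outputs_parse_through_the_loaders(self, small_sim, tmp_path):
        write_vcf(small_sim, tmp_path / "c.vcf")
        write_annotation_tsv(small_sim, tmp_path / "a.tsv")
        write_pedigree_files(small_sim, tmp_path / "c.ped", tmp_path / "p.tsv")

        cohort = parse_pedigree_file(tmp_path / "c.ped", tmp_path / "p.tsv")
        assert cohort.n_families == small_sim.cohort.n_families
        assert cohort.n_individuals == small_sim.cohort.n_individuals

        rows, report = load_variant_table(
            tmp_path / "c.vcf", tmp_path / "a.tsv", sample_family_map(small_sim)
        )
        assert report.n_unjoinable == 0
        assert len(rows) == len(small_sim.variants)
        original = {
            (v.key, f"{v.family_id}_{v.carrier_id}"): (
                v.gene, v.depth, v.alt_depth, v.consequence.value, v.exac_af,
            )
            for v in small_sim.variants
        }
        for row in rows:
            key = (row.key, row.carrier_id)
            assert key in original
            gene, depth, alt_depth, klass, exac = original[key]
            assert row.gene == gene
            assert (row.depth, row.alt_depth) == (depth, alt_depth)
            assert row.consequence.value is klass
            assert row.exac_af == pytest.approx(exac) if exac else row.exac_af is None

    def test_load_report_counts_match_file(self, small_sim, tmp_path):
        write_vcf(small_sim, tmp_path / "c.vcf")
        write_annotation_tsv(small_sim, tmp_path / "a.tsv")
        n_records = sum(
            1
            for line in (tmp_path / "c.vcf").read_text().splitlines()
            if not line.startswith("#")
        )
        _, report = load_variant_table(
            tmp_path / "c.vcf", tmp_path / "a.tsv", sample_family_map(small_sim)
        )
        assert report.n_vcf_records == n_records
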