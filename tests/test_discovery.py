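"""The discovery cascade: per-variant criteria, gene recurrence, rescue."""

from __future__ import annotations

import random

import pytest

from famprio.discovery import (
    CriteriaTally,
    DiscoveryConfig,
    ExternalCandidateList,
    ExternalSource,
    InclusionReason,
    MissingAnnotationError,
    aggregate_gene_recurrence,
    annotate_sporadic_overlap,
    apply_variant_criteria,
    load_external_lists,
    load_sporadic_aml_genes,
    mean_variants_per_family,
    rescue_by_cross_reference,
    scan_synonymous_splicing,
)
from famprio.segregation import SegregationResult, SegregationStatus
from famprio.variants import PredictorCall, PredictorProfile

from test_variants import make_variant

DAMAGING2 = PredictorProfile(
    PredictorCall.DAMAGING, PredictorCall.DAMAGING,
    PredictorCall.TOLERATED, PredictorCall.MISSING,
)

CLASS_HGVS = {
    "missense": ("c.100G>A", "p.Ala34Thr", "missense_variant"),
    "nonsense": ("c.370C>T", "p.Arg124X", "stop_gained"),
    "frameshift": ("c.99delA", "p.Lys33fs", "frameshift_variant"),
    "inframe": ("c.100_102dup", "p.Val34_Phe35dup", "inframe_insertion"),
    "splice3": ("c.258+2T>C", None, "splice_region_variant"),
    "splice5": ("c.3626+5G>C", None, "splice_region_variant"),
    "synonymous": ("c.351A>G", "p.Leu117=", "synonymous_variant"),
}

_POS = iter(range(1, 100000))


def variant(klass="missense", gene="GENE1", family="FAM1", vaf=0.48, depth=100,
            exac=None, **kwargs):
    hgvs_c, hgvs_p, raw = CLASS_HGVS[klass]
    predictors = kwargs.pop(
        "predictors", DAMAGING2 if klass == "missense" else
        PredictorProfile.all_missing()
    )
    return make_variant(
        pos=next(_POS), gene=gene, family_id=family,
        hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence_raw=raw,
        depth=depth, alt_depth=round(vaf * depth),
        exac_af=exac, gnomad_af=exac, predictors=predictors, **kwargs,
    )


def seg(status):
    return SegregationResult(
        status=status, n_affected_carriers=1, n_affected_tested=1
    )


class TestVariantCriteria:
    def test_typical_retained_profile(self):
        v = variant("missense", vaf=0.48)
        passing, tally = apply_variant_criteria([v], {})
        assert passing == [v]
        assert tally.missing_segregation == 1  # untestable, logged

    def test_low_vaf_excluded(self):
        v = variant("nonsense", vaf=0.25)
        passing, tally = apply_variant_criteria([v], {})
        assert passing == []
        assert tally.failed_vaf == 1

    def test_vaf_threshold_is_strict(self):
        v = variant("nonsense", vaf=0.30)
        passing, _ = apply_variant_criteria([v], {})
        assert passing == []

    def test_distal_splice_excluded(self):
        v = variant("splice5")
        passing, tally = apply_variant_criteria([v], {})
        assert passing == []
        assert tally.failed_consequence == 1

    def test_essential_splice_retained(self):
        passing, _ = apply_variant_criteria([variant("splice3")], {})
        assert len(passing) == 1

    def test_refuted_segregation_excluded(self):
        v = variant("missense")
        key = (v.family_id, v.chrom, v.pos, v.ref, v.alt)
        passing, tally = apply_variant_criteria(
            [v], {key: seg(SegregationStatus.REFUTED)}
        )
        assert passing == []
        assert tally.failed_segregation == 1

    def test_non_canonical_excluded(self):
        passing, _ = apply_variant_criteria([variant(canonical=False)], {})
        assert passing == []

    def test_hand_computed_exclusion_tally(self):
        """20 variants with known per-criterion fates."""
        variants = (
            [variant("missense") for _ in range(6)]            # pass
            + [variant("nonsense") for _ in range(2)]          # pass
            + [variant("missense", vaf=0.2) for _ in range(3)]  # fail (i)
            + [variant("splice5") for _ in range(2)]           # fail (ii)+(v)
            + [variant("synonymous") for _ in range(2)]        # fail (ii)+(v)
            + [variant("missense", exac=5e-4) for _ in range(2)]  # fail (iv)
            + [variant("missense",
                       predictors=PredictorProfile.all_missing())
               for _ in range(3)]                              # fail (v)
        )
        passing, tally = apply_variant_criteria(variants, {})
        assert tally.n_input == 20
        assert len(passing) == tally.n_kept == 8
        assert tally.failed_vaf == 3
        assert tally.failed_consequence == 4
        assert tally.failed_frequency == 2
        # distal splice and synonymous variants also miss the LoF exemption
        assert tally.failed_predictors == 3 + 4
        assert tally.failed_segregation == 0

    def test_containment_in_input(self):
        variants = [variant("missense"), variant("nonsense", vaf=0.1)]
        passing, _ = apply_variant_criteria(variants, {})
        assert set(v.key for v in passing) <= set(v.key for v in variants)


class TestGeneRecurrence:
    def test_lof_in_two_families_included(self):
        aggs = aggregate_gene_recurrence([
            variant("nonsense", gene="ADA", family="FML056"),
            variant("frameshift", gene="ADA", family="FML071"),
        ])
        (ada,) = aggs
        assert ada.included
        assert ada.inclusion_reason is InclusionReason.LOF_RECURRENCE
        assert ada.families_lof == {"FML056", "FML071"}

    def test_mixed_lof_and_missense_included_at_two(self):
        aggs = aggregate_gene_recurrence([
            variant("nonsense", gene="GP6", family="FML055"),
            variant("missense", gene="GP6", family="FML063"),
        ])
        (gp6,) = aggs
        assert gp6.included
        assert gp6.inclusion_reason is InclusionReason.MIXED_RECURRENCE

    def test_missense_in_two_families_excluded(self):
        aggs = aggregate_gene_recurrence([
            variant("missense", gene="SEC23B", family="FML061"),
            variant("missense", gene="SEC23B", family="FML062"),
        ])
        assert not aggs[0].included

    def test_missense_in_three_families_included(self):
        aggs = aggregate_gene_recurrence([
            variant("missense", gene="IL17RA", family=f)
            for f in ("FML050", "FML053", "FML068")
        ])
        assert aggs[0].inclusion_reason is InclusionReason.MISSENSE_RECURRENCE

    def test_two_variants_in_one_family_count_once(self):
        aggs = aggregate_gene_recurrence([
            variant("nonsense", gene="G", family="F1"),
            variant("frameshift", gene="G", family="F1"),
        ])
        assert not aggs[0].included
        assert aggs[0].families_lof == {"F1"}

    def test_order_invariance(self):
        vs = [
            variant("nonsense", gene="G1", family="F1"),
            variant("missense", gene="G1", family="F2"),
            variant("missense", gene="G2", family="F3"),
        ]
        forward = aggregate_gene_recurrence(vs)
        backward = aggregate_gene_recurrence(vs[::-1])
        assert [(a.gene, a.included, a.inclusion_reason) for a in forward] == [
            (a.gene, a.included, a.inclusion_reason) for a in backward
        ]

    def test_randomized_matrices_match_brute_force(self):
        """200 random family x gene incidence patterns against an
        independent re-count of the inclusion rules."""
        rng = random.Random(1234)
        cfg = DiscoveryConfig()
        for _ in range(200):
            n_genes = rng.randint(1, 8)
            n_fams = rng.randint(1, 6)
            vs = []
            truth: dict[str, dict[str, set]] = {}
            for g in range(n_genes):
                gene = f"G{g}"
                for f in range(n_fams):
                    fam = f"F{f}"
                    for _ in range(rng.randint(0, 2)):
                        klass = rng.choice(
                            ["missense", "nonsense", "frameshift", "splice3",
                             "inframe"]
                        )
                        vs.append(variant(klass, gene=gene, family=fam))
                        bucket = "missense" if klass == "missense" else "lof"
                        truth.setdefault(gene, {"lof": set(), "missense": set()})[
                            bucket
                        ].add(fam)
            aggs = {a.gene: a for a in aggregate_gene_recurrence(vs, cfg)}
            for gene, sets in truth.items():
                lof, mis = sets["lof"], sets["missense"]
                expected = (
                    (len(lof) >= cfg.lof_family_min)
                    or (len(lof) >= 1 and len(lof | mis) >= cfg.mixed_family_min
                        and len(mis) > 0)
                    or (len(mis) >= cfg.missense_family_min)
                )
                agg = aggs[gene]
                assert agg.included == expected, (gene, sets)
                assert agg.families_lof == lof
                assert agg.families_missense == mis
                assert agg.families_any == lof | mis
                if agg.included:
                    assert agg.inclusion_reason is not None


class TestCrossReferenceRescue:
    def rescue_lists(self):
        return [
            ExternalCandidateList(ExternalSource.PATNAIK, frozenset({"NAPRT1"})),
            ExternalCandidateList(ExternalSource.BLUTEAU, frozenset({"SH2B3"})),
        ]

    def test_single_family_gene_on_external_list_rescued(self):
        vs = [variant("inframe", gene="NAPRT1", family="FML064")]
        aggs = rescue_by_cross_reference(
            aggregate_gene_recurrence(vs), vs, self.rescue_lists()
        )
        assert aggs[0].included
        assert aggs[0].inclusion_reason is InclusionReason.CROSS_REFERENCE_RESCUE

    def test_single_missense_gene_rescued(self):
        vs = [variant("missense", gene="SH2B3", family="FML085")]
        aggs = rescue_by_cross_reference(
            aggregate_gene_recurrence(vs), vs, self.rescue_lists()
        )
        assert aggs[0].included

    def test_listed_gene_without_passing_variant_not_rescued(self):
        vs = [variant("missense", gene="OTHER", family="F1")]
        aggs = rescue_by_cross_reference(
            aggregate_gene_recurrence(vs), vs, self.rescue_lists()
        )
        assert not any(a.included for a in aggs)

    def test_recurrence_included_gene_untouched(self):
        vs = [
            variant("nonsense", gene="SH2B3", family="F1"),
            variant("nonsense", gene="SH2B3", family="F2"),
        ]
        aggs = rescue_by_cross_reference(
            aggregate_gene_recurrence(vs), vs, self.rescue_lists()
        )
        assert aggs[0].inclusion_reason is InclusionReason.LOF_RECURRENCE

    def test_packaged_lists_load(self):
        lists = load_external_lists()
        genes = set().union(*(l.genes for l in lists))
        assert {"DNAH9", "NAPRT1", "SH2B3", "PRF1"} <= genes


class TestSynonymousSplicingScan:
    def test_flagged_novel_synonymous_retained(self):
        v = variant("synonymous", splice_impact=0.9)
        assert scan_synonymous_splicing([v]) == [v]

    def test_low_score_dropped(self):
        v = variant("synonymous", splice_impact=0.1)
        assert scan_synonymous_splicing([v]) == []

    def test_known_population_variant_not_novel(self):
        v = variant("synonymous", splice_impact=0.9, exac=1e-5)
        assert scan_synonymous_splicing([v]) == []

    def test_non_synonymous_never_returned(self):
        v = variant("missense", splice_impact=0.99)
        assert scan_synonymous_splicing([v]) == []

    def test_missing_annotation_is_an_error(self):
        v = variant("synonymous")
        with pytest.raises(MissingAnnotationError):
            scan_synonymous_splicing([v])


class TestSporadicOverlap:
    def test_chip_gene_flagged(self):
        aggs = aggregate_gene_recurrence([
            variant("nonsense", gene="TET2", family="F1"),
            variant("missense", gene="TET2", family="F2"),
        ])
        aggs, pct = annotate_sporadic_overlap(aggs, load_sporadic_aml_genes())
        assert aggs[0].sporadic_aml
        assert pct == 100

    def test_reported_fraction(self):
        # 26 flagged of 65 included genes -> 40%
        sporadic = {f"S{i}" for i in range(26)}
        vs = []
        for i in range(26):
            vs += [variant("nonsense", gene=f"S{i}", family=f)
                   for f in ("F1", "F2")]
        for i in range(39):
            vs += [variant("nonsense", gene=f"N{i}", family=f)
                   for f in ("F1", "F2")]
        aggs, pct = annotate_sporadic_overlap(
            aggregate_gene_recurrence(vs), sporadic
        )
        assert sum(a.included for a in aggs) == 65
        assert pct == 40

    def test_empty_included_set_gives_null(self):
        _, pct = annotate_sporadic_overlap([], {"TET2"})
        assert pct is None


def test_mean_variants_per_family_reported_to_one_decimal():
    assert mean_variants_per_family(144, 37) == 3.9
    with pytest.raises(ValueError):
        mean_variants_per_family(10, 0)
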