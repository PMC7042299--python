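"""WES discovery cascade for molecularly uncharacterized families.

Candidate variants in the discovery arm must pass five per-variant criteria
on top of the WES pre-filter:

(i)   VAF > 30% (germline range; strict inequality),
(ii)  a qualifying consequence on the canonical transcript -- indels,
      nonsense, start-lost, essential splice (intronic offset within +-3)
      or missense,
(iii) segregation with disease not refuted where testing was possible,
(iv)  reference-population frequency below 1e-4 in ExAC (absent passes),
(v)   two-of-four predictor consensus (LoF-class exempt by default).

Gene-level recurrence (vi) then counts *families*, not variants: a gene is
included with loss-of-function-class variants in >= 2 families, with a
mixture of >= 1 LoF family among >= 2 total, or -- to tame the large
missense background -- with missense variants in >= 3 families.  Genes
falling short of recurrence can be rescued when they carry at least one
criteria-passing variant and appear in an external candidate list from a
prior familial MDS/AML or inherited bone-marrow-failure series.

Variants in CHIP-associated genes (TET2, DNMT3A, ASXL1) carry a caution
flag: blood-derived clonal hematopoiesis can mimic germline variants at
VAFs well inside the germline acceptance window.
"""

from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .pedigree import Cohort
from .segregation import (
    GenotypeCall,
    SegregationResult,
    SegregationStatus,
    assess_segregation,
)
from .variants import (
    AnnotatedVariant,
    Consequence,
    PrefilterTally,
    predictor_consensus,
    prefilter_variants,
)

#: genes whose blood-derived variants frequently reflect clonal hematopoiesis
CHIP_GENES = frozenset({"TET2", "DNMT3A", "ASXL1"})


class ExternalSource(str, enum.Enum):
    CHURPEK = "churpek"
    PATNAIK = "patnaik"
    BLUTEAU = "bluteau"


@dataclass(frozen=True)
class ExternalCandidateList:
    source: ExternalSource
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"{self.source.value}: empty candidate list")


def _read_symbols(path: Path) -> frozenset[str]:
    symbols = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    return frozenset(symbols)


def load_external_lists(
    paths: dict[ExternalSource, str | Path] | None = None,
) -> list[ExternalCandidateList]:
    """Load cross-reference candidate-gene lists (packaged defaults cover the
    three published series used for the rescue step)."""
    if paths is None:
        data = resources.files("famprio.data")
        paths = {
            ExternalSource.CHURPEK: Path(str(data / "external_churpek.txt")),
            ExternalSource.PATNAIK: Path(str(data / "external_patnaik.txt")),
            ExternalSource.BLUTEAU: Path(str(data / "external_bluteau.txt")),
        }
    return [
        ExternalCandidateList(source=source, genes=_read_symbols(Path(p)))
        for source, p in paths.items()
    ]


def load_sporadic_aml_genes(path: str | Path | None = None) -> frozenset[str]:
    if path is None:
        path = Path(str(resources.files("famprio.data") / "sporadic_aml_genes.txt"))
    return _read_symbols(Path(path))


class InclusionReason(str, enum.Enum):
    LOF_RECURRENCE = "lof_recurrence"
    MISSENSE_RECURRENCE = "missense_recurrence"
    MIXED_RECURRENCE = "mixed_recurrence"
    CROSS_REFERENCE_RESCUE = "cross_reference_rescue"


@dataclass
class GeneAggregate:
    """Per-gene cross-family evidence summary.

    ``families_lof`` collects families carrying a qualifying non-missense
    variant (nonsense, frameshift, in-frame indel, start-lost or essential
    splice); ``families_missense`` those with qualifying missense.
    """

    gene: str
    families_lof: set[str] = field(default_factory=set)
    families_missense: set[str] = field(default_factory=set)
    included: bool = False
    inclusion_reason: InclusionReason | None = None
    sporadic_aml: bool = False

    @property
    def families_any(self) -> set[str]:
        return self.families_lof | self.families_missense


@dataclass
class DiscoveryConfig:
    vaf_min: float = 0.30
    exac_max: float = 1e-4
    predictors_min: int = 2
    lof_predictor_exempt: bool = True
    splice_offset_max: int = 3
    lof_family_min: int = 2
    mixed_family_min: int = 2
    missense_family_min: int = 3
    prefilter_max_af: float = 0.005
    prefilter_min_depth: int = 20
    synonymous_splice_threshold: float = 0.5


@dataclass
class CriteriaTally:
    n_input: int = 0
    n_kept: int = 0
    failed_vaf: int = 0
    failed_consequence: int = 0
    failed_segregation: int = 0
    failed_frequency: int = 0
    failed_predictors: int = 0
    missing_segregation: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


SegKey = tuple[str, str, int, str, str]  # (family_id, chrom, pos, ref, alt)


def _seg_key(v: AnnotatedVariant) -> SegKey:
    return (v.family_id, v.chrom, v.pos, v.ref, v.alt)


def _qualifying_consequence(v: AnnotatedVariant, cfg: DiscoveryConfig) -> bool:
    if not v.canonical:
        return False
    c = v.consequence
    if c.value in (
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT_INDEL,
        Consequence.INFRAME_INDEL,
        Consequence.START_LOST,
    ):
        return True
    if c.value is Consequence.SPLICE_PROXIMAL:
        return abs(c.splice_offset) <= cfg.splice_offset_max
    return False


def apply_variant_criteria(
    variants: list[AnnotatedVariant],
    seg_results: dict[SegKey, SegregationResult],
    cfg: DiscoveryConfig | None = None,
) -> tuple[list[AnnotatedVariant], CriteriaTally]:
    """Apply the five per-variant criteria; returns passing variants plus a
    per-criterion exclusion tally (a variant failing several criteria counts
    under each).  A variant with no segregation entry is treated as
    untestable and logged."""
    cfg = cfg or DiscoveryConfig()
    tally = CriteriaTally(n_input=len(variants))
    passing: list[AnnotatedVariant] = []
    for v in variants:
        ok = True
        if v.vaf is None or not (v.vaf > cfg.vaf_min):
            tally.failed_vaf += 1
            ok = False
        if not _qualifying_consequence(v, cfg):
            tally.failed_consequence += 1
            ok = False
        seg = seg_results.get(_seg_key(v))
        if seg is None:
            tally.missing_segregation += 1
        elif seg.status is SegregationStatus.REFUTED:
            tally.failed_segregation += 1
            ok = False
        if v.exac_af is not None and not (v.exac_af < cfg.exac_max):
            tally.failed_frequency += 1
            ok = False
        if not predictor_consensus(
            v.predictors,
            v.consequence,
            min_damaging=cfg.predictors_min,
            lof_exempt=cfg.lof_predictor_exempt,
            splice_offset_max=cfg.splice_offset_max,
        ):
            tally.failed_predictors += 1
            ok = False
        if ok:
            passing.append(v)
    tally.n_kept = len(passing)
    return passing, tally


def _is_missense(v: AnnotatedVariant) -> bool:
    return v.consequence.value is Consequence.MISSENSE


def aggregate_gene_recurrence(
    passing: list[AnnotatedVariant],
    cfg: DiscoveryConfig | None = None,
) -> list[GeneAggregate]:
    """Family-level recurrence per gene with the inclusion decision.

    Two variants in the same family count once: recurrence asks how many
    independent families hit a gene.  Inclusion rules (thresholds
    configurable): non-missense in >= 2 families; >= 1 non-missense family
    among >= 2 total; or missense-only in >= 3 families.
    """
    cfg = cfg or DiscoveryConfig()
    by_gene: dict[str, GeneAggregate] = {}
    for v in passing:
        agg = by_gene.setdefault(v.gene, GeneAggregate(gene=v.gene))
        if _is_missense(v):
            agg.families_missense.add(v.family_id)
        else:
            agg.families_lof.add(v.family_id)
    for agg in by_gene.values():
        n_lof = len(agg.families_lof)
        n_mis = len(agg.families_missense)
        n_any = len(agg.families_any)
        if n_lof >= cfg.lof_family_min and n_mis == 0:
            agg.included = True
            agg.inclusion_reason = InclusionReason.LOF_RECURRENCE
        elif n_lof >= 1 and n_any >= cfg.mixed_family_min and n_mis > 0:
            agg.included = True
            agg.inclusion_reason = InclusionReason.MIXED_RECURRENCE
        elif n_mis >= cfg.missense_family_min:
            agg.included = True
            agg.inclusion_reason = InclusionReason.MISSENSE_RECURRENCE
    return sorted(by_gene.values(), key=lambda a: a.gene)


def rescue_by_cross_reference(
    aggregates: list[GeneAggregate],
    passing: list[AnnotatedVariant],
    lists: list[ExternalCandidateList],
) -> list[GeneAggregate]:
    """Include recurrence-negative genes that carry >= 1 criteria-passing
    variant and appear in at least one external candidate list.  Already
    included genes are untouched."""
    external = set().union(*(l.genes for l in lists)) if lists else set()
    genes_with_passing = {v.gene for v in passing}
    for agg in aggregates:
        if agg.included:
            continue
        if agg.gene in external and agg.gene in genes_with_passing:
            agg.included = True
            agg.inclusion_reason = InclusionReason.CROSS_REFERENCE_RESCUE
    return aggregates


class MissingAnnotationError(ValueError):
    pass


def scan_synonymous_splicing(
    variants: list[AnnotatedVariant],
    threshold: float = 0.5,
) -> list[AnnotatedVariant]:
    """Screen synonymous variants for predicted splice disruption.

    Returns synonymous variants whose splice-impact annotation exceeds
    ``threshold`` and which are absent from both reference-population
    databases ("novel").  This list is deliberately disjoint from the main
    candidate cascade, which never admits synonymous variants.
    """
    synonymous = [
        v for v in variants if v.consequence.value is Consequence.SYNONYMOUS
    ]
    if synonymous and all(v.splice_impact is None for v in synonymous):
        raise MissingAnnotationError(
            "no splice-impact annotation present; annotate synonymous variants "
            "with a splice-impact score before scanning"
        )
    return [
        v
        for v in synonymous
        if v.splice_impact is not None
        and v.splice_impact > threshold
        and v.exac_af is None
        and v.gnomad_af is None
    ]


def annotate_sporadic_overlap(
    aggregates: list[GeneAggregate],
    sporadic_genes: frozenset[str] | set[str],
) -> tuple[list[GeneAggregate], int | None]:
    """Flag included genes also mutated in sporadic AML; returns the
    aggregates and the flagged fraction as a whole-number percentage of the
    included set (None when nothing is included)."""
    included = [a for a in aggregates if a.included]
    for agg in aggregates:
        agg.sporadic_aml = agg.gene in sporadic_genes
    if not included:
        return aggregates, None
    n_flagged = sum(a.sporadic_aml for a in included)
    return aggregates, round(100.0 * n_flagged / len(included))


def mean_variants_per_family(n_variants: int, n_families: int) -> float:
    """Average prioritized variants per discovery family, one decimal."""
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    return round(n_variants / n_families, 1)


@dataclass
class DiscoveryReport:
    prefiltered: list[AnnotatedVariant]
    passing: list[AnnotatedVariant]
    final_variants: list[AnnotatedVariant]
    aggregates: list[GeneAggregate]
    prefilter_tally: PrefilterTally
    criteria_tally: CriteriaTally
    n_discovery_families: int
    sporadic_overlap_pct: int | None = None

    @property
    def included_genes(self) -> list[str]:
        return [a.gene for a in self.aggregates if a.included]

    @property
    def recurrence_genes(self) -> list[str]:
        return [
            a.gene
            for a in self.aggregates
            if a.included
            and a.inclusion_reason is not InclusionReason.CROSS_REFERENCE_RESCUE
        ]

    @property
    def rescued_genes(self) -> list[str]:
        return [
            a.gene
            for a in self.aggregates
            if a.inclusion_reason is InclusionReason.CROSS_REFERENCE_RESCUE
        ]

    @property
    def median_vaf(self) -> float | None:
        vafs = [v.vaf for v in self.final_variants if v.vaf is not None]
        return statistics.median(vafs) if vafs else None

    @property
    def families_with_variants(self) -> set[str]:
        return {v.family_id for v in self.final_variants}

    def per_family_counts(self, family_ids: list[str]) -> dict[str, int]:
        counts = {fid: 0 for fid in family_ids}
        for v in self.final_variants:
            counts[v.family_id] = counts.get(v.family_id, 0) + 1
        return counts

    @property
    def chip_cautions(self) -> list[AnnotatedVariant]:
        return [v for v in self.final_variants if v.gene in CHIP_GENES]

    def summary(self, family_ids: list[str] | None = None) -> dict:
        out = {
            "n_prefiltered": len(self.prefiltered),
            "n_passing": len(self.passing),
            "n_final_variants": len(self.final_variants),
            "n_included_genes": len(self.included_genes),
            "n_recurrence_genes": len(self.recurrence_genes),
            "n_rescued_genes": len(self.rescued_genes),
            "n_families_with_variants": len(self.families_with_variants),
            "median_vaf": self.median_vaf,
            "sporadic_overlap_pct": self.sporadic_overlap_pct,
            "n_chip_cautions": len(self.chip_cautions),
            "prefilter": self.prefilter_tally.as_dict(),
            "criteria": self.criteria_tally.as_dict(),
        }
        if family_ids:
            counts = self.per_family_counts(family_ids)
            values = list(counts.values())
            nonzero = [c for c in values if c > 0]
            out["mean_variants_per_family"] = mean_variants_per_family(
                len(self.final_variants), len(family_ids)
            )
            out["variants_per_family_range"] = [
                min(nonzero) if nonzero else 0,
                max(values) if values else 0,
            ]
            out["families_with_zero_variants"] = sorted(
                fid for fid, c in counts.items() if c == 0
            )
        return out


def build_segregation_results(
    cohort: Cohort,
    genotype_calls: dict[SegKey, list[GenotypeCall]],
) -> dict[SegKey, SegregationResult]:
    """Run segregation assessment for every (family, variant) genotype set."""
    return {
        key: assess_segregation(calls, cohort.family(key[0]))
        for key, calls in genotype_calls.items()
    }


def run_discovery_pipeline(
    cohort: Cohort,
    variants: list[AnnotatedVariant],
    genotype_calls: dict[SegKey, list[GenotypeCall]] | None = None,
    seg_results: dict[SegKey, SegregationResult] | None = None,
    cfg: DiscoveryConfig | None = None,
    external_lists: list[ExternalCandidateList] | None = None,
    sporadic_genes: frozenset[str] | None = None,
) -> DiscoveryReport:
    """Full discovery cascade: pre-filter, segregation, per-variant criteria,
    gene recurrence, cross-reference rescue and sporadic-AML annotation.

    Deterministic given its inputs and configuration.  The final variant
    list contains every criteria-passing variant in an included gene, so the
    containment chain final <= passing <= pre-filtered holds by
    construction.
    """
    cfg = cfg or DiscoveryConfig()
    if seg_results is None:
        seg_results = (
            build_segregation_results(cohort, genotype_calls)
            if genotype_calls
            else {}
        )
    prefiltered, pre_tally = prefilter_variants(
        variants, max_af=cfg.prefilter_max_af, min_depth=cfg.prefilter_min_depth
    )
    passing, crit_tally = apply_variant_criteria(prefiltered, seg_results, cfg)
    aggregates = aggregate_gene_recurrence(passing, cfg)
    if external_lists is None:
        external_lists = load_external_lists()
    aggregates = rescue_by_cross_reference(aggregates, passing, external_lists)
    if sporadic_genes is None:
        sporadic_genes = load_sporadic_aml_genes()
    aggregates, sporadic_pct = annotate_sporadic_overlap(aggregates, sporadic_genes)
    included = {a.gene for a in aggregates if a.included}
    final = [v for v in passing if v.gene in included]
    return DiscoveryReport(
        prefiltered=prefiltered,
        passing=passing,
        final_variants=final,
        aggregates=aggregates,
        prefilter_tally=pre_tally,
        criteria_tally=crit_tally,
        n_discovery_families=cohort.n_families,
        sporadic_overlap_pct=sporadic_pct,
    )
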