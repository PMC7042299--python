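"""Synthetic familial MDS/AML cohorts with known ground truth.

The generator emulates the statistical structure the discovery cascade
assumes so that every pipeline stage is testable without sequencing data:

* per-patient background of rare variants (negative binomial, mean 311,
  truncated to the observed 161-781 range), private to their carrier;
* germline VAF from binomial read sampling at allele fraction 0.5 over a
  Poisson read-depth model, so the empirical VAF median sits near 0.48-0.50;
* the observed consequence mix (86.3% missense / 6.2% indel / 2.4% nonsense
  / 5.1% splice-region);
* reference-population frequencies with a small ultra-rare
  (database-absent) component, plus a trickle of too-common, low-depth and
  segmental-duplication sites to exercise the pre-filter;
* injected causal genes shared identically by the affected members of a
  configurable number of families, built to satisfy the per-variant
  criteria unless deliberately spoiled;
* CHIP contaminants (TET2/DNMT3A/ASXL1) confined to a single individual at
  VAF 0.10-0.50, mimicking blood-derived clonal hematopoiesis.

Background gene symbols are drawn from a large synthetic pool (``BG#####``)
disjoint from known-locus, CHIP and external-candidate symbols, so a gene
can only enter the final list through genuine recurrence, deliberate
injection or deliberate rescue-list contamination.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .discovery import DiscoveryConfig, DiscoveryReport, SegKey
from .pedigree import (
    Affection,
    Cohort,
    Diagnosis,
    Individual,
    Pedigree,
    Sex,
    write_cohort,
)
from .segregation import GenotypeCall, GenotypeStatus
from .variants import (
    ANNOTATION_COLUMNS,
    AnnotatedVariant,
    Consequence,
    ConsequenceClass,
    PredictorCall,
    PredictorProfile,
)

CHIP_GENE_CHOICES = ("TET2", "DNMT3A", "ASXL1")


class SimulationConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CausalGeneSpec:
    """One injected candidate gene: symbol, number of recipient families and
    variant class (``lof``, ``missense`` or ``mixed``); ``spoil='low_vaf'``
    deliberately breaks the VAF criterion to exercise negative controls."""

    gene: str
    n_families: int
    variant_class: str = "lof"
    spoil: str | None = None


@dataclass
class SimulationConfig:
    n_families: int = 37
    #: probabilities over family sampling structures
    pedigree_shapes: dict[str, float] = field(
        default_factory=lambda: {
            "index_only": 0.38,
            "duo": 0.06,
            "trio": 0.31,
            "extended": 0.25,
        }
    )
    background_mean: float = 311.0
    #: negative-binomial size; chosen so truncation to the observed range
    #: leaves the mean essentially unbiased
    background_dispersion: float = 20.0
    background_range: tuple[int, int] = (161, 781)
    consequence_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.863,
            "indel": 0.062,
            "nonsense": 0.024,
            "splice": 0.051,
        }
    )
    frameshift_fraction: float = 0.5  # of indels; remainder in-frame
    splice_offset_max_gen: int = 8  # offsets drawn uniformly on +-1..this
    canonical_prob: float = 0.85
    depth_mean: float = 80.0
    low_depth_rate: float = 0.03
    low_depth_mean: float = 10.0
    germline_allele_fraction: float = 0.5
    exac_absent_prob: float = 0.02
    exac_common_prob: float = 0.02  # AF in [0.005, 0.05): removed by pre-filter
    exac_rare_band: tuple[float, float] = (1e-4, 5e-3)
    segdup_prob: float = 0.01
    predictor_damaging_prob_background: float = 0.15
    predictor_damaging_prob_causal: float = 0.9
    synonymous_mean: float = 30.0
    synonymous_high_splice_prob: float = 0.05
    chip_vaf_range: tuple[float, float] = (0.10, 0.50)
    n_chip: int = 2
    unaffected_carrier_prob: float = 0.2
    gene_pool_size: int = 20000
    causal_genes: list[CausalGeneSpec] = field(
        default_factory=lambda: [
            CausalGeneSpec("CANDA", 2, "lof"),
            CausalGeneSpec("CANDB", 3, "missense"),
            CausalGeneSpec("CANDC", 2, "mixed"),
        ]
    )

    def validate(self) -> None:
        if abs(sum(self.consequence_mix.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("consequence_mix must sum to 1")
        if abs(sum(self.pedigree_shapes.values()) - 1.0) > 1e-9:
            raise SimulationConfigError("pedigree_shapes must sum to 1")
        for spec in self.causal_genes:
            if spec.n_families > self.n_families:
                raise SimulationConfigError(
                    f"{spec.gene}: {spec.n_families} causal families exceed "
                    f"n_families={self.n_families}"
                )
            if spec.variant_class not in ("lof", "missense", "mixed"):
                raise SimulationConfigError(
                    f"{spec.gene}: unknown variant class {spec.variant_class!r}"
                )
        lo, hi = self.chip_vaf_range
        if not (0 <= lo <= hi <= 1):
            raise SimulationConfigError("chip_vaf_range must be ordered in [0,1]")


@dataclass
class InjectedVariant:
    gene: str
    family_id: str
    carrier_ids: list[str]
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str
    expected_recoverable: bool
    chip: bool = False
    spoiled: bool = False


@dataclass
class InjectionManifest:
    run_id: str
    entries: list[InjectedVariant] = field(default_factory=list)

    @property
    def causal_genes(self) -> set[str]:
        return {e.gene for e in self.entries if not e.chip}

    @property
    def expected_recoverable_genes(self) -> set[str]:
        return {e.gene for e in self.entries if e.expected_recoverable}

    @property
    def chip_genes(self) -> set[str]:
        return {e.gene for e in self.entries if e.chip}


@dataclass
class SimulatedCohort:
    run_id: str
    cohort: Cohort
    variants: list[AnnotatedVariant]
    genotype_calls: dict[SegKey, list[GenotypeCall]]
    manifest: InjectionManifest


def _truncated_nb(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    """Negative-binomial per-patient variant count, truncated to the
    configured range by resampling."""
    r = cfg.background_dispersion
    p = r / (r + cfg.background_mean)
    lo, hi = cfg.background_range
    for _ in range(1000):
        n = int(rng.negative_binomial(r, p))
        if lo <= n <= hi:
            return n
    return int(np.clip(n, lo, hi))


def _draw_depth(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    mean = cfg.low_depth_mean if rng.random() < cfg.low_depth_rate else cfg.depth_mean
    return max(1, int(rng.poisson(mean)))


def _draw_exac(rng: np.random.Generator, cfg: SimulationConfig) -> float | None:
    u = rng.random()
    if u < cfg.exac_absent_prob:
        return None
    if u < cfg.exac_absent_prob + cfg.exac_common_prob:
        return float(rng.uniform(0.005, 0.05))
    lo, hi = cfg.exac_rare_band
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_predictors(
    rng: np.random.Generator, p_damaging: float, missense: bool
) -> PredictorProfile:
    if not missense:
        return PredictorProfile.all_missing()
    calls = [
        PredictorCall.DAMAGING if rng.random() < p_damaging else PredictorCall.TOLERATED
        for _ in range(4)
    ]
    return PredictorProfile(*calls)


class _SiteCounter:
    """Hands out unique (chrom, pos) pairs across the cohort."""

    def __init__(self) -> None:
        self.n = 0

    def next(self) -> tuple[str, int]:
        chrom = f"chr{1 + self.n % 22}"
        pos = 10_000 + 100 * (self.n // 22)
        self.n += 1
        return chrom, pos


def _hgvs_for_class(
    klass: Consequence, offset: int | None, index: int
) -> tuple[str | None, str | None, str, str, str]:
    """(hgvs_c, hgvs_p, raw_term, ref, alt) consistent with a variant class."""
    n = 100 + 3 * index
    k = 30 + index
    if klass is Consequence.MISSENSE:
        return f"c.{n}G>A", f"p.Ala{k}Thr", "missense_variant", "G", "A"
    if klass is Consequence.NONSENSE:
        return f"c.{n}C>T", f"p.Arg{k}X", "stop_gained", "C", "T"
    if klass is Consequence.FRAMESHIFT_INDEL:
        return f"c.{n}delA", f"p.Lys{k}fs", "frameshift_variant", "CA", "C"
    if klass is Consequence.INFRAME_INDEL:
        return (
            f"c.{n}_{n + 2}dup",
            f"p.Val{k}_Phe{k + 1}dup",
            "inframe_insertion",
            "C",
            "CGTT",
        )
    if klass is Consequence.SPLICE_PROXIMAL:
        return f"c.{n}{offset:+d}G>A", None, "splice_region_variant", "G", "A"
    if klass is Consequence.SYNONYMOUS:
        return f"c.{n}A>G", f"p.Leu{k}=", "synonymous_variant", "A", "G"
    raise ValueError(klass)


def _draw_class(
    rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[Consequence, int | None]:
    u = rng.random()
    mix = cfg.consequence_mix
    if u < mix["missense"]:
        return Consequence.MISSENSE, None
    u -= mix["missense"]
    if u < mix["indel"]:
        if rng.random() < cfg.frameshift_fraction:
            return Consequence.FRAMESHIFT_INDEL, None
        return Consequence.INFRAME_INDEL, None
    u -= mix["indel"]
    if u < mix["nonsense"]:
        return Consequence.NONSENSE, None
    offset = int(rng.integers(1, cfg.splice_offset_max_gen + 1))
    if rng.random() < 0.5:
        offset = -offset
    return Consequence.SPLICE_PROXIMAL, offset


def _build_family(
    rng: np.random.Generator, cfg: SimulationConfig, family_id: str
) -> Pedigree:
    shapes = list(cfg.pedigree_shapes)
    probs = np.array([cfg.pedigree_shapes[s] for s in shapes])
    shape = shapes[int(rng.choice(len(shapes), p=probs / probs.sum()))]

    def diag() -> Diagnosis:
        return [Diagnosis.MDS, Diagnosis.AML][int(rng.random() < 0.5)]

    father = Individual("I.1", family_id, sex=Sex.MALE,
                        affection=Affection.UNKNOWN, sampled=False)
    mother = Individual("I.2", family_id, sex=Sex.FEMALE,
                        affection=Affection.UNKNOWN, sampled=False)
    index = Individual(
        "II.1", family_id, father_id="I.1", mother_id="I.2",
        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        affection=Affection.AFFECTED, diagnosis=diag(),
        age_at_onset=float(rng.integers(5, 70)), sampled=True,
    )
    members = [father, mother, index]
    if shape == "index_only":
        members.append(
            Individual("II.2", family_id, father_id="I.1", mother_id="I.2",
                       affection=Affection.AFFECTED, diagnosis=diag(),
                       sampled=False)
        )
    elif shape == "duo":
        father.affection = Affection.UNAFFECTED
        father.sampled = True
        members.append(
            Individual("II.2", family_id, father_id="I.1", mother_id="I.2",
                       affection=Affection.AFFECTED, diagnosis=diag(),
                       sampled=False)
        )
    elif shape == "trio":
        members.append(
            Individual("II.2", family_id, father_id="I.1", mother_id="I.2",
                       affection=Affection.AFFECTED, diagnosis=diag(),
                       sampled=True)
        )
    else:  # extended
        father.affection = Affection.AFFECTED
        father.diagnosis = diag()
        father.sampled = True
        members.append(
            Individual("II.2", family_id, father_id="I.1", mother_id="I.2",
                       affection=Affection.AFFECTED, diagnosis=diag(),
                       sampled=True)
        )
        members.append(
            Individual("II.3", family_id, father_id="I.1", mother_id="I.2",
                       affection=Affection.UNAFFECTED, sampled=True)
        )
    return Pedigree(family_id=family_id, members=members, index_case_id="II.1")


def _genotype_calls_for_private(
    fam: Pedigree, carrier_id: str, vaf: float | None
) -> list[GenotypeCall]:
    calls = []
    for m in fam.members:
        if not m.sampled:
            calls.append(GenotypeCall(m.individual_id, GenotypeStatus.NOT_GENOTYPED))
        elif m.individual_id == carrier_id:
            calls.append(GenotypeCall(m.individual_id, GenotypeStatus.CARRIER, vaf))
        else:
            calls.append(GenotypeCall(m.individual_id, GenotypeStatus.NON_CARRIER))
    return calls


def inject_chip_contaminant(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    fam: Pedigree,
    carrier_id: str,
    gene: str,
    sites: _SiteCounter,
    vaf: float | None = None,
) -> tuple[AnnotatedVariant, list[GenotypeCall], InjectedVariant]:
    """A clonal-hematopoiesis contaminant: one CHIP gene variant present in a
    single individual only, never shared with relatives."""
    if gene not in CHIP_GENE_CHOICES:
        raise SimulationConfigError(f"{gene} is not a CHIP gene")
    lo, hi = cfg.chip_vaf_range
    if vaf is None:
        vaf = float(rng.uniform(lo, hi))
    if not (lo <= vaf <= hi):
        raise SimulationConfigError(f"CHIP VAF {vaf} outside configured range")
    chrom, pos = sites.next()
    depth = max(30, int(rng.poisson(cfg.depth_mean)))
    alt_depth = int(round(vaf * depth))
    hgvs_c, hgvs_p, raw, ref, alt = _hgvs_for_class(Consequence.MISSENSE, None, pos)
    # clonal variants mimic genuinely damaging somatic driver mutations, so
    # they carry pathogenic-grade predictor support: only segregation or the
    # recurrence rules can exclude them, mirroring the diagnostic hazard
    predictors = _draw_predictors(rng, cfg.predictor_damaging_prob_causal, True)
    if predictors.n_damaging < 2:
        predictors = PredictorProfile(
            PredictorCall.DAMAGING, PredictorCall.DAMAGING,
            predictors.sift, predictors.provean,
        )
    variant = AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        transcript=f"ENST{pos:011d}", canonical=True,
        hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence_raw=raw,
        depth=depth, alt_depth=alt_depth,
        family_id=fam.family_id, carrier_id=carrier_id,
        exac_af=None, gnomad_af=None,
        predictors=predictors,
        consequence=ConsequenceClass(Consequence.MISSENSE),
    )
    calls = _genotype_calls_for_private(fam, carrier_id, variant.vaf)
    entry = InjectedVariant(
        gene=gene, family_id=fam.family_id, carrier_ids=[carrier_id],
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        variant_class="chip", expected_recoverable=False, chip=True,
    )
    return variant, calls, entry


def _germline_alt_depth(
    rng: np.random.Generator, depth: int, af: float, ensure_vaf_min: float | None
) -> int:
    alt = int(rng.binomial(depth, af))
    if ensure_vaf_min is not None:
        # injected variants are built to satisfy the VAF criterion
        for _ in range(100):
            if depth > 0 and alt / depth > ensure_vaf_min:
                break
            alt = int(rng.binomial(depth, af))
        alt = max(alt, int(np.floor(ensure_vaf_min * depth)) + 1)
    return min(alt, depth)


def simulate_cohort(
    cfg: SimulationConfig | None = None, seed: int = 0
) -> SimulatedCohort:
    """Generate a cohort, its annotated variant rows, per-family genotype
    calls and the injection manifest.  Fully reproducible given the seed."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    run_id = f"sim-{seed}"
    sites = _SiteCounter()

    pedigrees = [
        _build_family(rng, cfg, f"SIM{i + 1:03d}") for i in range(cfg.n_families)
    ]
    cohort = Cohort(pedigrees=pedigrees)

    variants: list[AnnotatedVariant] = []
    genotype_calls: dict[SegKey, list[GenotypeCall]] = {}
    manifest = InjectionManifest(run_id=run_id)

    # -- background: private rare variants per sampled individual ------------
    for fam in pedigrees:
        for member in fam.members:
            if not member.sampled:
                continue
            n_rare = _truncated_nb(rng, cfg)
            n_syn = int(rng.poisson(cfg.synonymous_mean))
            for j in range(n_rare + n_syn):
                synonymous = j >= n_rare
                if synonymous:
                    klass, offset = Consequence.SYNONYMOUS, None
                else:
                    klass, offset = _draw_class(rng, cfg)
                chrom, pos = sites.next()
                gene = f"BG{int(rng.integers(cfg.gene_pool_size)):05d}"
                depth = _draw_depth(rng, cfg)
                alt_depth = _germline_alt_depth(
                    rng, depth, cfg.germline_allele_fraction, None
                )
                hgvs_c, hgvs_p, raw, ref, alt = _hgvs_for_class(klass, offset, pos)
                splice_impact = None
                if synonymous:
                    if rng.random() < cfg.synonymous_high_splice_prob:
                        splice_impact = float(rng.uniform(0.5, 1.0))
                    else:
                        splice_impact = float(rng.uniform(0.0, 0.5))
                v = AnnotatedVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    transcript=f"ENST{pos:011d}",
                    canonical=bool(rng.random() < cfg.canonical_prob),
                    hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence_raw=raw,
                    depth=depth, alt_depth=alt_depth,
                    family_id=fam.family_id, carrier_id=member.individual_id,
                    exac_af=(af := _draw_exac(rng, cfg)),
                    gnomad_af=af,
                    segdup=bool(rng.random() < cfg.segdup_prob),
                    predictors=_draw_predictors(
                        rng,
                        cfg.predictor_damaging_prob_background,
                        klass is Consequence.MISSENSE,
                    ),
                    splice_impact=splice_impact,
                    consequence=ConsequenceClass(klass, offset),
                )
                variants.append(v)
                genotype_calls[
                    (fam.family_id, chrom, pos, ref, alt)
                ] = _genotype_calls_for_private(fam, member.individual_id, v.vaf)

    # -- injected causal genes ------------------------------------------------
    dcfg = DiscoveryConfig()
    for spec in cfg.causal_genes:
        chosen = rng.choice(cfg.n_families, size=spec.n_families, replace=False)
        recoverable = not spec.spoil and {
            "lof": spec.n_families >= dcfg.lof_family_min,
            "missense": spec.n_families >= dcfg.missense_family_min,
            "mixed": spec.n_families >= dcfg.mixed_family_min,
        }[spec.variant_class]
        for rank, fam_index in enumerate(sorted(int(i) for i in chosen)):
            fam = pedigrees[fam_index]
            if spec.variant_class == "lof":
                klass = (
                    Consequence.NONSENSE if rank % 2 == 0
                    else Consequence.FRAMESHIFT_INDEL
                )
            elif spec.variant_class == "missense":
                klass = Consequence.MISSENSE
            else:  # mixed: one LoF family, missense elsewhere
                klass = Consequence.NONSENSE if rank == 0 else Consequence.MISSENSE
            chrom, pos = sites.next()
            hgvs_c, hgvs_p, raw, ref, alt = _hgvs_for_class(klass, None, pos)
            sampled = [m for m in fam.members if m.sampled]
            carriers = [
                m.individual_id for m in sampled
                if m.affection is Affection.AFFECTED
            ]
            unaffected_carriers = [
                m.individual_id for m in sampled
                if m.affection is Affection.UNAFFECTED
                and rng.random() < cfg.unaffected_carrier_prob
            ]
            calls: list[GenotypeCall] = []
            rows: list[AnnotatedVariant] = []
            if spec.variant_class == "missense" or klass is Consequence.MISSENSE:
                predictors = _draw_predictors(
                    rng, cfg.predictor_damaging_prob_causal, True
                )
                if predictors.n_damaging < dcfg.predictors_min:
                    # manifest guarantee: injected variants satisfy the
                    # predictor criterion unless spoiled
                    predictors = PredictorProfile(
                        PredictorCall.DAMAGING,
                        PredictorCall.DAMAGING,
                        predictors.sift,
                        predictors.provean,
                    )
            else:
                predictors = PredictorProfile.all_missing()
            for m in fam.members:
                if not m.sampled:
                    calls.append(
                        GenotypeCall(m.individual_id, GenotypeStatus.NOT_GENOTYPED)
                    )
                    continue
                carrier = (
                    m.individual_id in carriers
                    or m.individual_id in unaffected_carriers
                )
                if not carrier:
                    calls.append(
                        GenotypeCall(m.individual_id, GenotypeStatus.NON_CARRIER)
                    )
                    continue
                depth = max(30, int(rng.poisson(cfg.depth_mean)))
                if spec.spoil == "low_vaf":
                    alt_depth = max(1, int(round(0.2 * depth)))
                else:
                    alt_depth = _germline_alt_depth(
                        rng, depth, cfg.germline_allele_fraction, dcfg.vaf_min
                    )
                v = AnnotatedVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=spec.gene,
                    transcript=f"ENST{pos:011d}", canonical=True,
                    hgvs_c=hgvs_c, hgvs_p=hgvs_p, consequence_raw=raw,
                    depth=depth, alt_depth=alt_depth,
                    family_id=fam.family_id, carrier_id=m.individual_id,
                    exac_af=None, gnomad_af=None,
                    predictors=predictors,
                    consequence=ConsequenceClass(klass),
                )
                rows.append(v)
                calls.append(
                    GenotypeCall(m.individual_id, GenotypeStatus.CARRIER, v.vaf)
                )
            variants.extend(rows)
            genotype_calls[(fam.family_id, chrom, pos, ref, alt)] = calls
            manifest.entries.append(
                InjectedVariant(
                    gene=spec.gene, family_id=fam.family_id,
                    carrier_ids=carriers + unaffected_carriers,
                    chrom=chrom, pos=pos, ref=ref, alt=alt,
                    variant_class=spec.variant_class,
                    expected_recoverable=recoverable,
                    spoiled=spec.spoil is not None,
                )
            )

    # -- CHIP contaminants ----------------------------------------------------
    chip_genes = list(CHIP_GENE_CHOICES[: max(0, min(cfg.n_chip, 3))])
    for gene in chip_genes:
        fam = pedigrees[int(rng.integers(cfg.n_families))]
        affected_sampled = [
            m for m in fam.members
            if m.sampled and m.affection is Affection.AFFECTED
        ]
        carrier = affected_sampled[int(rng.integers(len(affected_sampled)))]
        v, calls, entry = inject_chip_contaminant(
            rng, cfg, fam, carrier.individual_id, gene, sites
        )
        variants.append(v)
        genotype_calls[(fam.family_id, v.chrom, v.pos, v.ref, v.alt)] = calls
        manifest.entries.append(entry)

    return SimulatedCohort(
        run_id=run_id,
        cohort=cohort,
        variants=variants,
        genotype_calls=genotype_calls,
        manifest=manifest,
    )


@dataclass
class RecoveryMetrics:
    sensitivity: float | None
    recovered_genes: set[str]
    missed_genes: set[str]
    false_inclusions: list[str]
    per_gene: dict[str, str]


def evaluate_recovery(
    report: DiscoveryReport,
    manifest: InjectionManifest,
    rescue_genes: set[str] | None = None,
    run_id: str | None = None,
) -> RecoveryMetrics:
    """Parameter-recovery metrics for a pipeline run on a simulated cohort.

    Sensitivity = recovered / expected-recoverable injected genes (null when
    nothing was expected); false inclusions are included genes neither in the
    manifest nor attributable to a rescue list.
    """
    if run_id is not None and run_id != manifest.run_id:
        raise ValueError(
            f"run id mismatch: report from {run_id!r}, manifest {manifest.run_id!r}"
        )
    rescue_genes = rescue_genes or set()
    included = set(report.included_genes)
    expected = manifest.expected_recoverable_genes
    recovered = expected & included
    sensitivity = len(recovered) / len(expected) if expected else None
    false_inclusions = sorted(
        g
        for g in included
        if g not in manifest.causal_genes
        and g not in manifest.chip_genes
        and g not in rescue_genes
    )
    per_gene: dict[str, str] = {}
    for entry in manifest.entries:
        if entry.chip:
            per_gene[entry.gene] = (
                "chip_included" if entry.gene in included else "chip_excluded"
            )
        elif entry.gene in included:
            per_gene[entry.gene] = "recovered"
        elif entry.expected_recoverable:
            per_gene[entry.gene] = "missed"
        else:
            per_gene[entry.gene] = "not_expected"
    return RecoveryMetrics(
        sensitivity=sensitivity,
        recovered_genes=recovered,
        missed_genes=expected - included,
        false_inclusions=false_inclusions,
        per_gene=per_gene,
    )


# ---------------------------------------------------------------------------
# file writers: VCF, annotation TSV, PED/phenotype, genotype matrix, manifest
# ---------------------------------------------------------------------------


def _collect_records(sim: SimulatedCohort):
    """Group variant x carrier rows into per-site records."""
    records: dict[tuple[str, int, str, str], dict] = {}
    for v in sim.variants:
        rec = records.setdefault(
            v.key, {"variant": v, "carriers": {}}
        )
        rec["carriers"][v.carrier_id] = v
    return records


def _chrom_order(chrom: str) -> int:
    return int(chrom.replace("chr", ""))


def write_vcf(sim: SimulatedCohort, path: str | Path) -> None:
    """Multi-sample VCF with GT:AD:DP; non-carrier sampled relatives are
    written as homozygous reference, individuals from other families as
    missing."""
    samples: list[tuple[str, str]] = []  # (family_id, individual_id)
    for fam in sim.cohort.pedigrees:
        for m in fam.members:
            if m.sampled:
                samples.append((fam.family_id, m.individual_id))
    sample_names = [f"{fid}_{iid}" for fid, iid in samples]
    records = _collect_records(sim)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in range(1, 23):
            fh.write(f"##contig=<ID=chr{c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for key in sorted(records, key=lambda k: (_chrom_order(k[0]), k[1])):
            chrom, pos, ref, alt = key
            rec = records[key]
            proto: AnnotatedVariant = rec["variant"]
            fields = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT:AD:DP"]
            for fid, iid in samples:
                if fid != proto.family_id:
                    fields.append("./.:.:.")
                    continue
                carrier = rec["carriers"].get(iid)
                if carrier is not None:
                    ref_depth = carrier.depth - carrier.alt_depth
                    fields.append(
                        f"0/1:{ref_depth},{carrier.alt_depth}:{carrier.depth}"
                    )
                else:
                    fields.append(f"0/0:{proto.depth},0:{proto.depth}")
            fh.write("\t".join(fields) + "\n")


def write_annotation_tsv(sim: SimulatedCohort, path: str | Path) -> None:
    records = _collect_records(sim)
    pred_value = {
        PredictorCall.DAMAGING: "damaging",
        PredictorCall.TOLERATED: "tolerated",
        PredictorCall.MISSING: "",
    }
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for key in sorted(records, key=lambda k: (_chrom_order(k[0]), k[1])):
            v: AnnotatedVariant = records[key]["variant"]
            row = [
                v.chrom, str(v.pos), v.ref, v.alt, v.gene, v.transcript,
                "1" if v.canonical else "0",
                v.hgvs_c or "", v.hgvs_p or "", v.consequence_raw or "",
                "" if v.exac_af is None else repr(v.exac_af),
                "" if v.gnomad_af is None else repr(v.gnomad_af),
                "1" if v.segdup else "0",
                pred_value[v.predictors.polyphen2],
                pred_value[v.predictors.mutation_taster],
                pred_value[v.predictors.sift],
                pred_value[v.predictors.provean],
                "" if v.splice_impact is None else repr(v.splice_impact),
            ]
            fh.write("\t".join(row) + "\n")


def write_pedigree_files(
    sim: SimulatedCohort, ped_path: str | Path, phenotype_path: str | Path
) -> None:
    write_cohort(sim.cohort, ped_path, phenotype_path)


def write_genotype_matrix(sim: SimulatedCohort, path: str | Path) -> None:
    """Variant x individual matrix: 1 carrier, 0 genotyped non-carrier, NA."""
    status_code = {
        GenotypeStatus.CARRIER: "1",
        GenotypeStatus.NON_CARRIER: "0",
        GenotypeStatus.NOT_GENOTYPED: "NA",
    }
    with open(path, "w") as fh:
        fh.write("family_id\tchrom\tpos\tref\talt\tindividual_id\tcall\n")
        for key in sorted(
            sim.genotype_calls, key=lambda k: (k[0], _chrom_order(k[1]), k[2])
        ):
            fid, chrom, pos, ref, alt = key
            for call in sim.genotype_calls[key]:
                fh.write(
                    f"{fid}\t{chrom}\t{pos}\t{ref}\t{alt}\t"
                    f"{call.individual_id}\t{status_code[call.status]}\n"
                )


def write_manifest(sim: SimulatedCohort, path: str | Path) -> None:
    payload = {
        "run_id": sim.manifest.run_id,
        "entries": [asdict(e) for e in sim.manifest.entries],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sample_family_map(sim: SimulatedCohort) -> dict[str, str]:
    """VCF sample name -> family id, matching :func:`write_vcf` naming."""
    mapping = {}
    for fam in sim.cohort.pedigrees:
        for m in fam.members:
            if m.sampled:
                mapping[f"{fam.family_id}_{m.individual_id}"] = fam.family_id
    return mapping
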