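"""Known-locus triage: pathogenicity assessment and Group 1 / Group 2 assignment.

Families are screened first at established MDS/AML predisposition loci.  A
variant at a known locus is called pathogenic when previously described in
familial MDS/AML, or likely pathogenic when a novel variant satisfies all
five evidence criteria: reference-population frequency below 1e-5 (or
absent), VAF above 30%, two-of-four predictor consensus, no benign assertion
under ACMG review, and segregation not refuted where testing was possible.
Partial evidence yields a VUS.  Families with a pathogenic or likely
pathogenic call form Group 1; families with no call at any known locus go to
the WES discovery cascade (Group 2); families whose only known-locus finding
is a VUS are held out of both ("VUS-hold") so the discovery denominator is
not contaminated by partially explained families.

Zygosity is checked against the per-gene inheritance model: most loci act as
heterozygous autosomal-dominant alleles, a few (e.g. FANCA, SBDS, ERCC6L2)
require biallelic hits, and X-linked loci (WAS) are hemizygous in males with
VAF near 1.  A heterozygous-model variant with VAF near 1 is flagged as a
zygosity anomaly (possible somatic loss of heterozygosity) without changing
its category.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .pedigree import Pedigree, Sex
from .segregation import SegregationResult, SegregationStatus
from .variants import AnnotatedVariant, predictor_consensus


class ConfigError(ValueError):
    pass


class UnknownGeneError(KeyError):
    """Gene absent from the known-locus config; route to the discovery cascade."""


class Tier(str, enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    EMERGING = "emerging"


class Inheritance(str, enum.Enum):
    AD_HET = "AD_het"
    AR_BIALLELIC = "AR_biallelic"
    XL_HEMIZYGOUS = "XL_hemizygous"


@dataclass(frozen=True)
class KnownGeneEntry:
    gene: str
    tier: Tier
    inheritance: Inheritance


class PathogenicityCategory(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    EXCLUDED = "excluded"


class EvidenceFlag(str, enum.Enum):
    PREVIOUSLY_DESCRIBED = "previously_described"
    MAF_LT_1E5 = "maf_lt_1e5"
    VAF_GT_30 = "vaf_gt_30"
    PREDICTORS_2OF4 = "predictors_2of4"
    ACMG_NOT_BENIGN = "acmg_not_benign"
    SEGREGATION_SUPPORTED = "segregation_supported"
    ZYGOSITY_CONSISTENT = "zygosity_consistent"


#: evidence required (besides prior description) for a likely-pathogenic call
MANDATORY_FLAGS = frozenset(
    {
        EvidenceFlag.MAF_LT_1E5,
        EvidenceFlag.VAF_GT_30,
        EvidenceFlag.PREDICTORS_2OF4,
        EvidenceFlag.ACMG_NOT_BENIGN,
        EvidenceFlag.SEGREGATION_SUPPORTED,
    }
)


@dataclass
class PathogenicityCall:
    category: PathogenicityCategory
    evidence: set[EvidenceFlag] = field(default_factory=set)
    gene: str = ""
    family_id: str = ""
    zygosity_anomaly: bool = False
    notes: list[str] = field(default_factory=list)


class FamilyGroup(str, enum.Enum):
    GROUP1 = "group1"
    GROUP2 = "group2"
    VUS_HOLD = "vus_hold"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("famprio.data").joinpath(name)))


def load_known_gene_config(path: str | Path | None = None) -> list[KnownGeneEntry]:
    """Load the known-locus config (gene, tier, inheritance); the packaged
    default covers the three evidence tiers of established MDS/AML loci."""
    if path is None:
        path = _data_path("known_genes.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        return []
    required = {"gene", "tier", "inheritance"}
    if not required.issubset(df.columns):
        raise ConfigError(f"known-gene config needs columns {sorted(required)}")
    if df["gene"].duplicated().any():
        dup = sorted(df.loc[df["gene"].duplicated(), "gene"])
        raise ConfigError(f"duplicate gene entries: {dup}")
    return [
        KnownGeneEntry(
            gene=row["gene"],
            tier=Tier(row["tier"]),
            inheritance=Inheritance(row["inheritance"]),
        )
        for _, row in df.iterrows()
    ]


def load_known_variant_db(path: str | Path | None = None) -> set[tuple[str, str]]:
    """(gene, hgvs_c) pairs previously described in familial MDS/AML."""
    if path is None:
        path = _data_path("known_variants.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return {(row["gene"], row["hgvs_c"]) for _, row in df.iterrows()}


def check_zygosity(
    variant: AnnotatedVariant,
    gene_cfg: KnownGeneEntry,
    carrier_sex: Sex = Sex.UNKNOWN,
    other_variants_same_gene: int = 0,
    het_band: tuple[float, float] = (0.3, 0.7),
    hom_min: float = 0.9,
) -> tuple[bool, bool, str | None]:
    """Return (consistent, anomaly, note) for a variant under its gene's
    inheritance model.

    AR loci accept homozygosity (VAF >= 0.9) or a second heterozygous variant
    in the same gene in the same individual -- phase unverified, which is
    noted.  XL loci expect hemizygous males at VAF near 1.  AD loci expect
    the heterozygous band; VAF >= 0.9 under an AD model is an anomaly
    (possible loss of heterozygosity) that does not change the category.
    """
    vaf = variant.vaf
    if vaf is None:
        return False, False, "no VAF available for zygosity check"
    model = gene_cfg.inheritance
    if model is Inheritance.AD_HET:
        if het_band[0] < vaf < het_band[1]:
            return True, False, None
        if vaf >= hom_min:
            return False, True, "VAF near 1 under a heterozygous model (possible LOH)"
        return False, False, None
    if model is Inheritance.XL_HEMIZYGOUS:
        if carrier_sex is Sex.MALE or vaf >= hom_min:
            return vaf >= hom_min, False, None
        return het_band[0] < vaf < het_band[1], False, "female carrier at a hemizygous locus"
    # AR_biallelic
    if vaf >= hom_min:
        return True, False, None
    if other_variants_same_gene >= 1:
        return True, False, "compound heterozygous; trans phase unverified"
    return False, False, "single heterozygous variant at a biallelic locus"


def assess_known_variant(
    variant: AnnotatedVariant,
    seg: SegregationResult,
    known_db_hit: bool,
    gene_cfg: KnownGeneEntry,
    acmg_not_benign: bool = True,
    carrier_sex: Sex = Sex.UNKNOWN,
    other_variants_same_gene: int = 0,
    maf_max: float = 1e-5,
    vaf_min: float = 0.30,
) -> PathogenicityCall:
    """Five-criteria pathogenicity call for a variant at a known locus.

    ``acmg_not_benign`` is curator-supplied: the ACMG review is performed
    externally and consumed here as an evidence flag.
    """
    if variant.gene != gene_cfg.gene:
        raise UnknownGeneError(
            f"{variant.gene} does not match config entry {gene_cfg.gene}; "
            "route to the discovery cascade"
        )
    evidence: set[EvidenceFlag] = set()
    notes: list[str] = []

    if known_db_hit:
        evidence.add(EvidenceFlag.PREVIOUSLY_DESCRIBED)
    if (variant.exac_af is None or variant.exac_af < maf_max) and (
        variant.gnomad_af is None or variant.gnomad_af < maf_max
    ):
        evidence.add(EvidenceFlag.MAF_LT_1E5)
    if variant.vaf is not None and variant.vaf > vaf_min:
        evidence.add(EvidenceFlag.VAF_GT_30)
    if predictor_consensus(variant.predictors, variant.consequence):
        evidence.add(EvidenceFlag.PREDICTORS_2OF4)
    if acmg_not_benign:
        evidence.add(EvidenceFlag.ACMG_NOT_BENIGN)
    if seg.status is not SegregationStatus.REFUTED:
        evidence.add(EvidenceFlag.SEGREGATION_SUPPORTED)

    consistent, anomaly, note = check_zygosity(
        variant,
        gene_cfg,
        carrier_sex=carrier_sex,
        other_variants_same_gene=other_variants_same_gene,
    )
    if consistent:
        evidence.add(EvidenceFlag.ZYGOSITY_CONSISTENT)
    if note:
        notes.append(note)

    if EvidenceFlag.PREVIOUSLY_DESCRIBED in evidence:
        category = PathogenicityCategory.PATHOGENIC
    elif not acmg_not_benign or seg.status is SegregationStatus.REFUTED:
        category = PathogenicityCategory.EXCLUDED
    elif MANDATORY_FLAGS.issubset(evidence):
        category = PathogenicityCategory.LIKELY_PATHOGENIC
    else:
        category = PathogenicityCategory.VUS

    return PathogenicityCall(
        category=category,
        evidence=evidence,
        gene=variant.gene,
        family_id=variant.family_id,
        zygosity_anomaly=anomaly,
        notes=notes,
    )


def assign_family_group(
    pedigree: Pedigree, calls: list[PathogenicityCall]
) -> FamilyGroup:
    """Group 1 if any known-locus call is pathogenic/likely pathogenic;
    VUS-hold if the best call is a VUS (held out of the discovery
    denominator); Group 2 otherwise."""
    categories = {c.category for c in calls}
    if categories & {
        PathogenicityCategory.PATHOGENIC,
        PathogenicityCategory.LIKELY_PATHOGENIC,
    }:
        return FamilyGroup.GROUP1
    if PathogenicityCategory.VUS in categories:
        return FamilyGroup.VUS_HOLD
    return FamilyGroup.GROUP2


@dataclass
class CohortPartition:
    """Cohort-level Group 1 / Group 2 bookkeeping.

    ``n_group1`` counts every family with a reported known-locus variant --
    confirmed pathogenic/likely pathogenic calls plus VUS-hold families,
    which belong to the known-locus arm of the cohort even though they are
    withheld from discovery.  ``n_group2`` counts families entering the WES
    discovery cascade.
    """

    groups: dict[str, FamilyGroup]

    @property
    def n_group1(self) -> int:
        return sum(
            g in (FamilyGroup.GROUP1, FamilyGroup.VUS_HOLD)
            for g in self.groups.values()
        )

    @property
    def n_group1_confirmed(self) -> int:
        return sum(g is FamilyGroup.GROUP1 for g in self.groups.values())

    @property
    def n_vus_hold(self) -> int:
        return sum(g is FamilyGroup.VUS_HOLD for g in self.groups.values())

    @property
    def n_group2(self) -> int:
        return sum(g is FamilyGroup.GROUP2 for g in self.groups.values())

    @property
    def n_families(self) -> int:
        return len(self.groups)

    def percent_group1(self) -> int:
        return round(100.0 * self.n_group1 / self.n_families)

    def percent_group2(self) -> int:
        return round(100.0 * self.n_group2 / self.n_families)


def partition_cohort(groups: dict[str, FamilyGroup]) -> CohortPartition:
    return CohortPartition(groups=groups)


def load_group1_fixture(path: str | Path | None = None) -> dict[str, FamilyGroup]:
    """Packaged per-family triage fixture: family id -> group assignment.

    Families with a pathogenic or likely pathogenic known-locus call map to
    Group 1, VUS-only families to VUS-hold, the rest to Group 2.
    """
    if path is None:
        path = _data_path("group1_families.tsv")
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    groups: dict[str, FamilyGroup] = {}
    for fid, sub in df.groupby("family_id", sort=False):
        cats = set(sub["category"].dropna()) - {"", "none"}
        if cats & {"pathogenic", "likely_pathogenic"}:
            groups[fid] = FamilyGroup.GROUP1
        elif "VUS" in cats:
            groups[fid] = FamilyGroup.VUS_HOLD
        else:
            groups[fid] = FamilyGroup.GROUP2
    return groups
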