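"""Annotated germline variants: VAF, consequence classes, and the WES pre-filter.

One :class:`AnnotatedVariant` is one variant x carrier row, carrying every
piece of evidence the downstream filters consume: read depths and the variant
allele fraction (VAF), reference-population frequencies (ExAC / gnomAD), the
four in-silico pathogenicity predictor calls, the consequence on the
canonical transcript, and a segmental-duplication flag.

Germline heterozygous variants have VAF near 0.5; blood-derived somatic
clones (CHIP) can drift well below that but overlap the germline range, which
is why VAF alone never suffices and the pipeline layers frequency,
segregation and recurrence evidence on top.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


class VariantLoadError(ValueError):
    """Malformed VCF or annotation table."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_PROXIMAL = "splice_proximal"
    START_LOST = "start_lost"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: consequence classes expected to abolish protein function outright
LOF_CLASSES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT_INDEL, Consequence.START_LOST}
)


@dataclass(frozen=True)
class ConsequenceClass:
    value: Consequence
    splice_offset: int | None = None

    def __post_init__(self) -> None:
        if (self.splice_offset is not None) != (
            self.value is Consequence.SPLICE_PROXIMAL
        ):
            raise ValueError("splice_offset set iff class is splice_proximal")

    def is_lof(self, splice_offset_max: int = 3) -> bool:
        """LoF-class: nonsense/frameshift/start-lost, or splice within the
        essential region (|intronic offset| <= ``splice_offset_max``)."""
        if self.value in LOF_CLASSES:
            return True
        if self.value is Consequence.SPLICE_PROXIMAL:
            return abs(self.splice_offset) <= splice_offset_max
        return False


class PredictorCall(str, enum.Enum):
    DAMAGING = "damaging"
    TOLERATED = "tolerated"
    MISSING = "missing"


@dataclass(frozen=True)
class PredictorProfile:
    """Calls from the four predictors: PolyPhen2, MutationTaster, SIFT, Provean."""

    polyphen2: PredictorCall = PredictorCall.MISSING
    mutation_taster: PredictorCall = PredictorCall.MISSING
    sift: PredictorCall = PredictorCall.MISSING
    provean: PredictorCall = PredictorCall.MISSING

    @property
    def n_damaging(self) -> int:
        return sum(
            call is PredictorCall.DAMAGING
            for call in (self.polyphen2, self.mutation_taster, self.sift, self.provean)
        )

    @classmethod
    def all_missing(cls) -> "PredictorProfile":
        return cls()


def compute_vaf(alt_depth: int, depth: int) -> float | None:
    """Variant allele fraction alt_depth/depth; None at zero depth."""
    if alt_depth < 0 or depth < 0:
        raise ValueError("depths must be non-negative")
    if alt_depth > depth:
        raise ValueError(f"alt_depth {alt_depth} exceeds depth {depth}")
    if depth == 0:
        return None
    return alt_depth / depth


# intronic offset in an HGVS c. position, e.g. c.258+2T>C or c.2505-1G>T;
# requires the sign to sit between the exonic position and the edited bases
_SPLICE_RE = re.compile(r"c\.\*?\d+([+-]\d+)(?:_[*\d+-]+)?[ACGTacgt>]")
_MISSENSE_RE = re.compile(r"p\.\(?([A-Z][a-z]{2})\d+([A-Z][a-z]{2})\)?$")
_SYNONYMOUS_RE = re.compile(r"p\.\(?(?:=|([A-Z][a-z]{2})(\d+)(?:=|\1))\)?$")


def classify_consequence(
    hgvs_c: str | None,
    hgvs_p: str | None,
    consequence_raw: str | None = None,
) -> ConsequenceClass:
    """Classify a variant from HGVS c./p. notation, falling back on the raw
    annotation term.

    Splice-proximal variants are recognized by an intronic offset in the c.
    notation (``c.N+k`` / ``c.N-k``); the signed offset is retained so the
    downstream criterion can restrict to the essential +-1,2,3 positions.
    Protein-level rules: ``fs`` = frameshift, terminal ``X``/``*``/``Ter`` =
    nonsense, ``p.Met1?`` = start lost, unchanged residue = synonymous.
    """
    if hgvs_c is None and hgvs_p is None and consequence_raw is None:
        raise ValueError("at least one of hgvs_c, hgvs_p, consequence_raw required")

    if hgvs_c:
        m = _SPLICE_RE.search(hgvs_c)
        if m:
            return ConsequenceClass(Consequence.SPLICE_PROXIMAL, int(m.group(1)))

    if hgvs_p:
        p = hgvs_p.strip()
        if "fs" in p:
            return ConsequenceClass(Consequence.FRAMESHIFT_INDEL)
        if "Met1?" in p:
            return ConsequenceClass(Consequence.START_LOST)
        if p.endswith(("X", "*")) or p.endswith("Ter"):
            return ConsequenceClass(Consequence.NONSENSE)
        if _SYNONYMOUS_RE.match(p):
            return ConsequenceClass(Consequence.SYNONYMOUS)
        if any(tok in p for tok in ("delins", "del", "dup", "ins")):
            return ConsequenceClass(Consequence.INFRAME_INDEL)
        if _MISSENSE_RE.match(p):
            return ConsequenceClass(Consequence.MISSENSE)

    if consequence_raw:
        raw = consequence_raw.lower()
        if "frameshift" in raw:
            return ConsequenceClass(Consequence.FRAMESHIFT_INDEL)
        if "stop_gained" in raw or "nonsense" in raw:
            return ConsequenceClass(Consequence.NONSENSE)
        if "start_lost" in raw:
            return ConsequenceClass(Consequence.START_LOST)
        if "inframe" in raw:
            return ConsequenceClass(Consequence.INFRAME_INDEL)
        if "synonymous" in raw:
            return ConsequenceClass(Consequence.SYNONYMOUS)
        if "missense" in raw:
            return ConsequenceClass(Consequence.MISSENSE)

    # unparseable HGVS and no usable raw term
    return ConsequenceClass(Consequence.OTHER)


@dataclass
class AnnotatedVariant:
    """One variant in one carrier with all filterable evidence attached."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    canonical: bool
    hgvs_c: str | None
    hgvs_p: str | None
    consequence_raw: str | None
    depth: int
    alt_depth: int
    family_id: str
    carrier_id: str
    exac_af: float | None = None
    gnomad_af: float | None = None
    segdup: bool = False
    predictors: PredictorProfile = field(default_factory=PredictorProfile.all_missing)
    splice_impact: float | None = None
    consequence: ConsequenceClass | None = None
    vaf: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.alt_depth <= self.depth):
            raise ValueError(
                f"{self.key}: alt_depth {self.alt_depth} outside [0, {self.depth}]"
            )
        expected = compute_vaf(self.alt_depth, self.depth)
        if self.vaf is None:
            self.vaf = expected
        elif expected is not None and abs(self.vaf - expected) > 1e-9:
            raise ValueError(f"{self.key}: vaf inconsistent with AD/DP")
        for name, af in (("exac_af", self.exac_af), ("gnomad_af", self.gnomad_af)):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"{self.key}: {name} {af} outside [0, 1]")
        if self.consequence is None:
            self.consequence = classify_consequence(
                self.hgvs_c, self.hgvs_p, self.consequence_raw
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class LoadReport:
    n_vcf_records: int = 0
    n_alleles: int = 0
    n_variant_rows: int = 0
    n_unjoinable: int = 0
    n_zero_depth: int = 0
    warnings: list[str] = field(default_factory=list)


#: documented fixed header for the annotation TSV
ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "canonical",
    "hgvs_c",
    "hgvs_p",
    "consequence",
    "exac_af",
    "gnomad_af",
    "segdup",
    "polyphen2",
    "mutation_taster",
    "sift",
    "provean",
    "splice_impact",
]


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value)
    return None if s in ("", ".", "nan") else s


def _opt_float(value) -> float | None:
    s = _opt_str(value)
    return None if s is None else float(s)


def _predictor(value) -> PredictorCall:
    s = _opt_str(value)
    if s is None:
        return PredictorCall.MISSING
    s = s.lower()
    if s in ("d", "damaging", "deleterious", "probably_damaging", "disease_causing"):
        return PredictorCall.DAMAGING
    if s in ("t", "tolerated", "benign", "neutral", "polymorphism"):
        return PredictorCall.TOLERATED
    if s in ("missing", "na", "unknown"):
        return PredictorCall.MISSING
    raise VariantLoadError(f"unrecognized predictor call {value!r}")


def load_annotation_table(path: str | Path) -> dict[tuple[str, int, str, str], dict]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise VariantLoadError(f"annotation table lacks columns {missing}")
    table: dict[tuple[str, int, str, str], dict] = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        table[key] = row.to_dict()
    return table


def load_variant_table(
    vcf_path: str | Path,
    annotation_path: str | Path,
    sample_families: dict[str, str],
) -> tuple[list[AnnotatedVariant], LoadReport]:
    """Join a VCF against its annotation TSV into variant x carrier rows.

    ``sample_families`` maps VCF sample names to family ids.  Multi-allelic
    records are decomposed to biallelic rows before the join.  Records with
    no matching annotation row are excluded with a warning and counted in the
    load report; zero-depth carriers are retained with a null VAF.
    """
    from cyvcf2 import VCF

    annotation = load_annotation_table(annotation_path)
    report = LoadReport()
    variants: list[AnnotatedVariant] = []
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for record in vcf:
        report.n_vcf_records += 1
        chrom = record.CHROM
        for allele_index, alt in enumerate(record.ALT, start=1):
            report.n_alleles += 1
            key = (chrom, record.POS, record.REF, alt)
            ann = annotation.get(key)
            if ann is None:
                report.n_unjoinable += 1
                report.warnings.append(
                    f"no annotation for {chrom}:{record.POS} {record.REF}>{alt}"
                )
                continue
            ad = record.format("AD")
            dp = record.format("DP")
            genotypes = record.genotypes
            for i, sample in enumerate(samples):
                alleles = genotypes[i][:-1]
                if allele_index not in alleles:
                    continue
                depth = int(dp[i][0]) if dp is not None else int(sum(ad[i]))
                alt_depth = int(ad[i][allele_index]) if ad is not None else 0
                depth = max(depth, 0)
                alt_depth = max(alt_depth, 0)
                if depth == 0:
                    report.n_zero_depth += 1
                variants.append(
                    AnnotatedVariant(
                        chrom=chrom,
                        pos=record.POS,
                        ref=record.REF,
                        alt=alt,
                        gene=str(ann["gene"]),
                        transcript=str(ann["transcript"]),
                        canonical=str(ann["canonical"]).lower() in ("1", "true", "yes"),
                        hgvs_c=_opt_str(ann["hgvs_c"]),
                        hgvs_p=_opt_str(ann["hgvs_p"]),
                        consequence_raw=_opt_str(ann["consequence"]),
                        depth=depth,
                        alt_depth=min(alt_depth, depth),
                        exac_af=_opt_float(ann["exac_af"]),
                        gnomad_af=_opt_float(ann["gnomad_af"]),
                        segdup=str(ann["segdup"]).lower() in ("1", "true", "yes"),
                        predictors=PredictorProfile(
                            polyphen2=_predictor(ann["polyphen2"]),
                            mutation_taster=_predictor(ann["mutation_taster"]),
                            sift=_predictor(ann["sift"]),
                            provean=_predictor(ann["provean"]),
                        ),
                        splice_impact=_opt_float(ann["splice_impact"]),
                        family_id=sample_families.get(sample, sample),
                        carrier_id=sample,
                    )
                )
                report.n_variant_rows += 1
    return variants, report


@dataclass
class PrefilterTally:
    n_input: int = 0
    n_kept: int = 0
    excluded_frequency: int = 0
    excluded_depth: int = 0
    excluded_segdup: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


def prefilter_variants(
    variants: list[AnnotatedVariant],
    max_af: float = 0.005,
    min_depth: int = 20,
) -> tuple[list[AnnotatedVariant], PrefilterTally]:
    """WES pre-filter: population frequency < 0.005 (or absent from both
    ExAC and gnomAD), sequencing depth >= 20, and outside segmental
    duplications.  Absence from the reference databases passes the frequency
    rule.  Emits per-rule exclusion counts; a variant failing several rules
    is counted under each.
    """
    tally = PrefilterTally(n_input=len(variants))
    kept: list[AnnotatedVariant] = []
    for v in variants:
        ok = True
        freq_ok = (v.exac_af is None or v.exac_af < max_af) and (
            v.gnomad_af is None or v.gnomad_af < max_af
        )
        if not freq_ok:
            tally.excluded_frequency += 1
            ok = False
        if v.depth < min_depth:
            tally.excluded_depth += 1
            ok = False
        if v.segdup:
            tally.excluded_segdup += 1
            ok = False
        if ok:
            kept.append(v)
    tally.n_kept = len(kept)
    return kept, tally


def predictor_consensus(
    predictors: PredictorProfile,
    consequence: ConsequenceClass,
    min_damaging: int = 2,
    lof_exempt: bool = True,
    splice_offset_max: int = 3,
) -> bool:
    """Two-of-four predictor rule.

    Missense variants need >= ``min_damaging`` of the four predictors calling
    damaging (a missing call counts as not damaging).  LoF-class variants
    (nonsense, frameshift, start-lost, essential-splice) pass unconditionally
    by default because the predictors are missense-oriented and routinely
    abstain on truncating variants; set ``lof_exempt=False`` to apply the
    count to every class.
    """
    if lof_exempt and consequence.is_lof(splice_offset_max):
        return True
    return predictors.n_damaging >= min_damaging
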