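"""Per-variant, per-family segregation with tolerance for reduced penetrance.

The decision rule asks only whether carriage is *consistent* with disease
among the relatives that could actually be tested: a genotyped affected
non-carrier refutes the variant; two or more genotyped affected carriers
(and no affected non-carrier) support it; anything less informative is
untestable and passes downstream filters unpenalized.  Unaffected carriers
never refute, because reduced penetrance and late onset are recurring
features of germline MDS/AML predisposition (asymptomatic parents carrying
GATA2 or C-terminal CEBPA variants are documented); they are recorded so a
report can surface them.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .pedigree import Affection, Pedigree


class GenotypeStatus(str, enum.Enum):
    CARRIER = "carrier"
    NON_CARRIER = "non_carrier"
    NOT_GENOTYPED = "not_genotyped"


@dataclass(frozen=True)
class GenotypeCall:
    individual_id: str
    status: GenotypeStatus
    vaf: float | None = None

    def __post_init__(self) -> None:
        if self.vaf is not None and self.status is GenotypeStatus.NOT_GENOTYPED:
            raise ValueError("vaf recorded for an ungenotyped individual")


class SegregationStatus(str, enum.Enum):
    SEGREGATES = "segregates"
    REFUTED = "refuted"
    UNTESTABLE = "untestable"


@dataclass
class SegregationResult:
    status: SegregationStatus
    n_affected_carriers: int
    n_affected_tested: int
    unaffected_carriers: list[str] = field(default_factory=list)
    #: healthy genotyped non-carriers; narrative support, never decisive
    unaffected_non_carriers: list[str] = field(default_factory=list)


def assess_segregation(
    calls: list[GenotypeCall],
    pedigree: Pedigree,
    strict_unaffected: bool = False,
) -> SegregationResult:
    """Classify a variant's carriage pattern in one family.

    * refuted   -- any genotyped affected member is a non-carrier (or, in
      strict mode only, an unaffected member carries the variant);
    * segregates -- >= 2 genotyped affected members, all of them carriers;
    * untestable -- fewer than two affected members could be tested.

    Raises ``KeyError`` for a call naming an individual outside the pedigree.
    """
    for call in calls:
        if call.individual_id not in pedigree:
            raise KeyError(
                f"family {pedigree.family_id}: unknown individual "
                f"{call.individual_id!r}"
            )

    affected_carriers = 0
    affected_tested = 0
    affected_refuting = 0
    unaffected_carriers: list[str] = []
    unaffected_non_carriers: list[str] = []
    for call in calls:
        if call.status is GenotypeStatus.NOT_GENOTYPED:
            continue
        member = pedigree.member(call.individual_id)
        if member.affection is Affection.AFFECTED:
            affected_tested += 1
            if call.status is GenotypeStatus.CARRIER:
                affected_carriers += 1
            else:
                affected_refuting += 1
        elif member.affection is Affection.UNAFFECTED:
            if call.status is GenotypeStatus.CARRIER:
                unaffected_carriers.append(call.individual_id)
            else:
                unaffected_non_carriers.append(call.individual_id)

    if affected_refuting > 0:
        status = SegregationStatus.REFUTED
    elif strict_unaffected and unaffected_carriers:
        status = SegregationStatus.REFUTED
    elif affected_tested >= 2:
        status = SegregationStatus.SEGREGATES
    else:
        status = SegregationStatus.UNTESTABLE

    return SegregationResult(
        status=status,
        n_affected_carriers=affected_carriers,
        n_affected_tested=affected_tested,
        unaffected_carriers=unaffected_carriers,
        unaffected_non_carriers=unaffected_non_carriers,
    )
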