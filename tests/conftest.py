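from __future__ import annotations

import pytest

from famprio.pedigree import (
    Affection,
    Cohort,
    Diagnosis,
    Individual,
    Pedigree,
    Sex,
)


def make_individual(
    iid: str,
    fid: str = "FAM1",
    affection: Affection = Affection.UNKNOWN,
    diagnosis: Diagnosis | None = None,
    sex: Sex = Sex.UNKNOWN,
    father: str | None = None,
    mother: str | None = None,
    sampled: bool = True,
) -> Individual:
    return Individual(
        individual_id=iid,
        family_id=fid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        affection=affection,
        diagnosis=diagnosis,
        sampled=sampled,
    )


def make_family(
    fid: str,
    diagnoses: list[Diagnosis],
    n_unaffected: int = 1,
    index_case: str | None = None,
) -> Pedigree:
    """A flat sibship: one affected member per diagnosis plus unaffected sibs."""
    members = [
        make_individual(f"A{i}", fid, Affection.AFFECTED, d)
        for i, d in enumerate(diagnoses, start=1)
    ]
    members += [
        make_individual(f"U{i}", fid, Affection.UNAFFECTED)
        for i in range(1, n_unaffected + 1)
    ]
    return Pedigree(
        family_id=fid, members=members, index_case_id=index_case or "A1"
    )


@pytest.fixture
def trio_pedigree() -> Pedigree:
    """Affected index with genotyped parents."""
    members = [
        make_individual("father", affection=Affection.UNAFFECTED, sex=Sex.MALE),
        make_individual("mother", affection=Affection.UNAFFECTED, sex=Sex.FEMALE),
        make_individual(
            "index",
            affection=Affection.AFFECTED,
            diagnosis=Diagnosis.MDS,
            father="father",
            mother="mother",
        ),
    ]
    return Pedigree(family_id="FAM1", members=members, index_case_id="index")


@pytest.fixture
def multiplex_pedigree() -> Pedigree:
    """Index plus three affected relatives and one unaffected sib."""
    members = [
        make_individual("index", affection=Affection.AFFECTED, diagnosis=Diagnosis.AML),
        make_individual("rel1", affection=Affection.AFFECTED, diagnosis=Diagnosis.MDS),
        make_individual("rel2", affection=Affection.AFFECTED, diagnosis=Diagnosis.MDS),
        make_individual("rel3", affection=Affection.AFFECTED, diagnosis=Diagnosis.AML),
        make_individual("healthy", affection=Affection.UNAFFECTED),
    ]
    return Pedigree(family_id="FAM1", members=members, index_case_id="index")


def make_cohort_with_reference_totals() -> Cohort:
    """Synthetic cohort reproducing the reference series' denominators:
    86 families, 221 individuals, 168 affected, 53 unaffected.

    33 index-only families, 5 families with index plus one unaffected
    member, and 48 multiplex families (34 with three affected + one
    unaffected, 14 with two affected + one unaffected).
    """
    pedigrees = []
    n = 0
    for _ in range(33):
        n += 1
        pedigrees.append(make_family(f"F{n:03d}", [Diagnosis.MDS], n_unaffected=0))
    for _ in range(5):
        n += 1
        pedigrees.append(make_family(f"F{n:03d}", [Diagnosis.AML], n_unaffected=1))
    for _ in range(34):
        n += 1
        pedigrees.append(
            make_family(
                f"F{n:03d}",
                [Diagnosis.MDS, Diagnosis.AML, Diagnosis.MDS],
                n_unaffected=1,
            )
        )
    for _ in range(14):
        n += 1
        pedigrees.append(
            make_family(f"F{n:03d}", [Diagnosis.AML, Diagnosis.AML], n_unaffected=1)
        )
    return Cohort(pedigrees=pedigrees)
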