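"""Pedigrees, phenotypes and cohort-level summaries.

A familial MDS/AML cohort is a collection of pedigrees in which two or more
relatives (usually first degree) were diagnosed with a hematological
disorder, with at least one affected case categorized as MDS or AML.
Pedigrees are read from PLINK-style 6-column PED/FAM files; clinical
detail (diagnosis, age at onset, index-case flag) comes from a companion
phenotype TSV keyed by (family_id, individual_id).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd


class PedigreeParseError(ValueError):
    """Malformed PED/FAM or phenotype input."""


class PedigreeValidationError(ValueError):
    """Structurally invalid pedigree (dangling parent, cycle, bad index case)."""


class CohortInclusionError(ValueError):
    """Family violates the cohort inclusion rule (no MDS or AML case)."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Diagnosis(str, enum.Enum):
    MDS = "MDS"
    AML = "AML"
    THROMBOCYTOPENIA = "thrombocytopenia"
    BMF = "BMF/aplastic_anemia"
    OTHER_HEME = "other_heme"
    NONE = "none"


class FamilyPhenotype(str, enum.Enum):
    """Mutually exclusive clinical categories used in cohort summaries."""

    MDS = "MDS"
    AML = "AML"
    MDS_AML = "MDS/AML"
    MDS_AML_TCP = "MDS/AML/TCP"
    MDS_AML_BMF = "MDS/AML/BMF"


_DIAGNOSIS_ALIASES = {
    "mds": Diagnosis.MDS,
    "aml": Diagnosis.AML,
    "thrombocytopenia": Diagnosis.THROMBOCYTOPENIA,
    "tcp": Diagnosis.THROMBOCYTOPENIA,
    "bmf": Diagnosis.BMF,
    "bmf/aplastic_anemia": Diagnosis.BMF,
    "aplastic_anemia": Diagnosis.BMF,
    "other_heme": Diagnosis.OTHER_HEME,
    "none": Diagnosis.NONE,
}


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    diagnosis: Diagnosis | None = None
    age_at_onset: float | None = None
    sampled: bool = False


@dataclass
class Pedigree:
    family_id: str
    members: list[Individual] = field(default_factory=list)
    index_case_id: str | None = None
    consanguineous: bool = False
    other_malignancy: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise PedigreeValidationError(f"family {self.family_id}: no members")
        self._by_id = {m.individual_id: m for m in self.members}
        self._validate()

    def member(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    @property
    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    @property
    def unaffected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.UNAFFECTED]

    @property
    def index_only(self) -> bool:
        """True when genotype material exists for the index case alone."""
        sampled = [m for m in self.members if m.sampled]
        return len(sampled) <= 1

    def _validate(self) -> None:
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent is not None and parent not in self._by_id:
                    raise PedigreeValidationError(
                        f"family {self.family_id}: individual {m.individual_id} "
                        f"refers to absent parent {parent!r}"
                    )
        self._check_acyclic()
        if self.index_case_id is not None:
            if self.index_case_id not in self._by_id:
                raise PedigreeValidationError(
                    f"family {self.family_id}: index case {self.index_case_id!r} "
                    "is not a member"
                )
            idx = self._by_id[self.index_case_id]
            if idx.affection is not Affection.AFFECTED:
                raise PedigreeValidationError(
                    f"family {self.family_id}: index case {self.index_case_id!r} "
                    "is not affected"
                )

    def _check_acyclic(self) -> None:
        # iterative DFS over the parent graph; a back edge means someone is
        # their own ancestor
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {m.individual_id: WHITE for m in self.members}
        for root in color:
            if color[root] != WHITE:
                continue
            stack: list[tuple[str, Iterable[str]]] = [(root, self._parents_of(root))]
            color[root] = GRAY
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if color[p] == GRAY:
                        raise PedigreeValidationError(
                            f"family {self.family_id}: pedigree cycle through {p!r}"
                        )
                    if color[p] == WHITE:
                        color[p] = GRAY
                        stack.append((p, self._parents_of(p)))
                        advanced = True
                        break
                if not advanced:
                    color[node] = BLACK
                    stack.pop()

    def _parents_of(self, individual_id: str):
        m = self._by_id[individual_id]
        return iter([p for p in (m.father_id, m.mother_id) if p is not None])


@dataclass
class Cohort:
    pedigrees: list[Pedigree]

    def __post_init__(self) -> None:
        ids = [p.family_id for p in self.pedigrees]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeValidationError(f"duplicate family ids: {dup}")

    @property
    def n_families(self) -> int:
        return len(self.pedigrees)

    @property
    def n_individuals(self) -> int:
        return sum(len(p.members) for p in self.pedigrees)

    @property
    def n_affected(self) -> int:
        return sum(len(p.affected) for p in self.pedigrees)

    @property
    def n_unaffected(self) -> int:
        return sum(len(p.unaffected) for p in self.pedigrees)

    def family(self, family_id: str) -> Pedigree:
        for p in self.pedigrees:
            if p.family_id == family_id:
                return p
        raise KeyError(family_id)


def _parse_sex(token: str) -> Sex:
    return {"1": Sex.MALE, "2": Sex.FEMALE}.get(token, Sex.UNKNOWN)


def _parse_affection(token: str) -> Affection:
    if token == "2":
        return Affection.AFFECTED
    if token == "1":
        return Affection.UNAFFECTED
    return Affection.UNKNOWN  # 0 / -9 / anything else


def parse_diagnosis(token: str | None) -> Diagnosis | None:
    if token is None or token == "" or pd.isna(token):
        return None
    key = str(token).strip().lower()
    if key in _DIAGNOSIS_ALIASES:
        return _DIAGNOSIS_ALIASES[key]
    raise PedigreeParseError(f"unknown diagnosis {token!r}")


def parse_pedigree_file(path: str | Path, phenotype_path: str | Path) -> Cohort:
    """Read a 6-column PED/FAM file plus phenotype TSV into a :class:`Cohort`.

    PED columns: FID IID PAT MAT SEX PHENO, whitespace separated, ``0`` for a
    missing parent, phenotype coded 2=affected / 1=unaffected / 0 or -9 =
    unknown.  The phenotype TSV must carry ``family_id`` and ``individual_id``
    columns; ``diagnosis``, ``age_at_onset``, ``index_case`` and ``sampled``
    are joined when present.
    """
    path = Path(path)
    rows: list[tuple[str, str, str | None, str | None, Sex, Affection]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 6:
                raise PedigreeParseError(
                    f"{path.name}:{lineno}: expected 6 columns, got {len(cols)}"
                )
            fid, iid, pat, mat, sex, pheno = cols
            rows.append(
                (
                    fid,
                    iid,
                    None if pat == "0" else pat,
                    None if mat == "0" else mat,
                    _parse_sex(sex),
                    _parse_affection(pheno),
                )
            )
    if not rows:
        raise PedigreeParseError(f"{path.name}: no pedigree records")

    pheno_df = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    for required in ("family_id", "individual_id"):
        if required not in pheno_df.columns:
            raise PedigreeParseError(
                f"phenotype table lacks required column {required!r}"
            )
    pheno_map: dict[tuple[str, str], dict] = {
        (str(r["family_id"]), str(r["individual_id"])): r
        for _, r in pheno_df.iterrows()
    }

    def _truthy(value) -> bool:
        return str(value).strip().lower() in {"1", "true", "yes", "y"}

    families: dict[str, list[Individual]] = {}
    index_cases: dict[str, str] = {}
    fam_flags: dict[str, dict] = {}
    for fid, iid, pat, mat, sex, affection in rows:
        info = pheno_map.get((fid, iid), {})
        diagnosis = parse_diagnosis(info.get("diagnosis")) if len(info) else None
        age_raw = info.get("age_at_onset") if len(info) else None
        age = None
        if age_raw is not None and not pd.isna(age_raw) and str(age_raw) != "":
            age = float(age_raw)
        sampled = _truthy(info.get("sampled", "1")) if len(info) else True
        families.setdefault(fid, []).append(
            Individual(
                individual_id=iid,
                family_id=fid,
                father_id=pat,
                mother_id=mat,
                sex=sex,
                affection=affection,
                diagnosis=diagnosis,
                age_at_onset=age,
                sampled=sampled,
            )
        )
        if len(info) and _truthy(info.get("index_case", "0")):
            index_cases[fid] = iid
        if len(info):
            flags = fam_flags.setdefault(fid, {})
            if _truthy(info.get("consanguineous", "0")):
                flags["consanguineous"] = True
            om = info.get("other_malignancy")
            if om is not None and not pd.isna(om) and str(om) != "":
                flags["other_malignancy"] = str(om)

    pedigrees = [
        Pedigree(
            family_id=fid,
            members=members,
            index_case_id=index_cases.get(fid),
            consanguineous=fam_flags.get(fid, {}).get("consanguineous", False),
            other_malignancy=fam_flags.get(fid, {}).get("other_malignancy"),
        )
        for fid, members in families.items()
    ]
    return Cohort(pedigrees=pedigrees)


def write_cohort(
    cohort: Cohort, ped_path: str | Path, phenotype_path: str | Path
) -> None:
    """Write a cohort back to PED + phenotype TSV (inverse of the parser)."""
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    aff_code = {
        Affection.AFFECTED: "2",
        Affection.UNAFFECTED: "1",
        Affection.UNKNOWN: "0",
    }
    with open(ped_path, "w") as ped:
        for fam in cohort.pedigrees:
            for m in fam.members:
                ped.write(
                    "\t".join(
                        [
                            fam.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex_code[m.sex],
                            aff_code[m.affection],
                        ]
                    )
                    + "\n"
                )
    records = []
    for fam in cohort.pedigrees:
        for m in fam.members:
            records.append(
                {
                    "family_id": fam.family_id,
                    "individual_id": m.individual_id,
                    "diagnosis": m.diagnosis.value if m.diagnosis else "",
                    "age_at_onset": "" if m.age_at_onset is None else m.age_at_onset,
                    "index_case": int(m.individual_id == fam.index_case_id),
                    "sampled": int(m.sampled),
                    "consanguineous": int(fam.consanguineous),
                    "other_malignancy": fam.other_malignancy or "",
                }
            )
    pd.DataFrame.from_records(records).to_csv(phenotype_path, sep="\t", index=False)


def classify_family_phenotype(pedigree: Pedigree) -> FamilyPhenotype:
    """Assign the mutually exclusive clinical category of a family.

    Precedence: any bone-marrow-failure diagnosis among affected members wins
    (MDS/AML/BMF), then thrombocytopenia (MDS/AML/TCP), then co-occurrence of
    MDS and AML, then the single myeloid diagnosis.  A family with neither an
    MDS nor an AML case violates the cohort inclusion rule.
    """
    diagnoses = {
        m.diagnosis
        for m in pedigree.affected
        if m.diagnosis is not None and m.diagnosis is not Diagnosis.NONE
    }
    if Diagnosis.MDS not in diagnoses and Diagnosis.AML not in diagnoses:
        raise CohortInclusionError(
            f"family {pedigree.family_id}: no affected member with MDS or AML"
        )
    if Diagnosis.BMF in diagnoses:
        return FamilyPhenotype.MDS_AML_BMF
    if Diagnosis.THROMBOCYTOPENIA in diagnoses:
        return FamilyPhenotype.MDS_AML_TCP
    if Diagnosis.MDS in diagnoses and Diagnosis.AML in diagnoses:
        return FamilyPhenotype.MDS_AML
    if Diagnosis.MDS in diagnoses:
        return FamilyPhenotype.MDS
    return FamilyPhenotype.AML


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Tabulate clinical category counts plus consanguinity/other-malignancy.

    Percentages are 100 * count / n_families reported to one decimal place;
    category counts partition the cohort.
    """
    if cohort.n_families == 0:
        raise ValueError("empty cohort")
    counts = {cat: 0 for cat in FamilyPhenotype}
    n_consanguineous = 0
    n_other_malignancy = 0
    for fam in cohort.pedigrees:
        counts[classify_family_phenotype(fam)] += 1
        n_consanguineous += int(fam.consanguineous)
        n_other_malignancy += int(fam.other_malignancy is not None)
    n = cohort.n_families
    rows = [
        {
            "characteristic": cat.value,
            "n_families": counts[cat],
            "percent": round(100.0 * counts[cat] / n, 1),
        }
        for cat in FamilyPhenotype
    ]
    rows.append(
        {
            "characteristic": "consanguinity",
            "n_families": n_consanguineous,
            "percent": round(100.0 * n_consanguineous / n, 1),
        }
    )
    rows.append(
        {
            "characteristic": "other_malignancies",
            "n_families": n_other_malignancy,
            "percent": round(100.0 * n_other_malignancy / n, 1),
        }
    )
    return pd.DataFrame.from_records(rows)
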