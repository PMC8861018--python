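"""Three-generation pedigree structure and PED-like file round-trip.

The cross design mirrors a two-generation folate-deprivation study: an F0
pair produces F1 offspring; a focal F1 on the deficient (FD) diet is mated
to an unrelated folate-sufficient (FS) partner; their F2 embryos are the
samples in which de novo mutations are counted.  Diet groups:

* ``A`` — only the F0 female on the FD diet;
* ``B`` — only the F0 male on the FD diet;
* ``C`` — both F0 grandparents on the FD diet.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

Generation = Literal["F0", "F1", "F2"]

PED_COLUMNS = ["family_id", "sample_id", "father_id", "mother_id",
               "sex", "phenotype", "generation", "diet"]

_SEX_CODE = {"male": 1, "female": 2, "unknown": 0}
_SEX_NAME = {v: k for k, v in _SEX_CODE.items()}
_PHENO_CODE = {"normal": 1, "abnormal": 2, "NA": 0}
_PHENO_NAME = {v: k for k, v in _PHENO_CODE.items()}


@dataclass(frozen=True)
class PedigreeSample:
    """One sequenced individual."""

    sample_id: str
    generation: Generation
    sex: str = "unknown"
    mother_id: str | None = None
    father_id: str | None = None
    sibship_id: str = ""
    diet: str = "FS"
    phenotype: str = "NA"

    @property
    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None


class Pedigree:
    """A set of :class:`PedigreeSample` with parent-link validation."""

    def __init__(self, samples: Iterable[PedigreeSample]):
        self.samples = list(samples)
        self._by_id = {s.sample_id: s for s in self.samples}
        if len(self._by_id) != len(self.samples):
            raise ValueError("duplicate sample ids in pedigree")
        self.validate()

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> PedigreeSample:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def validate(self) -> None:
        for s in self.samples:
            for pid in (s.mother_id, s.father_id):
                if pid is not None and pid not in self._by_id:
                    raise ValueError(
                        f"sample {s.sample_id}: parent {pid} not in pedigree")
            if s.generation == "F0" and not s.is_founder:
                raise ValueError(f"F0 sample {s.sample_id} has parents")
            if s.generation == "F2" and (s.mother_id is None or s.father_id is None):
                raise ValueError(f"F2 sample {s.sample_id} lacks a parent link")

    # -- queries ---------------------------------------------------------
    def generation(self, gen: Generation) -> list[PedigreeSample]:
        return [s for s in self.samples if s.generation == gen]

    def sibship(self, sibship_id: str) -> list[PedigreeSample]:
        return [s for s in self.samples if s.sibship_id == sibship_id]

    @property
    def sibship_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.sibship_id and s.sibship_id != "control":
                seen.setdefault(s.sibship_id)
        return list(seen)

    @property
    def controls(self) -> list[PedigreeSample]:
        return [s for s in self.samples if s.sibship_id == "control"]

    def parents_of(self, sample_id: str) -> list[PedigreeSample]:
        s = self._by_id[sample_id]
        return [self._by_id[p] for p in (s.father_id, s.mother_id)
                if p is not None]

    def dnm_focal_ids(self) -> list[str]:
        """Samples eligible for de novo calling: F1/F2 study members with
        sequenced parents (founders and their unrelated mates have no
        baseline to compare against)."""
        return [s.sample_id for s in self.samples
                if s.generation in ("F1", "F2")
                and s.sibship_id != "control"
                and (s.mother_id or s.father_id)]

    def ancestors_in_sibship(self, sample_id: str) -> list[PedigreeSample]:
        """Sibship members of strictly earlier generations (the relatives a
        candidate variant must be absent from for a de novo call)."""
        s = self._by_id[sample_id]
        rank = {"F0": 0, "F1": 1, "F2": 2}
        return [m for m in self.sibship(s.sibship_id)
                if rank[m.generation] < rank[s.generation]]

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "family_id": s.sibship_id or "NA",
            "sample_id": s.sample_id,
            "father_id": s.father_id or "0",
            "mother_id": s.mother_id or "0",
            "sex": _SEX_CODE[s.sex],
            "phenotype": _PHENO_CODE[s.phenotype],
            "generation": s.generation,
            "diet": s.diet,
        } for s in self.samples]
        return pd.DataFrame(rows, columns=PED_COLUMNS)

    def to_ped(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_ped(cls, path: str | Path) -> "Pedigree":
        df = pd.read_csv(path, sep="\t", header=None, names=PED_COLUMNS,
                         dtype=str)
        samples = [
            PedigreeSample(
                sample_id=row.sample_id,
                generation=row.generation,
                sex=_SEX_NAME.get(int(row.sex), "unknown"),
                mother_id=None if row.mother_id == "0" else row.mother_id,
                father_id=None if row.father_id == "0" else row.father_id,
                sibship_id="" if row.family_id == "NA" else row.family_id,
                diet=row.diet,
                phenotype=_PHENO_NAME.get(int(row.phenotype), "NA"),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(samples)


def build_pedigree(n_sibships: int, n_f2_per_sibship: int,
                   group: str = "B", n_controls: int = 0) -> Pedigree:
    """Build the study cross: per sibship an F0 pair, a focal FD-diet F1
    male, his FS mate, and ``n_f2_per_sibship`` F2 embryos.

    ``group`` sets which F0 grandparents are on the FD diet (A: female,
    B: male, C: both).  Unrelated FS-diet control adults can be appended
    with ``n_controls``; they carry sibship id ``"control"``.
    """
    if n_sibships < 1 or n_f2_per_sibship < 1:
        raise ValueError("need at least one sibship and one F2 per sibship")
    if group not in ("A", "B", "C"):
        raise ValueError(f"unknown diet group {group!r}")

    f0_female_diet = "FD" if group in ("A", "C") else "FS"
    f0_male_diet = "FD" if group in ("B", "C") else "FS"

    samples: list[PedigreeSample] = []
    for i in range(1, n_sibships + 1):
        sib = f"{group}{i}"
        f0_m = f"{sib}_F0_M"
        f0_f = f"{sib}_F0_F"
        f1 = f"{sib}_F1_M1"
        mate = f"{sib}_F1_mate"
        samples.append(PedigreeSample(f0_m, "F0", "male", diet=f0_male_diet,
                                      sibship_id=sib, phenotype="normal"))
        samples.append(PedigreeSample(f0_f, "F0", "female", diet=f0_female_diet,
                                      sibship_id=sib, phenotype="normal"))
        samples.append(PedigreeSample(f1, "F1", "male", mother_id=f0_f,
                                      father_id=f0_m, sibship_id=sib,
                                      diet="FD", phenotype="normal"))
        samples.append(PedigreeSample(mate, "F1", "female", sibship_id=sib,
                                      diet="FS", phenotype="normal"))
        for j in range(1, n_f2_per_sibship + 1):
            samples.append(PedigreeSample(
                f"{sib}_F2_{j}", "F2", "unknown",
                mother_id=mate, father_id=f1, sibship_id=sib,
                diet="FD", phenotype="NA"))
    for k in range(1, n_controls + 1):
        samples.append(PedigreeSample(f"CTRL_{k}", "F0", "unknown",
                                      sibship_id="control", diet="FS",
                                      phenotype="normal"))
    return Pedigree(samples)
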