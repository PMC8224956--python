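"""Breeding-colony pedigree with Mendelian transmission of the causal allele.

The colony design mirrors a single spontaneous mutation carrier (the
founder, heterozygous for the semidominant allele) outcrossed to a set of
unrelated dams; carrier F1 are then intercrossed among themselves and
backcrossed to their own dam.  Each individual records, for each parent,
whether the gamete received carried the causal allele, so that gene
dropping can later be conditioned on exactly the same transmissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Individual", "PedigreeGraph", "CrossDesign", "build_pedigree"]

FOUNDER_ID = "founder"


@dataclass
class Individual:
    id: str
    sire: str | None
    dam: str | None
    sex: str  # 'M' or 'F'
    generation: int
    pat_allele: int  # causal allele on the paternally inherited haplotype
    mat_allele: int

    @property
    def causal_dosage(self) -> int:
        return self.pat_allele + self.mat_allele


@dataclass
class PedigreeGraph:
    individuals: dict[str, Individual] = field(default_factory=dict)
    founder_id: str = FOUNDER_ID

    def add(self, ind: Individual) -> None:
        if ind.id in self.individuals:
            raise ValueError(f"duplicate individual id {ind.id}")
        for p in (ind.sire, ind.dam):
            if p is not None and p not in self.individuals:
                raise ValueError(f"parent {p} of {ind.id} not in pedigree")
        self.individuals[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.sire is None and i.dam is None]

    def non_founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.sire is not None]

    def dosage(self, iid: str) -> int:
        return self.individuals[iid].causal_dosage

    def validate(self) -> None:
        """Check Mendelian consistency of the recorded causal transmissions."""
        if self.individuals[self.founder_id].causal_dosage != 1:
            raise ValueError("founder must be heterozygous for the causal allele")
        for ind in self.non_founders():
            sire = self.individuals[ind.sire]
            dam = self.individuals[ind.dam]
            for allele, parent in ((ind.pat_allele, sire), (ind.mat_allele, dam)):
                if allele not in (0, 1):
                    raise ValueError(f"{ind.id}: gamete allele must be 0/1")
                if allele == 1 and parent.causal_dosage == 0:
                    raise ValueError(f"{ind.id}: causal allele from non-carrier {parent.id}")
                if allele == 0 and parent.causal_dosage == 2:
                    raise ValueError(f"{ind.id}: missing causal allele from {parent.id}")
            if ind.generation <= max(sire.generation, dam.generation):
                raise ValueError(f"{ind.id}: generation not after parents")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": i.id,
                "sire": i.sire or "",
                "dam": i.dam or "",
                "sex": i.sex,
                "generation": i.generation,
                "dosage": i.causal_dosage,
            }
            for i in self.individuals.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class CrossDesign:
    """Family sizes for the three-generation mapping colony.

    Defaults give a colony of ~510 animals: 12 outcross litters, 12
    carrier-by-carrier intercross families, and 6 carrier-to-dam backcross
    families, comfortably covering the 188 genotyped individuals and the
    25/63/71 sequencing pools of the default scenario.
    """

    n_dams: int = 12
    f1_per_dam: int = 14
    n_intercross: int = 12
    f2_per_cross: int = 20
    n_backcross: int = 6
    bc_per_cross: int = 15

    def __post_init__(self) -> None:
        if self.n_dams < 1:
            raise ValueError("need at least one dam")
        for name in ("f1_per_dam", "f2_per_cross", "bc_per_cross",
                     "n_intercross", "n_backcross"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _gamete(parent: Individual, rng: np.random.Generator) -> int:
    d = parent.causal_dosage
    if d == 0:
        return 0
    if d == 2:
        return 1
    return int(rng.integers(2))


def build_pedigree(design: CrossDesign, rng: np.random.Generator) -> PedigreeGraph:
    """Build the colony pedigree with seeded Mendelian transmissions.

    Generation 0 is the heterozygous founder male plus ``n_dams`` unrelated
    non-carrier dams.  Generation 1 is the outcross F1; generation 2 holds
    the het x het intercross F2 and the F1 x own-dam backcross offspring.
    Raises if an intercross is requested but no carrier F1 pair exists.
    """
    ped = PedigreeGraph()
    ped.add(Individual(FOUNDER_ID, None, None, "M", 0, 1, 0))
    dams = [f"dam{j + 1:02d}" for j in range(design.n_dams)]
    for d in dams:
        ped.add(Individual(d, None, None, "F", 0, 0, 0))

    f1_by_dam: dict[str, list[Individual]] = {d: [] for d in dams}
    k = 0
    for d in dams:
        for _ in range(design.f1_per_dam):
            k += 1
            ind = Individual(
                f"F1_{k:03d}", FOUNDER_ID, d, rng.choice(["M", "F"]), 1,
                _gamete(ped[FOUNDER_ID], rng), 0,
            )
            ped.add(ind)
            f1_by_dam[d].append(ind)

    carriers = [i for d in dams for i in f1_by_dam[d] if i.causal_dosage == 1]
    males = [i for i in carriers if i.sex == "M"]
    females = [i for i in carriers if i.sex == "F"]

    k = 0
    if design.n_intercross > 0 and design.f2_per_cross > 0:
        if not males or not females:
            raise ValueError("intercross requested but no carrier F1 pair available")
        n_pairs = min(design.n_intercross, len(males), len(females))
        sires = rng.choice(len(males), size=n_pairs, replace=False)
        dams_i = rng.choice(len(females), size=n_pairs, replace=False)
        for si, di in zip(sires, dams_i):
            sire, dam = males[si], females[di]
            for _ in range(design.f2_per_cross):
                k += 1
                ped.add(Individual(
                    f"F2_{k:03d}", sire.id, dam.id, rng.choice(["M", "F"]), 2,
                    _gamete(sire, rng), _gamete(dam, rng),
                ))

    k = 0
    if design.n_backcross > 0 and design.bc_per_cross > 0:
        bc_sires = males
        if not bc_sires:
            raise ValueError("backcross requested but no carrier F1 male available")
        chosen = rng.choice(len(bc_sires), size=min(design.n_backcross, len(bc_sires)),
                            replace=False)
        for si in chosen:
            sire = bc_sires[si]
            for _ in range(design.bc_per_cross):
                k += 1
                ped.add(Individual(
                    f"BC_{k:03d}", sire.id, sire.dam, rng.choice(["M", "F"]), 2,
                    _gamete(sire, rng), 0,
                ))

    ped.validate()
    return ped
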