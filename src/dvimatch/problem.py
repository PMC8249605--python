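"""DVI problem representation, assignment counting and enumeration.

A DVI problem couples post-mortem data (victims with known sex and genotypes)
with ante-mortem data (reference families, each containing untyped missing
persons and at least one typed reference). A candidate solution is an
*assignment*: a sex-consistent partial one-to-one map from victims to missing
persons, written as a tuple whose i-th entry is a missing-person ID or ``'*'``
for an unmatched victim. The empty assignment (all ``'*'``) is the null model.

The closed-form count of sex-consistent assignments is

    n(s_F, s_M, m_F, m_M) = n0(s_F, m_F) * n0(s_M, m_M),
    n0(s, m) = sum_k C(s, k) * C(m, k) * k!

evaluated in exact integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .genetics import FrequencyDatabase, Genotype, MutationModel
from .pedigree import Pedigree

__all__ = [
    "STAR",
    "Family",
    "DVIProblem",
    "Assignment",
    "count_assignments_nosex",
    "count_assignments",
    "enumerate_assignments",
]

STAR = "*"


@dataclass(frozen=True)
class Family:
    """One ante-mortem reference family.

    ``missing`` members must be untyped pedigree members; ``genotypes`` holds
    the typed references' data as ``{marker: {individual: Genotype}}``.
    ``references`` may be declared explicitly (e.g. for simulation skeletons
    whose genotypes are yet to be drawn); by default it is derived as the set
    of typed members, in pedigree order.
    """

    fid: str
    pedigree: Pedigree
    missing: tuple[str, ...]
    genotypes: Mapping[str, Mapping[str, Genotype]] = field(default_factory=dict)
    references: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "missing", tuple(self.missing))
        object.__setattr__(
            self,
            "genotypes",
            {m: dict(g) for m, g in self.genotypes.items()},
        )
        members = set(self.pedigree.members)
        typed = {ind for genos in self.genotypes.values() for ind in genos}
        refs = tuple(self.references) or tuple(
            m for m in self.pedigree.members if m in typed
        )
        object.__setattr__(self, "references", refs)
        for mp in self.missing:
            if mp not in members:
                raise ValueError(f"missing person {mp!r} not in family {self.fid!r}")
            if mp in typed or mp in refs:
                raise ValueError(f"missing person {mp!r} is typed in family {self.fid!r}")
        if not refs:
            raise ValueError(f"family {self.fid!r} has no typed reference")
        if not set(refs) <= members or not typed <= members:
            raise ValueError(
                f"family {self.fid!r}: typed or reference non-members present"
            )


@dataclass(frozen=True)
class DVIProblem:
    """Victims, reference families, frequency database and mutation model."""

    victims: tuple[str, ...]
    victim_sex: Mapping[str, str]
    victim_genotypes: Mapping[str, Mapping[str, Genotype]]
    families: tuple[Family, ...]
    db: FrequencyDatabase
    model: MutationModel | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "victims", tuple(self.victims))
        object.__setattr__(self, "victim_sex", dict(self.victim_sex))
        object.__setattr__(
            self,
            "victim_genotypes",
            {m: dict(g) for m, g in self.victim_genotypes.items()},
        )
        object.__setattr__(self, "families", tuple(self.families))
        self._validate()

    def _validate(self) -> None:
        if len(set(self.victims)) != len(self.victims):
            raise ValueError("duplicate victim IDs")
        for v in self.victims:
            if v not in self.victim_sex:
                raise ValueError(f"victim {v!r} has no declared sex")
        seen: dict[str, str] = {}
        for fam in self.families:
            for mp in fam.missing:
                if mp in seen:
                    raise ValueError(
                        f"missing person {mp!r} declared in families "
                        f"{seen[mp]!r} and {fam.fid!r}"
                    )
                seen[mp] = fam.fid
        if set(self.victims) & set(seen):
            raise ValueError("victim IDs and missing-person IDs must be disjoint")
        for marker in self.victim_genotypes:
            self.db._check_marker(marker)
        for fam in self.families:
            for marker in fam.genotypes:
                self.db._check_marker(marker)

    # -- derived views -----------------------------------------------------

    @property
    def missing_persons(self) -> tuple[str, ...]:
        return tuple(mp for fam in self.families for mp in fam.missing)

    def mp_sex(self, mp: str) -> str:
        return self.family_of(mp).pedigree.sex[mp]

    def family_of(self, mp: str) -> Family:
        for fam in self.families:
            if mp in fam.missing:
                return fam
        raise KeyError(f"unknown missing person {mp!r}")

    def victim_data(self, victim: str) -> dict[str, Genotype]:
        """Genotypes of one victim as ``{marker: Genotype}``."""
        out = {}
        for marker, genos in self.victim_genotypes.items():
            if victim in genos:
                out[marker] = genos[victim]
        return out

    def sex_counts(self) -> tuple[int, int, int, int]:
        """(s_F, s_M, m_F, m_M)."""
        from .pedigree import FEMALE, MALE

        s_f = sum(1 for v in self.victims if self.victim_sex[v] == FEMALE)
        s_m = len(self.victims) - s_f
        mps = self.missing_persons
        m_f = sum(1 for mp in mps if self.mp_sex(mp) == FEMALE)
        return s_f, s_m, m_f, len(mps) - m_f

    def subset_markers(self, markers: Iterable[str]) -> "DVIProblem":
        """Problem restricted to the given markers (in the given order)."""
        markers = list(markers)
        sub_db = self.db.subset(markers)
        model = self.model
        if model is not None:
            if model.kind == "proportional" and model.rate > 0:
                model = MutationModel.proportional(sub_db, model.rate)
            else:
                model = MutationModel.none(sub_db)
        return DVIProblem(
            victims=self.victims,
            victim_sex=self.victim_sex,
            victim_genotypes={
                m: self.victim_genotypes.get(m, {}) for m in markers
            },
            families=tuple(
                Family(
                    fid=f.fid,
                    pedigree=f.pedigree,
                    missing=f.missing,
                    genotypes={m: f.genotypes.get(m, {}) for m in markers},
                    references=f.references,
                )
                for f in self.families
            ),
            db=sub_db,
            model=model,
        )


@dataclass(frozen=True)
class Assignment:
    """Tuple of length s: entry i is the match for victim i, or ``'*'``."""

    pairing: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairing", tuple(self.pairing))
        matched = [x for x in self.pairing if x != STAR]
        if len(set(matched)) != len(matched):
            raise ValueError(f"assignment {self.pairing} repeats a missing person")

    def __iter__(self) -> Iterator[str]:
        return iter(self.pairing)

    def __len__(self) -> int:
        return len(self.pairing)

    def __getitem__(self, i: int) -> str:
        return self.pairing[i]

    @property
    def is_empty(self) -> bool:
        return all(x == STAR for x in self.pairing)

    def pairs(self, victims: Iterable[str]) -> tuple[tuple[str, str], ...]:
        """(victim, missing person) pairs of the matched entries."""
        return tuple(
            (v, mp) for v, mp in zip(victims, self.pairing) if mp != STAR
        )

    @classmethod
    def empty(cls, s: int) -> "Assignment":
        return cls((STAR,) * s)

    def __str__(self) -> str:
        return "(" + ", ".join(self.pairing) + ")"


def count_assignments_nosex(s: int, m: int) -> int:
    """Number of assignments of ``s`` victims to ``m`` missing persons, sex ignored."""
    if s < 0 or m < 0:
        raise ValueError("counts must be non-negative")
    return sum(
        math.comb(s, k) * math.comb(m, k) * math.factorial(k)
        for k in range(min(s, m) + 1)
    )


def count_assignments(s_f: int, s_m: int, m_f: int, m_m: int) -> int:
    """Sex-consistent assignment count: the female and male classes factorize."""
    if min(s_f, s_m, m_f, m_m) < 0:
        raise ValueError("counts must be non-negative")
    return count_assignments_nosex(s_f, m_f) * count_assignments_nosex(s_m, m_m)


def enumerate_assignments(
    problem: DVIProblem,
    forbidden: set[tuple[str, str]] | None = None,
    *,
    ignore_sex: bool = False,
) -> list[Assignment]:
    """All sex-consistent assignments, in deterministic order.

    Enumeration is recursive by victim index; for each victim the candidates
    are ``'*'`` first, then missing persons in input order. ``forbidden`` is a
    set of (victim, MP) pairs to exclude. With ``ignore_sex`` everyone is
    treated as a single sex class. The empty assignment is always element 0.
    """
    forbidden = forbidden or set()
    mps = problem.missing_persons
    victims = problem.victims
    out: list[Assignment] = []
    current: list[str] = []
    used: set[str] = set()

    def recurse(i: int) -> None:
        if i == len(victims):
            out.append(Assignment(tuple(current)))
            return
        v = victims[i]
        current.append(STAR)
        recurse(i + 1)
        current.pop()
        for mp in mps:
            if mp in used or (v, mp) in forbidden:
                continue
            if not ignore_sex and problem.victim_sex[v] != problem.mp_sex(mp):
                continue
            current.append(mp)
            used.add(mp)
            recurse(i + 1)
            used.discard(mp)
            current.pop()

    recurse(0)
    return out
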