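"""Pedigree structures and the PED text format.

A pedigree is a set of individuals with optional father/mother links and a
binary sex. Non-founders must have exactly two parents of opposite sexes.
Likelihood computation (see :mod:`dvimatch.peeling`) requires loop-free
pedigrees: no individual may descend from a couple along two disjoint paths
and no marriage chain may close a cycle. :meth:`Pedigree.has_loop` implements
this check on the marriage graph.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = ["MALE", "FEMALE", "Pedigree", "parse_ped", "format_ped"]

MALE = "male"
FEMALE = "female"

_SEX_CODES = {"1": MALE, "2": FEMALE}
_SEX_TO_CODE = {MALE: "1", FEMALE: "2"}


@dataclass(frozen=True)
class Pedigree:
    """Immutable pedigree: members with parent links and sexes.

    Parameters
    ----------
    members
        Ordered individual IDs.
    father, mother
        Maps from child ID to parent ID; founders appear in neither.
    sex
        Map from individual ID to ``"male"`` / ``"female"``.
    """

    members: tuple[str, ...]
    father: Mapping[str, str] = field(default_factory=dict)
    mother: Mapping[str, str] = field(default_factory=dict)
    sex: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        object.__setattr__(self, "father", dict(self.father))
        object.__setattr__(self, "mother", dict(self.mother))
        object.__setattr__(self, "sex", dict(self.sex))
        self._validate()

    def _validate(self) -> None:
        members = set(self.members)
        if len(members) != len(self.members):
            raise ValueError("duplicate individual IDs in pedigree")
        for ind in self.members:
            if self.sex.get(ind) not in (MALE, FEMALE):
                raise ValueError(f"individual {ind!r}: sex must be male/female")
            has_f, has_m = ind in self.father, ind in self.mother
            if has_f != has_m:
                raise ValueError(
                    f"individual {ind!r} must have two parents or none"
                )
            if has_f:
                f, m = self.father[ind], self.mother[ind]
                for parent in (f, m):
                    if parent not in members:
                        raise ValueError(
                            f"parent {parent!r} of {ind!r} is not a member"
                        )
                if self.sex[f] != MALE:
                    raise ValueError(f"father {f!r} of {ind!r} is not male")
                if self.sex[m] != FEMALE:
                    raise ValueError(f"mother {m!r} of {ind!r} is not female")
        extra = set(self.father) - members
        if extra:
            raise ValueError(f"parent links for non-members: {sorted(extra)}")
        # acyclicity of descent
        dag = nx.DiGraph()
        dag.add_nodes_from(self.members)
        for child in self.father:
            dag.add_edge(self.father[child], child)
            dag.add_edge(self.mother[child], child)
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("parent links form a cycle")

    # -- structure ---------------------------------------------------------

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m not in self.father)

    @property
    def nonfounders(self) -> tuple[str, ...]:
        return tuple(m for m in self.members if m in self.father)

    def parents(self, ind: str) -> tuple[str, str] | None:
        if ind in self.father:
            return (self.father[ind], self.mother[ind])
        return None

    def topological_order(self) -> tuple[str, ...]:
        """Members ordered founders-first, parents before children."""
        dag = nx.DiGraph()
        dag.add_nodes_from(self.members)
        for child in self.father:
            dag.add_edge(self.father[child], child)
            dag.add_edge(self.mother[child], child)
        order = list(nx.lexicographical_topological_sort(
            dag, key=lambda n: self.members.index(n)
        ))
        return tuple(order)

    def has_loop(self) -> bool:
        """True if the pedigree contains a loop.

        The marriage graph has one node per individual plus one node per
        mating couple, with edges partner--couple and couple--child. The
        pedigree is loop-free iff this graph is a forest.
        """
        g = nx.Graph()
        g.add_nodes_from(("ind", m) for m in self.members)
        for child in self.father:
            couple = ("couple", self.father[child], self.mother[child])
            g.add_edge(("ind", self.father[child]), couple)
            g.add_edge(("ind", self.mother[child]), couple)
            g.add_edge(couple, ("ind", child))
        return g.number_of_edges() > g.number_of_nodes() - nx.number_connected_components(g)

    def relabel(self, mapping: Mapping[str, str]) -> "Pedigree":
        """Pedigree with individual IDs renamed through ``mapping``."""
        def ren(x: str) -> str:
            return mapping.get(x, x)

        return Pedigree(
            members=tuple(ren(m) for m in self.members),
            father={ren(c): ren(p) for c, p in self.father.items()},
            mother={ren(c): ren(p) for c, p in self.mother.items()},
            sex={ren(m): s for m, s in self.sex.items()},
        )


def parse_ped(text: str) -> dict[str, Pedigree]:
    """Parse PED-style text into pedigrees keyed by family ID.

    Columns: ``family_id individual_id father_id mother_id sex`` with ``0``
    meaning "no parent" and sex coded 1=male, 2=female. Whitespace-separated;
    lines starting with ``#`` are ignored.
    """
    rows: dict[str, list[tuple[str, str, str, str]]] = {}
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(
                f"PED line {lineno}: expected 5 columns, got {len(parts)}"
            )
        fam, ind, fa, mo, sexcode = parts
        if sexcode not in _SEX_CODES:
            raise ValueError(
                f"PED line {lineno}: sex must be 1 (male) or 2 (female), "
                f"got {sexcode!r}"
            )
        if (fa == "0") != (mo == "0"):
            raise ValueError(
                f"PED line {lineno}: individual {ind!r} must have both "
                "parents or neither"
            )
        rows.setdefault(fam, []).append((ind, fa, mo, _SEX_CODES[sexcode]))
    out: dict[str, Pedigree] = {}
    for fam, entries in rows.items():
        members = tuple(e[0] for e in entries)
        father = {e[0]: e[1] for e in entries if e[1] != "0"}
        mother = {e[0]: e[2] for e in entries if e[2] != "0"}
        sex = {e[0]: e[3] for e in entries}
        try:
            out[fam] = Pedigree(members, father, mother, sex)
        except ValueError as exc:
            raise ValueError(f"family {fam!r}: {exc}") from exc
    return out


def format_ped(pedigrees: Mapping[str, Pedigree]) -> str:
    """Inverse of :func:`parse_ped`."""
    lines = []
    for fam, ped in pedigrees.items():
        for ind in ped.members:
            fa, mo = ped.father.get(ind, "0"), ped.mother.get(ind, "0")
            lines.append(f"{fam}\t{ind}\t{fa}\t{mo}\t{_SEX_TO_CODE[ped.sex[ind]]}")
    return "\n".join(lines) + "\n"
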