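"""Profile simulation, built-in toy fixtures and power experiments.

Gene dropping samples founder genotypes from Hardy-Weinberg equilibrium and
transmits alleles down the pedigree through the mutation model. Conditional
simulation of a DVI problem merges the true victim identities into their
missing persons' slots, drops genotypes for every family (plus independent
singleton draws for unmatched victims) and extracts the victims' and
references' profiles. True-positive-rate experiments replay the search
algorithms on many such replicates.

The two built-in fixtures are small single-marker problems whose every
likelihood ratio, log-likelihood and posterior can be checked by hand:

* ``fig1`` -- three victims against two reference families (one reference
  each); a 10-allele equifrequent marker. The missing person M1 has married
  into family 1 and is unrelated to its reference, so he can only be
  identified jointly with M2.
* ``fig2`` -- three victims against one three-generation family whose only
  reference is the grandmother R1; a 3-allele marker (frequencies 0.05,
  0.05, 0.90) with genotypes chosen so that the best single pairing
  obstructs the jointly optimal solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import FrequencyDatabase, Genotype, MutationModel
from .pedigree import FEMALE, MALE, Pedigree
from .peeling import GenotypeMap
from .problem import STAR, Assignment, DVIProblem, Family
from .search import algorithm1, algorithm2, algorithm3

__all__ = [
    "SimulationConfig",
    "gene_drop",
    "simulate_problem",
    "tpr_experiment",
    "fixture",
    "fixture_structure",
    "synthetic_panel",
    "synthetic_planecrash_problem",
    "synthetic_large_family_problem",
]


# ---------------------------------------------------------------------------
# gene dropping


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def gene_drop(
    ped: Pedigree,
    db: FrequencyDatabase,
    model: MutationModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> dict[str, dict[str, Genotype]]:
    """Simulate genotypes for every pedigree member at every marker.

    Founders receive two independent draws from the allele frequencies;
    each non-founder samples one allele from each parent (uniformly among
    the parent's two) and passes it through the mutation model's transition
    matrix. Deterministic for a fixed seed: members are visited in
    topological order (founders before descendants), markers in database
    order.
    """
    if ped.has_loop():
        raise ValueError("looped pedigrees are unsupported (loops unsupported)")
    if model is None:
        model = MutationModel.none(db)
    rng = _rng(seed)
    order = ped.topological_order()
    out: dict[str, dict[str, Genotype]] = {m: {} for m in db.markers}
    for marker in db.markers:
        alleles = db.alleles(marker)
        n = len(alleles)
        p = db.freqs(marker)
        trans = model.transition(marker)
        carried: dict[str, tuple[int, int]] = {}
        for ind in order:
            par = ped.parents(ind)
            if par is None:
                a, b = rng.choice(n, size=2, p=p)
            else:
                f, m = par
                a = trans[carried[f][rng.integers(2)]]
                a = rng.choice(n, p=a)
                b = trans[carried[m][rng.integers(2)]]
                b = rng.choice(n, p=b)
            carried[ind] = (int(a), int(b))
            out[marker][ind] = Genotype(alleles[int(a)], alleles[int(b)])
    return out


def simulate_problem(
    problem: DVIProblem,
    true_assignment: Assignment,
    seed: int | np.random.Generator | None = None,
) -> DVIProblem:
    """A copy of ``problem`` with fresh genotypes drawn under a true solution.

    Victims paired in ``true_assignment`` take the genotypes gene-dropped for
    their missing person; unmatched victims are drawn as independent
    Hardy-Weinberg singletons; references take their dropped genotypes. The
    problem structure (IDs, sexes, families, markers) is unchanged.
    """
    rng = _rng(seed)
    if len(true_assignment) != len(problem.victims):
        raise ValueError("true assignment length must equal the number of victims")
    pairs = {}
    for v, mp in zip(problem.victims, true_assignment.pairing):
        if mp == STAR:
            continue
        if problem.victim_sex[v] != problem.mp_sex(mp):
            raise ValueError(
                f"true assignment pairs {v!r} ({problem.victim_sex[v]}) with "
                f"{mp!r} ({problem.mp_sex(mp)})"
            )
        pairs[mp] = v
    victim_genos: dict[str, dict[str, Genotype]] = {m: {} for m in problem.db.markers}
    new_families = []
    for fam in problem.families:
        dropped = gene_drop(fam.pedigree, problem.db, problem.model, rng)
        ref_ids = set(fam.references)
        fam_genos: dict[str, dict[str, Genotype]] = {}
        for marker, genos in dropped.items():
            fam_genos[marker] = {r: genos[r] for r in ref_ids}
            for mp in fam.missing:
                if mp in pairs:
                    victim_genos[marker][pairs[mp]] = genos[mp]
        new_families.append(
            Family(fid=fam.fid, pedigree=fam.pedigree, missing=fam.missing,
                   genotypes=fam_genos, references=fam.references)
        )
    unmatched = [
        v for v, mp in zip(problem.victims, true_assignment.pairing) if mp == STAR
    ]
    for v in unmatched:
        singleton = Pedigree(
            members=(v,), sex={v: problem.victim_sex[v]}
        )
        dropped = gene_drop(singleton, problem.db, problem.model, rng)
        for marker, genos in dropped.items():
            victim_genos[marker][v] = genos[v]
    return DVIProblem(
        victims=problem.victims,
        victim_sex=problem.victim_sex,
        victim_genotypes=victim_genos,
        families=tuple(new_families),
        db=problem.db,
        model=problem.model,
    )


# ---------------------------------------------------------------------------
# TPR experiments


@dataclass(frozen=True)
class SimulationConfig:
    """Design of a true-positive-rate experiment.

    ``marker_counts`` are prefixes of the database marker list; ``threshold``
    is the LR threshold applied by every algorithm (for ``alg3`` it applies
    to the top joint LR against the null; ``alg3_best`` ignores it).
    """

    true_assignment: Assignment
    n_reps: int = 200
    marker_counts: tuple[int, ...] = (5, 10)
    seed: int = 0
    threshold: float = 10_000.0
    algorithms: tuple[str, ...] = ("alg1", "alg2", "alg3", "alg3_best")

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not self.marker_counts:
            raise ValueError("marker_counts must be non-empty")


def _solution_set(solutions: Iterable[Assignment]) -> set[tuple[str, ...]]:
    return {a.pairing for a in solutions}


def tpr_experiment(config: SimulationConfig, problem: DVIProblem) -> pd.DataFrame:
    """Estimated true positive rates per algorithm and marker count.

    A replicate counts as a true positive when the reported solution set is
    exactly the true assignment (``tpr``, the default reading) or when the
    truth is among the tied solutions (``tpr_member``). ``alg3`` additionally
    requires the top joint LR against the null to reach the threshold;
    ``alg3_best`` is the same search with the threshold ignored.

    Returns a tidy DataFrame with columns ``markers``, ``algorithm``,
    ``tpr``, ``tpr_member`` and ``n_reps``.
    """
    truth = config.true_assignment.pairing
    max_count = max(config.marker_counts)
    if max_count > len(problem.db.markers):
        raise ValueError(
            f"marker count {max_count} exceeds database ({len(problem.db.markers)})"
        )
    rows = []
    rng = np.random.default_rng(config.seed)
    exact = {
        (k, alg): 0 for k in config.marker_counts for alg in config.algorithms
    }
    member = {
        (k, alg): 0 for k in config.marker_counts for alg in config.algorithms
    }
    for _ in range(config.n_reps):
        sim = simulate_problem(problem, config.true_assignment, rng)
        for k in config.marker_counts:
            sub = sim.subset_markers(problem.db.markers[:k])
            for alg in config.algorithms:
                if alg == "alg1":
                    sols = _solution_set(algorithm1(sub, config.threshold).solutions)
                elif alg == "alg2":
                    sols = _solution_set(algorithm2(sub, config.threshold).solutions)
                elif alg in ("alg3", "alg3_best"):
                    res = algorithm3(sub, config.threshold)
                    sols = _solution_set(res.solutions)
                    if alg == "alg3" and len(res.table):
                        if float(res.table["LR"].iloc[0]) < config.threshold:
                            sols = set()
                else:
                    raise ValueError(f"unknown algorithm {alg!r}")
                if sols == {truth}:
                    exact[(k, alg)] += 1
                if truth in sols:
                    member[(k, alg)] += 1
    for k in config.marker_counts:
        for alg in config.algorithms:
            rows.append(
                {
                    "markers": k,
                    "algorithm": alg,
                    "tpr": exact[(k, alg)] / config.n_reps,
                    "tpr_member": member[(k, alg)] / config.n_reps,
                    "n_reps": config.n_reps,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# built-in fixtures


def fixture(name: str) -> DVIProblem:
    """Built-in single-marker toy problems ``fig1`` and ``fig2``."""
    if name == "fig1":
        return _fig1()
    if name == "fig2":
        return _fig2()
    raise ValueError(f"unknown fixture {name!r}; expected 'fig1' or 'fig2'")


def _fig1() -> DVIProblem:
    db = FrequencyDatabase.equifrequent(["L1"], 10)
    fam1 = Family(
        fid="F1",
        pedigree=Pedigree(
            members=("M1", "R1", "M2"),
            father={"M2": "M1"},
            mother={"M2": "R1"},
            sex={"M1": MALE, "R1": FEMALE, "M2": MALE},
        ),
        missing=("M1", "M2"),
        genotypes={"L1": {"R1": Genotype("2", "2")}},
    )
    fam2 = Family(
        fid="F2",
        pedigree=Pedigree(
            members=("FA2", "R2", "M3"),
            father={"M3": "FA2"},
            mother={"M3": "R2"},
            sex={"FA2": MALE, "R2": FEMALE, "M3": FEMALE},
        ),
        missing=("M3",),
        genotypes={"L1": {"R2": Genotype("3", "3")}},
    )
    return DVIProblem(
        victims=("V1", "V2", "V3"),
        victim_sex={"V1": MALE, "V2": MALE, "V3": FEMALE},
        victim_genotypes={
            "L1": {
                "V1": Genotype("1", "1"),
                "V2": Genotype("1", "2"),
                "V3": Genotype("3", "4"),
            }
        },
        families=(fam1, fam2),
        db=db,
        model=MutationModel.none(db),
    )


def _fig2() -> DVIProblem:
    db = FrequencyDatabase(
        {"L1": {"1": 0.05, "2": 0.05, "3": 0.90}}
    )
    fam = Family(
        fid="F1",
        pedigree=Pedigree(
            members=("M1", "R1", "M2", "SP", "M3"),
            father={"M2": "M1", "M3": "M2"},
            mother={"M2": "R1", "M3": "SP"},
            sex={"M1": MALE, "R1": FEMALE, "M2": MALE, "SP": FEMALE, "M3": MALE},
        ),
        missing=("M1", "M2", "M3"),
        genotypes={"L1": {"R1": Genotype("1", "1")}},
    )
    return DVIProblem(
        victims=("V1", "V2", "V3"),
        victim_sex={"V1": MALE, "V2": MALE, "V3": MALE},
        victim_genotypes={
            "L1": {
                "V1": Genotype("1", "1"),
                "V2": Genotype("2", "2"),
                "V3": Genotype("1", "2"),
            }
        },
        families=(fam,),
        db=db,
        model=MutationModel.none(db),
    )


def fixture_structure(name: str, db: FrequencyDatabase) -> DVIProblem:
    """A fixture's structure (IDs, sexes, families) bound to another panel.

    Genotypes are left empty; pass the result to :func:`simulate_problem`
    to draw profiles under a chosen true assignment.
    """
    base = fixture(name)
    return DVIProblem(
        victims=base.victims,
        victim_sex=base.victim_sex,
        victim_genotypes={},
        families=tuple(
            Family(fid=f.fid, pedigree=f.pedigree, missing=f.missing,
                   references=f.references)
            for f in base.families
        ),
        db=db,
    )


# ---------------------------------------------------------------------------
# synthetic panels and case-study-shaped problems


def synthetic_panel(n_markers: int = 10, n_alleles: int = 10) -> FrequencyDatabase:
    """Synthetic multi-allelic marker panel with a fixed triangular spectrum.

    Allele k of every marker has frequency proportional to k, giving an
    expected heterozygosity of about 0.87 for ten alleles -- comparable to
    forensic STR panels. Deterministic (no randomness).
    """
    total = n_alleles * (n_alleles + 1) / 2
    freqs = {str(k): k / total for k in range(1, n_alleles + 1)}
    return FrequencyDatabase(
        {f"S{i + 1}": dict(freqs) for i in range(n_markers)}
    )


def synthetic_planecrash_problem(
    seed: int = 0, n_markers: int = 15
) -> tuple[DVIProblem, Assignment]:
    """Synthetic problem shaped like a plane-crash case.

    Eight victims against five reference families, each family holding one
    missing person and one typed reference (a parent of the missing person).
    Genotypes are simulated under the returned true assignment, which pairs
    five victims and leaves three unmatched. This is a synthetic stand-in of
    the same dimensions as a published case whose genotypes are not public.
    """
    db = synthetic_panel(n_markers=n_markers, n_alleles=10)
    sexes = [MALE, FEMALE, MALE, MALE, FEMALE]
    families = []
    for i in range(5):
        mp, ref, sp = f"M{i + 1}", f"R{i + 1}", f"SP{i + 1}"
        ped = Pedigree(
            members=(ref, sp, mp),
            father={mp: ref if i % 2 == 0 else sp},
            mother={mp: sp if i % 2 == 0 else ref},
            sex={
                ref: MALE if i % 2 == 0 else FEMALE,
                sp: FEMALE if i % 2 == 0 else MALE,
                mp: sexes[i],
            },
        )
        families.append(
            Family(fid=f"F{i + 1}", pedigree=ped, missing=(mp,), references=(ref,))
        )
    victims = tuple(f"V{i + 1}" for i in range(8))
    victim_sex = {
        "V1": MALE, "V2": FEMALE, "V3": MALE, "V4": MALE,
        "V5": FEMALE, "V6": MALE, "V7": FEMALE, "V8": MALE,
    }
    truth = Assignment(("M1", "M2", STAR, STAR, "M5", "M3", STAR, "M4"))
    skeleton = DVIProblem(
        victims=victims,
        victim_sex=victim_sex,
        victim_genotypes={},
        families=tuple(families),
        db=db,
    )
    return simulate_problem(skeleton, truth, seed), truth


def synthetic_large_family_problem(
    seed: int = 0, n_markers: int = 13
) -> tuple[DVIProblem, Assignment]:
    """Synthetic problem shaped like a large-reference-family case.

    A single three-generation pedigree with twelve missing persons (six
    female, six male) and six typed references, searched with five victims
    (three female, two male); the a-priori assignment space has 9847
    elements. Genotypes are simulated under the returned true assignment.
    This is a synthetic stand-in of the same dimensions as a published case
    whose genotypes are not public.
    """
    db = synthetic_panel(n_markers=n_markers, n_alleles=10)
    members = {
        # gen 0: founding couple, both missing
        "M1": (MALE, None),
        "M2": (FEMALE, None),
        # gen 1: their children and spouses
        "M3": (MALE, ("M1", "M2")),
        "M4": (FEMALE, ("M1", "M2")),
        "M5": (MALE, ("M1", "M2")),
        "R1": (FEMALE, ("M1", "M2")),
        "M6": (FEMALE, None),   # spouse of M3
        "M7": (MALE, None),     # spouse of M4
        "S5": (FEMALE, None),   # untyped spouse of M5
        "R2": (MALE, None),     # spouse of R1
        # gen 2
        "M8": (MALE, ("M3", "M6")),
        "R3": (FEMALE, ("M3", "M6")),
        "M9": (FEMALE, ("M7", "M4")),
        "R4": (MALE, ("M7", "M4")),
        "M10": (FEMALE, ("M5", "S5")),
        "M11": (MALE, ("M5", "S5")),
        "R5": (FEMALE, ("M5", "S5")),
        "M12": (FEMALE, ("R2", "R1")),
        "R6": (FEMALE, ("R2", "R1")),
    }
    ped = Pedigree(
        members=tuple(members),
        father={c: p[0] for c, (s, p) in members.items() if p},
        mother={c: p[1] for c, (s, p) in members.items() if p},
        sex={c: s for c, (s, p) in members.items()},
    )
    missing = tuple(f"M{i}" for i in range(1, 13))
    refs = tuple(f"R{i}" for i in range(1, 7))
    fam = Family(fid="F1", pedigree=ped, missing=missing, references=refs)
    victims = ("V1", "V2", "V3", "V4", "V5")
    victim_sex = {
        "V1": FEMALE, "V2": FEMALE, "V3": FEMALE, "V4": MALE, "V5": MALE,
    }
    truth = Assignment(("M2", "M10", "M12", "M8", "M11"))
    skeleton = DVIProblem(
        victims=victims,
        victim_sex=victim_sex,
        victim_genotypes={},
        families=(fam,),
        db=db,
    )
    return simulate_problem(skeleton, truth, seed), truth
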