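"""Shared fixtures: toy problems and randomized pedigree/problem generators."""

from __future__ import annotations

import numpy as np
import pytest

from dvimatch import (
    STAR,
    Assignment,
    DVIProblem,
    Family,
    FrequencyDatabase,
    Genotype,
    MutationModel,
    Pedigree,
    fixture,
    gene_drop,
    simulate_problem,
)
from dvimatch.pedigree import FEMALE, MALE


@pytest.fixture(scope="session")
def fig1() -> DVIProblem:
    return fixture("fig1")


@pytest.fixture(scope="session")
def fig2() -> DVIProblem:
    return fixture("fig2")


def random_frequency_db(
    rng: np.random.Generator, n_markers: int = 1, n_alleles: int = 5
) -> FrequencyDatabase:
    data = {}
    for i in range(n_markers):
        freqs = rng.dirichlet(np.ones(n_alleles) * 2.0)
        freqs = np.clip(freqs, 0.01, None)
        freqs /= freqs.sum()
        data[f"L{i + 1}"] = {str(a + 1): float(f) for a, f in enumerate(freqs)}
    return FrequencyDatabase(data)


def random_pedigree(
    rng: np.random.Generator, max_members: int = 8
) -> Pedigree:
    """Random loop-free pedigree grown by adding children or founder spouses."""
    counter = [0]

    def fresh(sex: str) -> str:
        counter[0] += 1
        return f"I{counter[0]}{'m' if sex == MALE else 'f'}"

    members: list[str] = []
    sex: dict[str, str] = {}
    father: dict[str, str] = {}
    mother: dict[str, str] = {}

    def add(ind: str, s: str) -> str:
        members.append(ind)
        sex[ind] = s
        return ind

    add(fresh(MALE), MALE)
    add(fresh(FEMALE), FEMALE)
    couples = [(members[0], members[1])]
    while len(members) < max_members and rng.random() < 0.85:
        if rng.random() < 0.6 or len(members) + 2 > max_members:
            f, m = couples[rng.integers(len(couples))]
            child = add(fresh(MALE if rng.random() < 0.5 else FEMALE),
                        MALE if counter[0] % 2 else FEMALE)
            sex[child] = MALE if child.endswith("m") else FEMALE
            father[child], mother[child] = f, m
        else:
            # marry an existing individual to a brand-new founder
            ind = members[int(rng.integers(len(members)))]
            spouse = add(fresh(FEMALE if sex[ind] == MALE else MALE),
                         FEMALE if sex[ind] == MALE else MALE)
            couple = (ind, spouse) if sex[ind] == MALE else (spouse, ind)
            couples.append(couple)
            child = add(fresh(MALE), MALE if rng.random() < 0.5 else FEMALE)
            sex[child] = MALE if rng.random() < 0.5 else FEMALE
            father[child], mother[child] = couple
    return Pedigree(tuple(members), father, mother, sex)


def random_typed_data(
    rng: np.random.Generator,
    ped: Pedigree,
    db: FrequencyDatabase,
    model: MutationModel | None = None,
    max_untyped: int = 3,
):
    """Gene-drop the pedigree, then hide genotypes of a few members."""
    dropped = gene_drop(ped, db, model, rng)
    n_untyped = int(rng.integers(0, max_untyped + 1))
    hidden = set(
        rng.choice(len(ped.members), size=min(n_untyped, len(ped.members)),
                   replace=False)
    )
    hidden_ids = {ped.members[i] for i in hidden}
    return {
        marker: {ind: g for ind, g in genos.items() if ind not in hidden_ids}
        for marker, genos in dropped.items()
    }


def random_problem(
    rng: np.random.Generator,
    s_max: int = 4,
    m_max: int = 4,
    n_markers: int = 1,
    n_alleles: int = 5,
) -> DVIProblem:
    """Random small DVI problem with genotypes simulated under a random truth."""
    db = random_frequency_db(rng, n_markers, n_alleles)
    n_fam = int(rng.integers(1, 3))
    families = []
    mp_counter = 0
    for i in range(n_fam):
        f, m, c1, c2 = f"FA{i}", f"MO{i}", f"C{i}a", f"C{i}b"
        ped = Pedigree(
            members=(f, m, c1, c2),
            father={c1: f, c2: f},
            mother={c1: m, c2: m},
            sex={f: MALE, m: FEMALE, c1: MALE, c2: FEMALE},
        )
        candidates = [f, m, c1, c2]
        ref = candidates[int(rng.integers(4))]
        missing = [x for x in candidates if x != ref]
        rng.shuffle(missing)
        keep = missing[: int(rng.integers(1, min(len(missing), m_max) + 1))]
        rename = {mp: f"M{mp_counter + k + 1}" for k, mp in enumerate(keep)}
        mp_counter += len(keep)
        ped = ped.relabel(rename)
        families.append(
            Family(
                fid=f"F{i + 1}",
                pedigree=ped,
                missing=tuple(rename.values()),
                references=(ref,),
            )
        )
    s = int(rng.integers(1, s_max + 1))
    victims = tuple(f"V{i + 1}" for i in range(s))
    victim_sex = {
        v: MALE if rng.random() < 0.5 else FEMALE for v in victims
    }
    skeleton = DVIProblem(
        victims=victims,
        victim_sex=victim_sex,
        victim_genotypes={},
        families=tuple(families),
        db=db,
    )
    # random sex-consistent truth
    mps = list(skeleton.missing_persons)
    rng.shuffle(mps)
    pairing = []
    used = set()
    for v in victims:
        choice = STAR
        if rng.random() < 0.6:
            for mp in mps:
                if mp not in used and skeleton.mp_sex(mp) == victim_sex[v]:
                    choice = mp
                    used.add(mp)
                    break
        pairing.append(choice)
    return simulate_problem(skeleton, Assignment(tuple(pairing)), rng)
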