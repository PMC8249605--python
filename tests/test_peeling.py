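"""Pedigree likelihoods: peeling vs brute force, factorization, mutation limits."""

import math

import numpy as np
import pytest

from dvimatch import (
    FrequencyDatabase,
    Genotype,
    MutationModel,
    Pedigree,
    build_proportional_model,
    hwe_genotype_probability,
    pedigree_loglik,
    pedigree_loglik_bruteforce,
)
from dvimatch.pedigree import FEMALE, MALE

from conftest import random_frequency_db, random_pedigree, random_typed_data


@pytest.fixture(scope="module")
def db5():
    return FrequencyDatabase.equifrequent(["L1", "L2"], 5)


def trio() -> Pedigree:
    return Pedigree(
        members=("F", "M", "C"),
        father={"C": "F"},
        mother={"C": "M"},
        sex={"F": MALE, "M": FEMALE, "C": MALE},
    )


class TestBasics:
    def test_empty_data_gives_zero(self, db5):
        assert pedigree_loglik(trio(), {}, db5) == 0.0
        assert pedigree_loglik(trio(), {"L1": {}}, db5) == 0.0

    def test_singleton_equals_hwe(self, db5):
        ped = Pedigree(("A",), sex={"A": FEMALE})
        g = Genotype("1", "2")
        ll = pedigree_loglik(ped, {"L1": {"A": g}}, db5)
        assert ll == pytest.approx(math.log(hwe_genotype_probability(g, "L1", db5)))
        assert pedigree_loglik_bruteforce(ped, {"L1": {"A": g}}, db5) == pytest.approx(ll)

    def test_mendelian_exclusion_is_minus_inf(self, db5):
        data = {"L1": {"F": Genotype("1", "1"), "C": Genotype("2", "2")}}
        assert pedigree_loglik(trio(), data, db5) == -math.inf

    def test_fig1_null_pedigree(self, fig1):
        # all five typed individuals as unrelated singletons: log(4e-10)
        members = ["V1", "V2", "V3", "R1", "R2"]
        genos = {}
        for source in [fig1.victim_genotypes] + [f.genotypes for f in fig1.families]:
            for marker, table in source.items():
                genos.setdefault(marker, {}).update(table)
        ped = Pedigree(tuple(members), sex={m: MALE for m in members})
        ll = pedigree_loglik(ped, genos, fig1.db)
        assert ll == pytest.approx(math.log(4e-10), abs=1e-10)
        assert round(ll, 2) == -21.64

    def test_looped_pedigree_rejected(self, db5):
        ped = Pedigree(
            members=("F", "M", "S", "D", "X"),
            father={"S": "F", "D": "F", "X": "S"},
            mother={"S": "M", "D": "M", "X": "D"},
            sex={"F": MALE, "M": FEMALE, "S": MALE, "D": FEMALE, "X": MALE},
        )
        with pytest.raises(ValueError, match="loops unsupported"):
            pedigree_loglik(ped, {"L1": {"X": Genotype("1", "1")}}, db5)

    def test_nonmember_typed_rejected(self, db5):
        with pytest.raises(ValueError, match="not a pedigree member"):
            pedigree_loglik(trio(), {"L1": {"ZZ": Genotype("1", "1")}}, db5)


class TestAgainstBruteForce:
    def test_fixture_pedigrees(self, fig1, fig2):
        for problem in (fig1, fig2):
            for fam in problem.families:
                exact = pedigree_loglik(fam.pedigree, fam.genotypes, problem.db)
                brute = pedigree_loglik_bruteforce(
                    fam.pedigree, fam.genotypes, problem.db
                )
                assert exact == pytest.approx(brute, abs=1e-10)

    def test_randomized_pedigrees(self):
        rng = np.random.default_rng(20240917)
        checked = 0
        for _ in range(100):
            ped = random_pedigree(rng, max_members=8)
            db = random_frequency_db(rng, n_markers=1, n_alleles=5)
            model = (
                build_proportional_model(db, 0.002)
                if rng.random() < 0.3
                else None
            )
            data = random_typed_data(rng, ped, db, model, max_untyped=3)
            exact = pedigree_loglik(ped, data, db, model)
            brute = pedigree_loglik_bruteforce(ped, data, db, model)
            assert exact == pytest.approx(brute, abs=1e-10)
            checked += 1
        assert checked == 100

    def test_brute_force_guard(self):
        db = FrequencyDatabase.equifrequent(["L1"], 10)
        members = tuple(f"I{i}" for i in range(12))
        ped = Pedigree(members, sex={m: MALE for m in members})
        with pytest.raises(ValueError, match="too large"):
            pedigree_loglik_bruteforce(ped, {"L1": {"I0": Genotype("1", "1")}}, db)


class TestStructuralProperties:
    def test_marker_factorization(self, db5):
        data = {
            "L1": {"F": Genotype("1", "2"), "C": Genotype("2", "3")},
            "L2": {"F": Genotype("4", "4"), "C": Genotype("4", "5")},
        }
        both = pedigree_loglik(trio(), data, db5)
        solo = sum(
            pedigree_loglik(trio(), {m: data[m]}, db5) for m in ("L1", "L2")
        )
        assert both == pytest.approx(solo, abs=1e-12)

    def test_relabeling_invariance(self, db5):
        ped = trio()
        data = {"L1": {"F": Genotype("1", "2"), "C": Genotype("2", "3")}}
        mapping = {"F": "papa", "M": "mama", "C": "kid"}
        renamed = ped.relabel(mapping)
        data2 = {"L1": {mapping.get(k, k): v for k, v in data["L1"].items()}}
        assert pedigree_loglik(renamed, data2, db5) == pytest.approx(
            pedigree_loglik(ped, data, db5), abs=1e-12
        )

    def test_rate_zero_proportional_equals_no_mutation(self, db5):
        data = {"L1": {"F": Genotype("1", "1"), "M": Genotype("2", "3"),
                       "C": Genotype("1", "2")}}
        none = pedigree_loglik(trio(), data, db5, MutationModel.none(db5))
        prop0 = pedigree_loglik(trio(), data, db5, build_proportional_model(db5, 0.0))
        assert none == prop0

    def test_mutation_rescues_exclusion(self, db5):
        data = {"L1": {"F": Genotype("1", "1"), "C": Genotype("2", "2")}}
        model = build_proportional_model(db5, 0.001)
        ll = pedigree_loglik(trio(), data, db5, model)
        assert ll > -math.inf
        assert ll == pytest.approx(
            pedigree_loglik_bruteforce(trio(), data, db5, model), abs=1e-10
        )

    def test_untyped_members_marginalized_not_deleted(self, db5):
        # grandparent genotype shifts the grandchild's likelihood through an
        # untyped middle generation
        ped = Pedigree(
            members=("GF", "GM", "F", "M", "C"),
            father={"F": "GF", "C": "F"},
            mother={"F": "GM", "C": "M"},
            sex={"GF": MALE, "GM": FEMALE, "F": MALE, "M": FEMALE, "C": MALE},
        )
        with_gp = pedigree_loglik(
            ped,
            {"L1": {"GF": Genotype("1", "1"), "GM": Genotype("1", "1"),
                    "C": Genotype("1", "1")}},
            db5,
        )
        alone = pedigree_loglik(ped, {"L1": {"C": Genotype("1", "1")}}, db5)
        gp_only = pedigree_loglik(
            ped,
            {"L1": {"GF": Genotype("1", "1"), "GM": Genotype("1", "1")}},
            db5,
        )
        assert with_gp > alone + gp_only  # positive dependence through descent
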