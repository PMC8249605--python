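"""Assignment likelihoods, pairwise LR matrices and conditioning."""

import math

import numpy as np
import pytest

from dvimatch import (
    STAR,
    Assignment,
    assignment_loglik,
    conditioned_lr_matrix,
    full_vs_reduced_lr_check,
    lr_vs_null,
    null_loglik,
    pairwise_lr_matrix,
    rank_assignments,
)

from conftest import random_problem


class TestAssignmentLoglik:
    def test_fig1_null(self, fig1):
        assert round(null_loglik(fig1), 2) == -21.64

    def test_fig1_full_pairing(self, fig1):
        a = Assignment(("M1", "M2", "M3"))
        assert round(assignment_loglik(fig1, a), 2) == -16.12
        assert lr_vs_null(fig1, a) == pytest.approx(250.0, rel=1e-9)

    def test_fig1_excluded_assignment(self, fig1):
        assert assignment_loglik(fig1, Assignment(("M2", "M1", "M3"))) == -math.inf
        assert lr_vs_null(fig1, Assignment(("M2", "M1", "M3"))) == 0.0

    def test_fig2_joint_optimum(self, fig2):
        a = Assignment(("M3", "M1", "M2"))
        assert round(assignment_loglik(fig2, a), 2) == -15.67
        assert lr_vs_null(fig2, a) == pytest.approx(2000.0, rel=1e-9)

    def test_empty_assignment_lr_is_one(self, fig1):
        assert lr_vs_null(fig1, Assignment.empty(3)) == pytest.approx(1.0)

    def test_invalid_assignments_rejected(self, fig1):
        with pytest.raises(ValueError, match="sex-inconsistent"):
            assignment_loglik(fig1, Assignment(("M3", STAR, STAR)))
        with pytest.raises(ValueError, match="length"):
            assignment_loglik(fig1, Assignment(("M1",)))


class TestPairwiseMatrix:
    def test_fig1_entries(self, fig1):
        B = pairwise_lr_matrix(fig1)
        assert B.loc["V2", "M2"] == pytest.approx(5.0, rel=1e-9)
        assert B.loc["V1", "M1"] == pytest.approx(1.0, rel=1e-9)
        assert B.loc["V2", "M1"] == pytest.approx(1.0, rel=1e-9)
        assert B.loc["V1", "M2"] == 0.0  # Mendelian exclusion
        # sex-inconsistent entries are exactly zero
        assert B.loc["V3", "M1"] == 0.0
        assert B.loc["V1", "M3"] == 0.0

    def test_fig2_entries(self, fig2):
        B = pairwise_lr_matrix(fig2)
        assert B.loc["V1", "M2"] == pytest.approx(20.0, rel=1e-9)
        np.testing.assert_allclose(B["M1"].to_numpy(), 1.0, rtol=1e-9)
        assert B.loc["V2", "M2"] == 0.0

    def test_full_vs_reduced_identity_on_fixtures(self, fig1, fig2):
        assert full_vs_reduced_lr_check(fig1)
        assert full_vs_reduced_lr_check(fig2)

    def test_full_vs_reduced_identity_randomized(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            problem = random_problem(rng, s_max=2, m_max=3)
            assert full_vs_reduced_lr_check(problem)


class TestConditioning:
    def test_empty_fixed_equals_pairwise(self, fig2):
        B = pairwise_lr_matrix(fig2)
        C = conditioned_lr_matrix(fig2, [])
        np.testing.assert_allclose(B.to_numpy(), C.to_numpy())

    def test_fig2_blocking(self, fig2):
        # fixing V1 = M2 types M2 as 1/1, excluding the 2/2 victim V2 from
        # the parent-child relations to M1 and M3
        C = conditioned_lr_matrix(fig2, [("V1", "M2")])
        assert list(C.index) == ["V2", "V3"]
        assert list(C.columns) == ["M1", "M3"]
        assert C.loc["V2", "M1"] == 0.0
        assert C.loc["V2", "M3"] == 0.0
        assert C.loc["V3", "M1"] == pytest.approx(10.0, rel=1e-9)
        assert C.loc["V3", "M3"] == pytest.approx(10.0, rel=1e-9)

    def test_fig1_updated_entry_exceeds_one(self, fig1):
        C = conditioned_lr_matrix(fig1, [("V2", "M2"), ("V3", "M3")])
        assert C.shape == (1, 1)
        assert C.loc["V1", "M1"] == pytest.approx(10.0, rel=1e-9)

    def test_telescoping(self, fig2):
        # L(full) = L(fixed part) + conditional contribution of the remainder
        full = assignment_loglik(fig2, Assignment(("M3", "M1", "M2")))
        fixed_part = assignment_loglik(fig2, Assignment((STAR, STAR, "M2")))
        C = conditioned_lr_matrix(fig2, [("V3", "M2")])
        # remainder: V1 = M3 then V2 = M1 conditional on both; each
        # conditional LR replaces the victim's singleton contribution
        step1 = math.log(C.loc["V1", "M3"])
        C2 = conditioned_lr_matrix(fig2, [("V3", "M2"), ("V1", "M3")])
        step2 = math.log(C2.loc["V2", "M1"])
        assert full == pytest.approx(fixed_part + step1 + step2, abs=1e-9)

    def test_inconsistent_fixed_rejected(self, fig1):
        with pytest.raises(ValueError, match="conflicts"):
            conditioned_lr_matrix(fig1, [("V1", "M1"), ("V1", "M2")])
        with pytest.raises(ValueError, match="impossible"):
            conditioned_lr_matrix(fig1, [("V1", "M2")])


class TestRanking:
    def test_fig1_table(self, fig1):
        table = rank_assignments(fig1)
        assert len(table) == 14
        top = table.iloc[0]
        assert (top["V1"], top["V2"], top["V3"]) == ("M1", "M2", "M3")
        assert round(top["loglik"], 2) == -16.12
        assert top["LR"] == pytest.approx(250.0, rel=1e-9)
        assert top["posterior"] == pytest.approx(0.7184, abs=5e-4)
        assert (table["LR"] == 0.0).sum() == 4
        assert table["posterior"].sum() == pytest.approx(1.0, abs=1e-9)
        # ranked output is non-increasing in loglik
        ll = table["loglik"].to_numpy()
        assert all(ll[i] >= ll[i + 1] - 1e-12 for i in range(len(ll) - 1))

    def test_argmax_sanity(self, fig2):
        table = rank_assignments(fig2)
        best = table["loglik"].iloc[0]
        assert all(table["loglik"] <= best + 1e-12)

    def test_bad_prior_rejected(self, fig1):
        from dvimatch import enumerate_assignments

        assignments = enumerate_assignments(fig1)
        with pytest.raises(ValueError, match="zero total weight"):
            rank_assignments(fig1, assignments, prior=[0.0] * len(assignments))
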