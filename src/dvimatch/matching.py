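"""Likelihoods and likelihood ratios of victim-to-missing-person assignments.

The likelihood of an assignment substitutes each paired victim's genotypes
into the corresponding missing person's pedigree slot; families are
independent, and every unmatched victim contributes its Hardy-Weinberg
singleton probability. All likelihood ratios are reported against the null
(empty) assignment. The pairwise LR matrix is computed on *reduced* problems
-- victim i's data against family-of-j's data only -- which equals the
full-data LR; :func:`full_vs_reduced_lr_check` verifies that identity
numerically.

Log-likelihoods are natural logs; ``-inf`` (impossible data) maps to LR 0.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genetics import Genotype, hwe_genotype_probability
from .peeling import pedigree_loglik
from .problem import STAR, Assignment, DVIProblem, Family, enumerate_assignments

__all__ = [
    "assignment_loglik",
    "lr_vs_null",
    "null_loglik",
    "pairwise_lr_matrix",
    "conditioned_lr_matrix",
    "full_vs_reduced_lr_check",
    "rank_assignments",
]


def singleton_loglik(problem: DVIProblem, victim: str) -> float:
    """Log-probability of a victim's genotypes as an unrelated individual."""
    total = 0.0
    for marker, geno in problem.victim_data(victim).items():
        total += math.log(hwe_genotype_probability(geno, marker, problem.db))
    return total


def _family_data(
    problem: DVIProblem,
    fam: Family,
    substitutions: Mapping[str, str],
) -> dict[str, dict[str, Genotype]]:
    """Reference genotypes plus victim genotypes placed in MP slots.

    ``substitutions`` maps missing-person ID -> victim ID.
    """
    data: dict[str, dict[str, Genotype]] = {
        m: dict(g) for m, g in fam.genotypes.items()
    }
    for mp, victim in substitutions.items():
        for marker, geno in problem.victim_data(victim).items():
            data.setdefault(marker, {})[mp] = geno
    return data


def _family_loglik(
    problem: DVIProblem, fam: Family, substitutions: Mapping[str, str]
) -> float:
    data = _family_data(problem, fam, substitutions)
    return pedigree_loglik(fam.pedigree, data, problem.db, problem.model)


def _check_pairs(problem: DVIProblem, pairs: Iterable[tuple[str, str]]) -> None:
    victims_seen: set[str] = set()
    mps_seen: set[str] = set()
    for v, mp in pairs:
        if v not in problem.victim_sex:
            raise ValueError(f"unknown victim {v!r}")
        problem.family_of(mp)  # raises on unknown MP
        if v in victims_seen or mp in mps_seen:
            raise ValueError(f"pairing ({v}, {mp}) conflicts with another pairing")
        victims_seen.add(v)
        mps_seen.add(mp)
        if problem.victim_sex[v] != problem.mp_sex(mp):
            raise ValueError(
                f"sex-inconsistent pairing: victim {v!r} is "
                f"{problem.victim_sex[v]}, {mp!r} is {problem.mp_sex(mp)}"
            )


def assignment_loglik(problem: DVIProblem, a: Assignment) -> float:
    """Natural-log likelihood of the PM and AM data under assignment ``a``."""
    if len(a) != len(problem.victims):
        raise ValueError(
            f"assignment length {len(a)} != number of victims {len(problem.victims)}"
        )
    pairs = a.pairs(problem.victims)
    _check_pairs(problem, pairs)
    by_family: dict[str, dict[str, str]] = {}
    for v, mp in pairs:
        fam = problem.family_of(mp)
        by_family.setdefault(fam.fid, {})[mp] = v
    total = 0.0
    for fam in problem.families:
        ll = _family_loglik(problem, fam, by_family.get(fam.fid, {}))
        if ll == -math.inf:
            return -math.inf
        total += ll
    matched = {v for v, _ in pairs}
    for v in problem.victims:
        if v not in matched:
            total += singleton_loglik(problem, v)
    return total


def null_loglik(problem: DVIProblem) -> float:
    """Log-likelihood of the empty assignment (all victims unrelated)."""
    return assignment_loglik(problem, Assignment.empty(len(problem.victims)))


def lr_vs_null(problem: DVIProblem, a: Assignment) -> float:
    """Likelihood ratio of ``a`` against the empty assignment; 0 if excluded."""
    ll = assignment_loglik(problem, a)
    if ll == -math.inf:
        return 0.0
    return math.exp(ll - null_loglik(problem))


def pairwise_lr_matrix(problem: DVIProblem) -> pd.DataFrame:
    """Victims x missing-persons matrix of single-pairing LRs.

    Entry (i, j) is computed on the reduced problem (victim i's data and
    family-of-j's data only); 0 encodes sex inconsistency or exclusion.
    """
    return conditioned_lr_matrix(problem, fixed=())


def conditioned_lr_matrix(
    problem: DVIProblem,
    fixed: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Pairwise LR matrix conditional on confirmed pairings.

    Victims in ``fixed`` are merged into their missing persons' pedigree
    slots as typed members; rows and columns of fixed pairings are removed
    and remaining entries are recomputed against the updated families.
    """
    fixed = tuple(fixed)
    _check_pairs(problem, fixed)
    fixed_victims = {v for v, _ in fixed}
    fixed_mps = {mp for _, mp in fixed}
    base_subs: dict[str, dict[str, str]] = {}
    for v, mp in fixed:
        fam = problem.family_of(mp)
        base_subs.setdefault(fam.fid, {})[mp] = v

    base_ll: dict[str, float] = {}
    for fam in problem.families:
        ll = _family_loglik(problem, fam, base_subs.get(fam.fid, {}))
        if ll == -math.inf:
            raise ValueError(
                f"fixed pairings are impossible within family {fam.fid!r}"
            )
        base_ll[fam.fid] = ll

    victims = [v for v in problem.victims if v not in fixed_victims]
    mps = [mp for mp in problem.missing_persons if mp not in fixed_mps]
    mat = np.zeros((len(victims), len(mps)))
    singles = {v: singleton_loglik(problem, v) for v in victims}
    for j, mp in enumerate(mps):
        fam = problem.family_of(mp)
        subs = dict(base_subs.get(fam.fid, {}))
        for i, v in enumerate(victims):
            if problem.victim_sex[v] != problem.mp_sex(mp):
                continue
            subs[mp] = v
            num = _family_loglik(problem, fam, subs)
            del subs[mp]
            if num == -math.inf:
                continue
            mat[i, j] = math.exp(num - base_ll[fam.fid] - singles[v])
    return pd.DataFrame(mat, index=victims, columns=mps)


def full_vs_reduced_lr_check(
    problem: DVIProblem, rtol: float = 1e-9
) -> bool:
    """Verify the full-data vs reduced-problem LR identity for every pair."""
    reduced = pairwise_lr_matrix(problem)
    s = len(problem.victims)
    for i, v in enumerate(problem.victims):
        for mp in problem.missing_persons:
            if problem.victim_sex[v] != problem.mp_sex(mp):
                continue
            pairing = [STAR] * s
            pairing[i] = mp
            full = lr_vs_null(problem, Assignment(tuple(pairing)))
            red = float(reduced.loc[v, mp])
            if not math.isclose(full, red, rel_tol=rtol, abs_tol=1e-300):
                return False
    return True


def rank_assignments(
    problem: DVIProblem,
    assignments: Sequence[Assignment] | None = None,
    prior: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Rank assignments by likelihood; the joint (brute-force) approach.

    Returns a DataFrame with one column per victim, then ``loglik`` (natural
    log), ``LR`` (against the empty assignment) and ``posterior`` (prior-
    weighted; flat over the supplied assignments by default). Rows are sorted
    by descending log-likelihood, ties keeping enumeration order.
    """
    if assignments is None:
        assignments = enumerate_assignments(problem)
    logliks = np.array([assignment_loglik(problem, a) for a in assignments])
    ll0 = null_loglik(problem)
    lrs = np.exp(logliks - ll0)  # -inf maps to 0
    if prior is None:
        logprior = np.zeros(len(assignments))
    else:
        prior = np.asarray(prior, dtype=float)
        if len(prior) != len(assignments) or np.any(prior < 0):
            raise ValueError("prior must be non-negative, one weight per assignment")
        if prior.sum() == 0:
            raise ValueError("prior has zero total weight")
        with np.errstate(divide="ignore"):
            logprior = np.log(prior)
    weighted = logliks + logprior
    denom = logsumexp(weighted)
    posterior = np.exp(weighted - denom)
    df = pd.DataFrame(
        [list(a.pairing) for a in assignments], columns=list(problem.victims)
    )
    df["loglik"] = logliks
    df["LR"] = lrs
    df["posterior"] = posterior
    order = np.argsort(-logliks, kind="stable")
    return df.iloc[order].reset_index(drop=True)
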