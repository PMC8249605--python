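"""Posterior pairing and non-pairing probabilities.

Given the likelihoods of a complete enumeration of assignments and a prior
over them, Bayes' theorem yields, for every victim V_i and missing person M_j,

    q_{i,j} = sum_{a: a(i)=M_j} L(a) pi(a) / sum_a L(a) pi(a)

and the non-pairing probability q_{i,*} analogously over assignments leaving
V_i unmatched. Each victim's row (all MPs plus '*') sums to 1, and for any
column j and two victims, q_{i,j} + q_{i',j} <= 1 -- so with a decision
threshold alpha > 0.5, concluded pairings can never conflict.

All sums are computed with log-sum-exp; a flat prior is the default.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .matching import assignment_loglik
from .problem import STAR, Assignment, DVIProblem, enumerate_assignments

__all__ = ["posterior_table", "classify_pairings"]


def posterior_table(
    problem: DVIProblem,
    assignments: Sequence[Assignment] | None = None,
    logliks: Sequence[float] | None = None,
    prior: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Posterior pairing probabilities as a victims x (MPs + '*') table.

    ``assignments`` must enumerate the full space the posterior is taken
    over (by default the complete sex-consistent enumeration). Pre-computed
    ``logliks`` may be passed to avoid recomputation; ``prior`` is a
    non-negative weight per assignment (flat if omitted; renormalized
    internally).
    """
    if assignments is None:
        assignments = enumerate_assignments(problem)
    if logliks is None:
        logliks = [assignment_loglik(problem, a) for a in assignments]
    logliks = np.asarray(logliks, dtype=float)
    if len(logliks) != len(assignments):
        raise ValueError("one log-likelihood per assignment required")
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
    if denom == -math.inf:
        raise ValueError("all assignments have zero posterior mass")

    mps = list(problem.missing_persons)
    cols = mps + [STAR]
    table = np.zeros((len(problem.victims), len(cols)))
    col_index = {c: j for j, c in enumerate(cols)}
    for i, v in enumerate(problem.victims):
        for j, c in enumerate(cols):
            mask = np.array([a[i] == c for a in assignments])
            if mask.any():
                table[i, j] = math.exp(logsumexp(weighted[mask]) - denom)
    return pd.DataFrame(table, index=list(problem.victims), columns=cols)


def classify_pairings(
    table: pd.DataFrame, alpha: float
) -> set[tuple[str, str]]:
    """All pairings with posterior probability exceeding ``alpha``.

    ``alpha`` must be at least 0.5: since the comparison is strict and the
    column bound gives q_{i,j} + q_{i',j} <= 1, two victims can never both
    exceed 0.5 for the same missing person, so the conclusions are
    conflict-free.
    """
    if not (0.5 <= alpha <= 1.0):
        raise ValueError(
            f"alpha must be in [0.5, 1] to guarantee consistency; got {alpha}"
        )
    out = set()
    for v in table.index:
        for mp in table.columns:
            if mp == STAR:
                continue
            if table.loc[v, mp] > alpha:
                out.add((v, mp))
    return out
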