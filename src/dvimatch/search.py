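"""Search strategies for DVI problems.

Three strategies are provided, all driven by an LR threshold ``T > 1``:

* :func:`algorithm1` -- sequential without updates: repeatedly accept the
  largest entry of the *static* pairwise LR matrix, deleting its row and
  column, until all remaining entries fall below ``T``.
* :func:`algorithm2` -- sequential with updates: as algorithm 1, but the
  matrix is recomputed conditional on all previously accepted pairings.
* :func:`algorithm3` -- combined: Step 1 iteratively fixes *undisputed*
  pairings (entry >= T with every other entry in its row and column <= 1, or
  <= entry/T in the relaxed variant) and reconditions the matrix to a
  fixpoint; Step 2 enumerates the remaining sex-consistent assignments,
  drops those containing a zero of the updated matrix, and ranks the merged
  assignments by joint likelihood.

Tied maxima (log-likelihoods within 1e-9) branch into separate search paths;
all distinct terminal assignments are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .matching import (
    conditioned_lr_matrix,
    lr_vs_null,
    pairwise_lr_matrix,
    rank_assignments,
)
from .problem import (
    STAR,
    Assignment,
    DVIProblem,
    count_assignments,
    enumerate_assignments,
)

__all__ = [
    "SearchResult",
    "JointResult",
    "algorithm1",
    "algorithm2",
    "find_undisputed",
    "algorithm3",
]

_LOG_TIE_TOL = 1e-9


def _reaches(value: float, T: float) -> bool:
    """value >= T up to the same relative tolerance used for ties."""
    return value >= T * (1.0 - _LOG_TIE_TOL)


@dataclass(frozen=True)
class SearchResult:
    """Output of a sequential search: tied terminal assignments plus a trail."""

    solutions: tuple[Assignment, ...]
    trail: tuple[dict, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class JointResult:
    """Output of the combined search.

    ``table`` is the ranked assignment table (full merged assignments, LRs
    against the global null); ``undisputed`` the pairings fixed in Step 1;
    ``matrix`` the final conditioned pairwise LR matrix.
    """

    table: pd.DataFrame
    undisputed: tuple[tuple[str, str], ...]
    matrix: pd.DataFrame
    trail: tuple[dict, ...] = field(default_factory=tuple)

    @property
    def solutions(self) -> tuple[Assignment, ...]:
        """Top-ranked assignment(s), including ties within tolerance."""
        if len(self.table) == 0:
            return ()
        logliks = self.table["loglik"].to_numpy()
        top = logliks[0]
        vcols = [c for c in self.table.columns if c not in ("loglik", "LR", "posterior")]
        tied = self.table[np.isclose(logliks, top, rtol=0.0, atol=_LOG_TIE_TOL)]
        return tuple(Assignment(tuple(row)) for row in tied[vcols].itertuples(index=False))


def _max_candidates(matrix: pd.DataFrame) -> tuple[float, list[tuple[str, str]]]:
    """Largest positive entry and all positions tying it (log tolerance)."""
    values = matrix.to_numpy()
    if values.size == 0:
        return 0.0, []
    peak = float(values.max())
    if peak <= 0.0:
        return 0.0, []
    log_peak = math.log(peak)
    ties = []
    for i, v in enumerate(matrix.index):
        for j, mp in enumerate(matrix.columns):
            x = values[i, j]
            if x > 0 and abs(math.log(x) - log_peak) <= _LOG_TIE_TOL:
                ties.append((v, mp))
    return peak, ties


def _assignment_from_pairs(
    problem: DVIProblem, pairs: dict[str, str]
) -> Assignment:
    return Assignment(tuple(pairs.get(v, STAR) for v in problem.victims))


def _sequential(
    problem: DVIProblem,
    T: float,
    matrix_fn: Callable[[tuple[tuple[str, str], ...]], pd.DataFrame],
) -> SearchResult:
    if T <= 1:
        raise ValueError(f"threshold T must be > 1; got {T}")
    terminals: dict[tuple[str, ...], Assignment] = {}
    trail: list[dict] = []

    def step(accepted: tuple[tuple[str, str], ...], matrix: pd.DataFrame) -> None:
        peak, ties = _max_candidates(matrix)
        if not ties or not _reaches(peak, T):
            a = _assignment_from_pairs(problem, dict(accepted))
            terminals.setdefault(a.pairing, a)
            return
        for v, mp in ties:
            trail.append({"accepted": (v, mp), "LR": float(matrix.loc[v, mp]),
                          "depth": len(accepted)})
            nxt = accepted + ((v, mp),)
            step(nxt, matrix_fn(nxt))

    step((), matrix_fn(()))
    return SearchResult(solutions=tuple(terminals.values()), trail=tuple(trail))


def algorithm1(problem: DVIProblem, T: float) -> SearchResult:
    """Sequential search without updates (static pairwise matrix)."""
    base = pairwise_lr_matrix(problem)

    def matrix_fn(accepted: tuple[tuple[str, str], ...]) -> pd.DataFrame:
        rows = [v for v, _ in accepted]
        cols = [mp for _, mp in accepted]
        return base.drop(index=rows, columns=cols)

    return _sequential(problem, T, matrix_fn)


def algorithm2(problem: DVIProblem, T: float) -> SearchResult:
    """Sequential search with updates (matrix reconditioned on each pairing)."""

    def matrix_fn(accepted: tuple[tuple[str, str], ...]) -> pd.DataFrame:
        return conditioned_lr_matrix(problem, accepted)

    return _sequential(problem, T, matrix_fn)


def find_undisputed(
    matrix: pd.DataFrame, T: float, relaxed: bool = False
) -> set[tuple[str, str]]:
    """Undisputed pairings of a pairwise LR matrix.

    Strict rule: entry >= T while every other entry in its row and column is
    <= 1. Relaxed rule: the limit 1 is replaced by entry / T.
    """
    if T <= 1:
        raise ValueError(f"threshold T must be > 1; got {T}")
    out: set[tuple[str, str]] = set()
    values = matrix.to_numpy()
    for i, v in enumerate(matrix.index):
        for j, mp in enumerate(matrix.columns):
            entry = values[i, j]
            if not _reaches(entry, T):
                continue
            limit = entry / T if relaxed else 1.0
            others = np.concatenate([np.delete(values[i, :], j),
                                     np.delete(values[:, j], i)])
            if np.all(others <= limit * (1.0 + 1e-12)):
                out.add((v, mp))
    return out


def algorithm3(
    problem: DVIProblem,
    T: float,
    relaxed: bool = False,
    *,
    cap: int = 10**6,
    posterior_space: str = "reduced",
) -> JointResult:
    """Combined undisputed + joint search, ranked by likelihood.

    Step 1 iterates undisputed screening and conditioning to a fixpoint;
    Step 2 enumerates the remaining sex-consistent assignments, excluding
    pairs that are zero in the updated matrix, and ranks the merged
    assignments. Posteriors are flat-prior; with the default
    ``posterior_space="reduced"`` they are conditional on the undisputed
    pairings (which carry probability 1), while ``"full"`` renormalizes over
    the complete a-priori assignment space.

    Raises
    ------
    ValueError
        If the Step 2 a-priori enumeration would exceed ``cap`` assignments
        (guidance: lower T so that more pairings become undisputed).
    """
    if T <= 1:
        raise ValueError(f"threshold T must be > 1; got {T}")
    if posterior_space not in ("reduced", "full"):
        raise ValueError("posterior_space must be 'reduced' or 'full'")
    fixed: tuple[tuple[str, str], ...] = ()
    trail: list[dict] = []
    while True:
        matrix = conditioned_lr_matrix(problem, fixed)
        found = find_undisputed(matrix, T, relaxed)
        if not found:
            break
        for pair in sorted(found):
            trail.append({"undisputed": pair, "LR": float(matrix.loc[pair])})
        fixed = fixed + tuple(sorted(found))

    rem_victims = list(matrix.index)
    rem_mps = list(matrix.columns)
    from .pedigree import FEMALE

    s_f = sum(1 for v in rem_victims if problem.victim_sex[v] == FEMALE)
    m_f = sum(1 for mp in rem_mps if problem.mp_sex(mp) == FEMALE)
    n_apriori = count_assignments(
        s_f, len(rem_victims) - s_f, m_f, len(rem_mps) - m_f
    )
    if n_apriori > cap:
        raise ValueError(
            f"joint step would enumerate {n_apriori} assignments (cap {cap}); "
            "lower the threshold T to fix more undisputed pairings"
        )
    forbidden = {
        (v, mp)
        for v in rem_victims
        for mp in rem_mps
        if matrix.loc[v, mp] == 0.0
    }
    # fixed victims/MPs take no part in the enumeration; they are merged back in
    fixed_victims = {v for v, _ in fixed}
    fixed_mps = {mp for _, mp in fixed}
    for v in problem.victims:
        for mp in problem.missing_persons:
            if v in fixed_victims or mp in fixed_mps:
                forbidden.add((v, mp))
    remainder = enumerate_assignments(problem, forbidden=forbidden)
    fixed_map = dict(fixed)
    merged = [
        Assignment(
            tuple(
                fixed_map.get(v, entry)
                for v, entry in zip(problem.victims, a.pairing)
            )
        )
        for a in remainder
    ]
    table = rank_assignments(problem, merged)
    if posterior_space == "full":
        full = rank_assignments(problem)
        total = float(full["LR"].sum())
        table = table.assign(posterior=table["LR"] / total)
    return JointResult(
        table=table, undisputed=fixed, matrix=matrix, trail=tuple(trail)
    )
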