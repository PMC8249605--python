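"""Exact pedigree likelihoods by peeling, with a brute-force oracle.

The peeling engine is an allele-level formulation of Elston-Stewart: each
individual contributes two variables (paternal and maternal allele), founders
carry independent Hardy-Weinberg priors on both, each transmission is a factor
through the mutation-model transition matrix, and typed individuals contribute
an unordered-genotype indicator on their own allele pair. Summing the factor
product over all variables -- performed by greedy variable elimination, which
on a loop-free pedigree is exactly the nuclear-family peeling sequence --
yields the marker likelihood. All work is done with running rescaling so that
deep pedigrees and many markers cannot underflow; results are returned as
natural-log likelihoods with ``-inf`` marking Mendelian impossibility.

Looped pedigrees are rejected; all supported analyses use loop-free ones.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache
from typing import Hashable, Mapping

import numpy as np

from .genetics import FrequencyDatabase, Genotype, MutationModel
from .pedigree import Pedigree

__all__ = ["pedigree_loglik", "pedigree_loglik_bruteforce"]

# A genotype map is Mapping[marker, Mapping[individual, Genotype]].
GenotypeMap = Mapping[str, Mapping[str, Genotype]]

_Var = tuple[str, int]  # (individual, 0=paternal | 1=maternal)
_Factor = tuple[tuple[_Var, ...], np.ndarray]

_BRUTE_FORCE_MAX_COMBOS = 2_000_000


def _structure_key(ped: Pedigree) -> tuple:
    return (
        ped.members,
        tuple(sorted(ped.father.items())),
        tuple(sorted(ped.mother.items())),
    )


@lru_cache(maxsize=512)
def _elimination_order(key: tuple) -> tuple[_Var, ...]:
    """Greedy min-fill elimination order for the allele-variable graph.

    The interaction graph is built from the factor scopes that are constant
    across markers and observation patterns: transmission trios and the
    within-individual (paternal, maternal) coupling. An order computed on this
    graph is valid for any subset of observed individuals.
    """
    members, father_items, mother_items = key
    father = dict(father_items)
    mother = dict(mother_items)
    scopes: list[tuple[_Var, ...]] = []
    for ind in members:
        scopes.append(((ind, 0), (ind, 1)))
        if ind in father:
            f, m = father[ind], mother[ind]
            scopes.append(((f, 0), (f, 1), (ind, 0)))
            scopes.append(((m, 0), (m, 1), (ind, 1)))
    neighbours: dict[_Var, set[_Var]] = {
        (ind, k): set() for ind in members for k in (0, 1)
    }
    for scope in scopes:
        for a in scope:
            for b in scope:
                if a != b:
                    neighbours[a].add(b)
    order: list[_Var] = []
    remaining = set(neighbours)
    while remaining:
        # min-fill: eliminate the variable adding fewest new edges
        best, best_fill, best_deg = None, None, None
        for v in sorted(remaining):
            nbrs = neighbours[v] & remaining
            fill = sum(
                1
                for a, b in itertools.combinations(sorted(nbrs), 2)
                if b not in neighbours[a]
            )
            deg = len(nbrs)
            if best is None or (fill, deg) < (best_fill, best_deg):
                best, best_fill, best_deg = v, fill, deg
        nbrs = neighbours[best] & remaining
        for a in nbrs:
            neighbours[a] |= nbrs - {a}
        order.append(best)
        remaining.discard(best)
    return tuple(order)


def _expand(factor: _Factor, all_vars: list[_Var]) -> np.ndarray:
    """Broadcast a factor's array into the axis order given by ``all_vars``."""
    fvars, arr = factor
    perm = sorted(range(len(fvars)), key=lambda i: all_vars.index(fvars[i]))
    arr = np.transpose(arr, perm)
    ordered = [fvars[i] for i in perm]
    shape, it = [], 0
    for v in all_vars:
        if it < len(ordered) and ordered[it] == v:
            shape.append(arr.shape[it])
            it += 1
        else:
            shape.append(1)
    return arr.reshape(shape)


def _marker_loglik(
    ped: Pedigree,
    observed: Mapping[str, Genotype],
    db: FrequencyDatabase,
    marker: str,
    model: MutationModel,
) -> float:
    alleles = db.alleles(marker)
    n = len(alleles)
    p = db.freqs(marker)
    trans = model.transition(marker)
    # transmission kernel from a parent's ordered genotype: average of rows
    factors: list[_Factor] = []
    for ind in ped.members:
        par = ped.parents(ind)
        if par is None:
            factors.append((((ind, 0),), p.copy()))
            factors.append((((ind, 1),), p.copy()))
        else:
            f, m = par
            # P(child paternal allele | father's two alleles)
            trio = 0.5 * (trans[:, None, :] + trans[None, :, :])
            factors.append((((f, 0), (f, 1), (ind, 0)), trio))
            factors.append((((m, 0), (m, 1), (ind, 1)), trio))
    for ind, geno in observed.items():
        if ind not in ped.sex:
            raise ValueError(f"typed individual {ind!r} is not a pedigree member")
        ia = db.index(marker, geno.allele_a)
        ib = db.index(marker, geno.allele_b)
        obs = np.zeros((n, n))
        obs[ia, ib] = 1.0
        obs[ib, ia] = 1.0
        factors.append((((ind, 0), (ind, 1)), obs))

    logscale = 0.0
    for var in _elimination_order(_structure_key(ped)):
        bucket = [f for f in factors if var in f[0]]
        factors = [f for f in factors if var not in f[0]]
        all_vars = []
        for fvars, _ in bucket:
            for v in fvars:
                if v not in all_vars:
                    all_vars.append(v)
        prod = _expand(bucket[0], all_vars)
        for f in bucket[1:]:
            prod = prod * _expand(f, all_vars)
        summed = prod.sum(axis=all_vars.index(var))
        peak = float(summed.max()) if summed.size else 0.0
        if peak <= 0.0:
            return -math.inf
        summed = summed / peak
        logscale += math.log(peak)
        new_vars = tuple(v for v in all_vars if v != var)
        factors.append((new_vars, summed))
    # remaining factors are scalars
    total = 1.0
    for _, arr in factors:
        total *= float(arr)
    if total <= 0.0:
        return -math.inf
    return logscale + math.log(total)


def _check_inputs(ped: Pedigree, data: GenotypeMap, db: FrequencyDatabase) -> None:
    if ped.has_loop():
        raise ValueError("looped pedigrees are unsupported (loops unsupported)")
    members = set(ped.members)
    for marker, genos in data.items():
        db._check_marker(marker)
        for ind, geno in genos.items():
            if ind not in members:
                raise ValueError(
                    f"typed individual {ind!r} at marker {marker!r} "
                    "is not a pedigree member"
                )
            for allele in geno.alleles:
                db.index(marker, allele)  # raises on unknown allele


def pedigree_loglik(
    ped: Pedigree,
    data: GenotypeMap,
    db: FrequencyDatabase,
    model: MutationModel | None = None,
) -> float:
    """Natural-log likelihood of genotype data on a loop-free pedigree.

    Founder genotypes follow Hardy-Weinberg equilibrium; each parent-child
    transmission passes through the mutation model (Mendelian if ``model`` is
    None). Markers are independent: the result is the sum of per-marker log
    likelihoods, ``-inf`` if the data are impossible under the pedigree, and
    0 for empty data.
    """
    if model is None:
        model = MutationModel.none(db)
    _check_inputs(ped, data, db)
    total = 0.0
    for marker, genos in data.items():
        if not genos:
            continue
        ll = _marker_loglik(ped, genos, db, marker, model)
        if ll == -math.inf:
            return -math.inf
        total += ll
    return total


def _unordered_genotypes(n: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(n) for j in range(i, n)]


def _config_probability(
    ped: Pedigree,
    geno_idx: Mapping[str, tuple[int, int]],
    p: np.ndarray,
    trans: np.ndarray,
) -> float:
    prob = 1.0
    for ind in ped.members:
        a, b = geno_idx[ind]
        par = ped.parents(ind)
        if par is None:
            prob *= p[a] * p[b] if a == b else 2.0 * p[a] * p[b]
        else:
            f, m = par
            fa, fb = geno_idx[f]
            ma, mb = geno_idx[m]
            tf = 0.5 * (trans[fa] + trans[fb])
            tm = 0.5 * (trans[ma] + trans[mb])
            if a == b:
                prob *= tf[a] * tm[a]
            else:
                prob *= tf[a] * tm[b] + tf[b] * tm[a]
        if prob == 0.0:
            return 0.0
    return prob


def pedigree_loglik_bruteforce(
    ped: Pedigree,
    data: GenotypeMap,
    db: FrequencyDatabase,
    model: MutationModel | None = None,
) -> float:
    """Oracle for :func:`pedigree_loglik` by explicit summation.

    Enumerates every combination of unordered genotypes for untyped members
    and sums the joint probabilities. Intended for small instances only;
    raises if the enumeration would exceed an internal guard (about 2e6
    combinations per marker).
    """
    if model is None:
        model = MutationModel.none(db)
    _check_inputs(ped, data, db)
    total = 0.0
    for marker, genos in data.items():
        if not genos:
            continue
        n = len(db.alleles(marker))
        p = db.freqs(marker)
        trans = model.transition(marker)
        untyped = [m for m in ped.members if m not in genos]
        combos = (n * (n + 1) // 2) ** len(untyped)
        if len(untyped) > 10 or combos > _BRUTE_FORCE_MAX_COMBOS:
            raise ValueError(
                f"instance too large for brute force at marker {marker!r}: "
                f"{len(untyped)} untyped members, {combos} combinations"
            )
        typed_idx = {
            ind: (db.index(marker, g.allele_a), db.index(marker, g.allele_b))
            for ind, g in genos.items()
        }
        gts = _unordered_genotypes(n)
        marker_prob = 0.0
        for combo in itertools.product(gts, repeat=len(untyped)):
            cfg = dict(typed_idx)
            cfg.update(zip(untyped, combo))
            marker_prob += _config_probability(ped, cfg, p, trans)
        if marker_prob <= 0.0:
            return -math.inf
        total += math.log(marker_prob)
    return total
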