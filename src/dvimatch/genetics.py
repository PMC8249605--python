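"""Marker-level primitives: allele frequencies, genotypes and mutation models.

All downstream likelihood machinery is built on three objects defined here:

* :class:`FrequencyDatabase` -- ordered per-marker allele labels with their
  population frequencies (the Hardy-Weinberg founder prior).
* :class:`Genotype` -- an unordered pair of allele labels.
* :class:`MutationModel` -- per-marker allele transmission matrices. Two kinds
  are supported: ``none`` (Mendelian transmission, identity matrix) and
  ``proportional`` (off-diagonal transition probabilities proportional to the
  target-allele frequency, calibrated so the expected per-transmission
  mutation rate equals the requested rate; this model is stationary, i.e. it
  leaves the allele-frequency vector unchanged).

Allele labels are opaque strings throughout; STR repeat labels like ``"9.3"``
are legal and never interpreted numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "FrequencyDatabase",
    "Genotype",
    "MutationModel",
    "hwe_genotype_probability",
    "build_proportional_model",
    "transmission_probability",
]

_FREQ_SUM_TOL = 1e-6
_RENORM_MAX_DEV = 1e-3


class FrequencyDatabase:
    """Ordered collection of markers, each with allele labels and frequencies.

    Parameters
    ----------
    data
        Mapping ``marker -> {allele: frequency}``. Marker and allele order is
        preserved (insertion order).
    renormalize
        If True, frequency vectors whose sum deviates from 1 by at most 1e-3
        are rescaled to sum exactly to 1. Larger deviations always raise.
    """

    def __init__(
        self,
        data: Mapping[str, Mapping[str, float]],
        *,
        renormalize: bool = False,
    ) -> None:
        self._alleles: dict[str, tuple[str, ...]] = {}
        self._freqs: dict[str, np.ndarray] = {}
        self._index: dict[str, dict[str, int]] = {}
        for marker, table in data.items():
            alleles = tuple(str(a) for a in table)
            if len(set(alleles)) != len(alleles):
                raise ValueError(f"duplicate allele labels for marker {marker!r}")
            freqs = np.asarray([float(table[a]) for a in table], dtype=float)
            if len(freqs) == 0:
                raise ValueError(f"marker {marker!r} has no alleles")
            if np.any(freqs <= 0):
                raise ValueError(
                    f"marker {marker!r}: all allele frequencies must be > 0"
                )
            dev = abs(freqs.sum() - 1.0)
            if dev > _FREQ_SUM_TOL:
                if renormalize and dev <= _RENORM_MAX_DEV:
                    freqs = freqs / freqs.sum()
                else:
                    raise ValueError(
                        f"marker {marker!r}: frequencies sum to {freqs.sum():.8f}, "
                        "not 1"
                    )
            self._alleles[marker] = alleles
            self._freqs[marker] = freqs
            self._index[marker] = {a: i for i, a in enumerate(alleles)}

    # -- accessors ---------------------------------------------------------

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self._alleles)

    def __contains__(self, marker: str) -> bool:
        return marker in self._alleles

    def alleles(self, marker: str) -> tuple[str, ...]:
        self._check_marker(marker)
        return self._alleles[marker]

    def freqs(self, marker: str) -> np.ndarray:
        """Frequency vector for ``marker``, aligned with :meth:`alleles`."""
        self._check_marker(marker)
        return self._freqs[marker]

    def freq(self, marker: str, allele: str) -> float:
        return float(self._freqs[marker][self.index(marker, allele)])

    def index(self, marker: str, allele: str) -> int:
        self._check_marker(marker)
        try:
            return self._index[marker][allele]
        except KeyError:
            raise KeyError(
                f"unknown allele {allele!r} for marker {marker!r}"
            ) from None

    def _check_marker(self, marker: str) -> None:
        if marker not in self._alleles:
            raise KeyError(f"unknown marker {marker!r}")

    def subset(self, markers: Iterable[str]) -> "FrequencyDatabase":
        """Database restricted to the given markers, in the given order."""
        return FrequencyDatabase(
            {
                m: dict(zip(self._alleles[m], self._freqs[m]))
                for m in markers
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyDatabase):
            return NotImplemented
        return self._alleles == other._alleles and all(
            np.array_equal(self._freqs[m], other._freqs[m]) for m in self._alleles
        )

    def __repr__(self) -> str:
        return f"FrequencyDatabase({len(self._alleles)} markers)"

    # -- constructors ------------------------------------------------------

    @classmethod
    def equifrequent(
        cls, markers: Iterable[str], n_alleles: int
    ) -> "FrequencyDatabase":
        """Markers sharing ``n_alleles`` alleles labelled 1..n, equal frequencies."""
        p = 1.0 / n_alleles
        return cls(
            {m: {str(a + 1): p for a in range(n_alleles)} for m in markers}
        )


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of allele labels; ``Genotype('1','2') == Genotype('2','1')``."""

    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        a, b = sorted((str(self.allele_a), str(self.allele_b)))
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    @property
    def homozygous(self) -> bool:
        return self.allele_a == self.allele_b

    @classmethod
    def parse(cls, text: str, sep: str = "/") -> "Genotype | None":
        """Parse ``"a/b"``; the missing-genotype token ``"-"`` yields None."""
        text = text.strip()
        if text in ("-", "", "-/-"):
            return None
        parts = text.split(sep)
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ValueError(f"malformed genotype {text!r}; expected 'a/b' or '-'")
        return cls(parts[0], parts[1])

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"


@dataclass(frozen=True, eq=False)
class MutationModel:
    """Per-marker allele transmission matrices.

    ``transition(marker)[i, j]`` is the probability that a parental allele with
    index ``i`` (in database order) is transmitted as allele ``j``.
    """

    kind: str
    rate: float
    db: FrequencyDatabase = field(repr=False)
    _matrices: dict[str, np.ndarray] = field(repr=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MutationModel):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.rate == other.rate
            and self.db == other.db
            and self._matrices.keys() == other._matrices.keys()
            and all(
                np.allclose(self._matrices[m], other._matrices[m])
                for m in self._matrices
            )
        )

    def transition(self, marker: str) -> np.ndarray:
        self.db._check_marker(marker)
        return self._matrices[marker]

    @classmethod
    def none(cls, db: FrequencyDatabase) -> "MutationModel":
        mats = {m: np.eye(len(db.alleles(m))) for m in db.markers}
        return cls(kind="none", rate=0.0, db=db, _matrices=mats)

    @classmethod
    def proportional(cls, db: FrequencyDatabase, rate: float) -> "MutationModel":
        return build_proportional_model(db, rate)


def build_proportional_model(db: FrequencyDatabase, rate: float) -> MutationModel:
    """Stationary proportional mutation model.

    For each marker with frequency vector ``p``, off-diagonal entries are
    ``m[a][b] = gamma * p_b`` and diagonal entries ``m[a][a] = 1 - gamma * (1 - p_a)``
    with ``gamma = rate / sum_a p_a * (1 - p_a)``, so that the expected mutation
    probability per transmission (frequency-weighted) equals ``rate`` and ``p``
    is a stationary distribution of the matrix.

    Raises
    ------
    ValueError
        If ``rate`` is outside ``[0, 1)`` or too large for a marker's frequency
        spectrum (a diagonal entry would go negative).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"mutation rate must be in [0, 1); got {rate}")
    if rate == 0.0:
        model = MutationModel.none(db)
        return MutationModel(
            kind="proportional", rate=0.0, db=db, _matrices=model._matrices
        )
    mats: dict[str, np.ndarray] = {}
    for marker in db.markers:
        p = db.freqs(marker)
        denom = float(np.sum(p * (1.0 - p)))
        if denom == 0.0:  # single-allele marker: no mutation possible
            raise ValueError(
                f"marker {marker!r}: proportional model undefined "
                "(degenerate frequency spectrum)"
            )
        gamma = rate / denom
        diag = 1.0 - gamma * (1.0 - p)
        if np.any(diag < 0):
            raise ValueError(
                f"marker {marker!r}: mutation rate {rate} too large for its "
                "frequency spectrum"
            )
        mat = gamma * np.tile(p, (len(p), 1))
        np.fill_diagonal(mat, diag)
        mats[marker] = mat
    return MutationModel(kind="proportional", rate=rate, db=db, _matrices=mats)


def hwe_genotype_probability(
    g: Genotype, marker: str, db: FrequencyDatabase
) -> float:
    """Hardy-Weinberg probability of an unordered genotype.

    ``p_a**2`` for homozygotes, ``2 * p_a * p_b`` for heterozygotes.
    """
    pa = db.freq(marker, g.allele_a)
    pb = db.freq(marker, g.allele_b)
    return pa * pa if g.homozygous else 2.0 * pa * pb


def transmission_probability(
    parent_allele: str, child_allele: str, marker: str, model: MutationModel
) -> float:
    """P(transmitted allele | parental allele) under the mutation model."""
    i = model.db.index(marker, parent_allele)
    j = model.db.index(marker, child_allele)
    return float(model.transition(marker)[i, j])
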