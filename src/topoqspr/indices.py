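"""Degree-based topological indices.

Each index is a sum over edges of a term depending only on the endpoint
degrees (d_u, d_v), so it is evaluated from the edge partition: for each
partition entry ((a, b), count) the per-edge term is weighted by count.

Implemented indices (per-edge term for an edge with endpoint degrees a, b):

====  =======================================  =============================
name  term                                     common name
====  =======================================  =============================
M1    a + b                                    first Zagreb index
M2    a * b                                    second Zagreb index
H     2 / (a + b)                              harmonic index
F     a**2 + b**2                              forgotten index
SS    sqrt(a*b / (a + b))                      (see note below)
ABC   sqrt((a + b - 2) / (a*b))                atom-bond connectivity index
RI    sqrt(1 / (a*b))                          Randic index
SC    sqrt(1 / (a + b))                        sum-connectivity index
GA    2*sqrt(a*b) / (a + b)                    geometric-arithmetic index
HZ    (a + b)**2                               hyper-Zagreb index
====  =======================================  =============================

.. note::
   The descriptor named ``SS`` here is sometimes labelled "symmetric
   division degree" in the QSPR literature, but the formula used throughout
   this package is sqrt(d_u*d_v/(d_u+d_v)) per edge; the conventional SDD,
   sum of (d_u^2+d_v^2)/(d_u*d_v), is a different quantity.  We keep the
   arithmetic that our reference descriptor tables were computed with.

The identity HZ = F + 2*M2 holds exactly for every graph, since
(a+b)^2 = a^2 + b^2 + 2ab edge by edge; it is used elsewhere as a data
integrity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from .graph import EdgePartition, MolecularGraph, edge_partition

__all__ = ["INDEX_NAMES", "DescriptorVector", "compute_index", "compute_all",
           "register_index", "index_from_graph"]

# registry: name -> per-edge term as a function of the two endpoint degrees
_TERMS: dict[str, Callable[[int, int], float]] = {
    "M1": lambda a, b: a + b,
    "M2": lambda a, b: a * b,
    "H": lambda a, b: 2.0 / (a + b),
    "F": lambda a, b: a * a + b * b,
    "SS": lambda a, b: math.sqrt(a * b / (a + b)),
    "ABC": lambda a, b: math.sqrt((a + b - 2) / (a * b)),
    "RI": lambda a, b: math.sqrt(1.0 / (a * b)),
    "SC": lambda a, b: math.sqrt(1.0 / (a + b)),
    "GA": lambda a, b: 2.0 * math.sqrt(a * b) / (a + b),
    "HZ": lambda a, b: (a + b) ** 2,
}

INDEX_NAMES: tuple[str, ...] = ("M1", "M2", "H", "F", "SS", "ABC", "RI", "SC",
                                "GA", "HZ")


def register_index(name: str, term: Callable[[int, int], float]) -> None:
    """Register a new degree-based index by its per-edge term.

    ``term(a, b)`` receives the sorted endpoint degrees (a <= b, both >= 1)
    and must return a finite real.  Existing names cannot be overwritten.
    """
    if name in _TERMS:
        raise ValueError(f"index {name!r} already registered")
    _TERMS[name] = term


def compute_index(p: EdgePartition, name: str) -> float:
    """Evaluate one index: sum over partition entries of count * term(a, b)."""
    try:
        term = _TERMS[name]
    except KeyError:
        raise KeyError(f"unknown index {name!r}; known: "
                       f"{sorted(_TERMS)}") from None
    return float(sum(c * term(a, b) for (a, b), c in p.counts.items()))


@dataclass(frozen=True)
class DescriptorVector:
    """The ten index values of one molecule."""

    M1: float
    M2: float
    H: float
    F: float
    SS: float
    ABC: float
    RI: float
    SC: float
    GA: float
    HZ: float

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in INDEX_NAMES}

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in INDEX_NAMES)

    def __add__(self, other: "DescriptorVector") -> "DescriptorVector":
        return DescriptorVector(*(x + y for x, y in
                                  zip(self.as_tuple(), other.as_tuple())))


def compute_all(p: EdgePartition) -> DescriptorVector:
    """All ten indices of a partition, in canonical order."""
    return DescriptorVector(**{n: compute_index(p, n) for n in INDEX_NAMES})


def index_from_graph(g: MolecularGraph, name: str) -> float:
    """Convenience: index of a graph via its edge partition."""
    return compute_index(edge_partition(g), name)
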