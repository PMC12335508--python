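"""Bivariate edge-partition polynomials and topological indices.

The neighborhood M-polynomial of a graph G is

    NM(G; s, t) = sum_{k <= l} m_kl * s**k * t**l

where ``m_kl`` counts edges whose endpoint neighbor-degree sums are
``(k, l)``; the analogous degree-based polynomial uses endpoint degrees.
Index values are obtained either by applying operator chains to the
polynomial and evaluating at ``s = t = 1``, or directly as weighted sums
over the partition classes.  Both routes are implemented and must agree;
the operator calculus uses

    Ds = s d/ds,   Dt = t d/dt,   Ss = integral in s of g/s,
    St = integral in t of g/t,    J: g(s, t) -> g(s, s).

Six indices are produced per molecule:

    M1  = sum m (k+l)              first Zagreb       (degree classes)
    M2  = sum m k*l                second Zagreb      (degree classes)
    NM1 = sum m (k+l)              first nbhd Zagreb  (neighborhood classes)
    NM2 = sum m k*l                second nbhd Zagreb (neighborhood classes)
    NH  = sum m 2/(k+l)            neighborhood harmonic
    NSS = sum m sqrt(kl/(k+l))     neighborhood Shilpa-Shanmukha

M1/M2 are computed from the degree partition and NM1/NM2/NH/NSS from the
neighborhood partition: these are the conventions under which the
published index table is internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .molgraph import EdgePartition, MolecularGraph, edge_partition

__all__ = [
    "BivariatePolynomial",
    "IndexVector",
    "INDEX_COLUMNS",
    "partition_polynomial",
    "apply_operator",
    "compute_indices",
    "compute_indices_via_operators",
    "index_table",
]

INDEX_COLUMNS = ("M1", "M2", "NM1", "NM2", "NSS", "NH")


@dataclass(frozen=True)
class BivariatePolynomial:
    """Sparse polynomial ``sum c_ab * s**a * t**b``; zero terms are dropped."""

    terms: Mapping[tuple[int, int], float]

    def __post_init__(self) -> None:
        cleaned = {e: c for e, c in self.terms.items() if c != 0}
        object.__setattr__(self, "terms", cleaned)

    def evaluate(self, s: float, t: float) -> float:
        return sum(c * s**a * t**b for (a, b), c in self.terms.items())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BivariatePolynomial):
            return NotImplemented
        return dict(self.terms) == dict(other.terms)


@dataclass(frozen=True)
class IndexVector:
    """The six index values for one molecule."""

    M1: float
    M2: float
    NM1: float
    NM2: float
    NSS: float
    NH: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.M1, self.M2, self.NM1, self.NM2, self.NSS, self.NH)


def partition_polynomial(p: EdgePartition) -> BivariatePolynomial:
    """The generating polynomial of an edge partition: one term per class."""
    if not p.classes:
        raise ValueError("empty partition (edgeless graph)")
    return BivariatePolynomial({kl: float(m) for kl, m in p.classes.items()})


def apply_operator(poly: BivariatePolynomial, op: str) -> BivariatePolynomial:
    """Apply one operator of the index calculus to ``poly``.

    ``Ds``/``Dt`` multiply each coefficient by the s/t exponent;
    ``Ss``/``St`` divide by it (zero exponents are a division error);
    ``J`` collapses ``(a, b)`` terms to the single variable power ``a+b``.
    """
    out: dict[tuple[int, int], float] = {}
    for (a, b), c in poly.terms.items():
        if op == "Ds":
            key, val = (a, b), c * a
        elif op == "Dt":
            key, val = (a, b), c * b
        elif op == "Ss":
            if a == 0:
                raise ZeroDivisionError("Ss on a term with zero s-exponent")
            key, val = (a, b), c / a
        elif op == "St":
            if b == 0:
                raise ZeroDivisionError("St on a term with zero t-exponent")
            key, val = (a, b), c / b
        elif op == "J":
            key, val = (a + b, 0), c
        else:
            raise ValueError(f"unknown operator {op!r}")
        out[key] = out.get(key, 0.0) + val
    return BivariatePolynomial(out)


def _chain(poly: BivariatePolynomial, ops: Iterable[str]) -> BivariatePolynomial:
    for op in ops:
        poly = apply_operator(poly, op)
    return poly


def compute_indices_via_operators(g: MolecularGraph) -> IndexVector:
    """Index values through the operator calculus (the polynomial route).

    Used as a cross-check against :func:`compute_indices`; both must agree
    to floating tolerance on every graph.
    """
    dpoly = partition_polynomial(edge_partition(g, "degree"))
    npoly = partition_polynomial(edge_partition(g, "neighborhood"))

    def at1(p: BivariatePolynomial) -> float:
        return p.evaluate(1.0, 1.0)

    m1 = at1(apply_operator(dpoly, "Ds")) + at1(apply_operator(dpoly, "Dt"))
    m2 = at1(_chain(dpoly, ["Ds", "Dt"]))
    nm1 = at1(apply_operator(npoly, "Ds")) + at1(apply_operator(npoly, "Dt"))
    nm2 = at1(_chain(npoly, ["Ds", "Dt"]))
    nh = 2.0 * at1(_chain(npoly, ["J", "Ss"]))
    # NSS has no polynomial shortcut: the square root acts per edge class.
    nss = sum(
        m * math.sqrt(k * l / (k + l))
        for (k, l), m in edge_partition(g, "neighborhood").classes.items()
    )
    return IndexVector(M1=m1, M2=m2, NM1=nm1, NM2=nm2, NSS=nss, NH=nh)


def compute_indices(g: MolecularGraph) -> IndexVector:
    """The six indices as direct weighted sums over the edge partitions."""
    if g.n_edges == 0:
        raise ValueError("edgeless graph has no indices")
    dcls = edge_partition(g, "degree").classes
    ncls = edge_partition(g, "neighborhood").classes
    return IndexVector(
        M1=float(sum(m * (k + l) for (k, l), m in dcls.items())),
        M2=float(sum(m * k * l for (k, l), m in dcls.items())),
        NM1=float(sum(m * (k + l) for (k, l), m in ncls.items())),
        NM2=float(sum(m * k * l for (k, l), m in ncls.items())),
        NSS=sum(m * math.sqrt(k * l / (k + l)) for (k, l), m in ncls.items()),
        NH=sum(m * 2.0 / (k + l) for (k, l), m in ncls.items()),
    )


def index_table(graphs: Iterable[MolecularGraph]) -> pd.DataFrame:
    """One row of indices per molecule, indexed by name.

    Column order follows the published index table: M1, M2, NM1, NM2,
    NSS, NH.  Duplicate molecule names are rejected.
    """
    rows: dict[str, tuple[float, ...]] = {}
    for g in graphs:
        if g.name in rows:
            raise ValueError(f"duplicate graph name {g.name!r}")
        rows[g.name] = compute_indices(g).as_tuple()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(INDEX_COLUMNS)).rename_axis("drug")
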