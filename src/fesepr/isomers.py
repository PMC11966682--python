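"""Valence isomers of a [4Fe4S]1+ cubane and their classification.

A reduced [4Fe4S]1+ cluster with an S=1/2 ground state hosts a delocalized
mixed-valence Fe(2.5+)-Fe(2.5+) pair antiferromagnetically coupled to a
ferrous Fe(2+)-Fe(2+) pair.  Distributing the two pairs over the four iron
sites yields C(4,2) = 6 distinct arrangements — the valence isomers.  In
broken-symmetry electronic-structure output the two pairs are readily told
apart by the sign of the per-site spin populations: the majority-spin
(positive) sites form the mixed-valence pair, the minority-spin (negative)
sites the ferrous pair.

This module enumerates the isomers on a cubane topology, classifies a
four-site spin-population record into a pair partition, and compares two
assignments (identical / plane interchange / plane reorientation) — the
vocabulary used to describe how second-sphere rearrangements repartition
the cluster.  It never computes spin populations (that is the electronic
structure code's job) and never maps isomers onto EPR species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CubaneTopology",
    "SpinPopulationRecord",
    "ValenceAssignment",
    "AmbiguousValenceError",
    "TieError",
    "enumerate_valence_isomers",
    "classify_from_spin_populations",
    "compare_assignments",
]


class AmbiguousValenceError(ValueError):
    """Spin populations do not show the 2-positive/2-negative pattern."""


class TieError(ValueError):
    """Two partitions are exactly tied at the group boundary."""

    def __init__(self, message: str, candidates: Sequence["ValenceAssignment"]):
        super().__init__(message)
        self.candidates = list(candidates)


@dataclass(frozen=True)
class CubaneTopology:
    """Four Fe sites, four sulfide bridges, and their adjacency.

    In the default cubane each Fe binds three of the four mu3-sulfides
    (site i is adjacent to every bridge except bridge i).  ``planes``
    optionally names the 6 site-pair "layers" used in structural
    depictions; keys are frozensets of two site labels.
    """

    sites: tuple[str, str, str, str] = ("Fe1", "Fe2", "Fe3", "Fe4")
    bridges: tuple[str, str, str, str] = ("S1", "S2", "S3", "S4")
    adjacency: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    planes: Mapping[frozenset, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.sites)) != 4 or len(set(self.bridges)) != 4:
            raise ValueError("a cubane has exactly 4 distinct Fe sites and 4 bridges")
        adj = dict(self.adjacency)
        if not adj:
            adj = {s: tuple(b for j, b in enumerate(self.bridges) if j != i)
                   for i, s in enumerate(self.sites)}
        for s in self.sites:
            if len(adj.get(s, ())) != 3:
                raise ValueError(f"site {s} must be adjacent to exactly 3 bridges")
        if self.planes:
            expect = {frozenset(p) for p in combinations(self.sites, 2)}
            if {frozenset(k) for k in self.planes} != expect:
                raise ValueError("pair-to-plane map must cover all 6 site pairs")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "planes",
                           {frozenset(k): v for k, v in self.planes.items()})

    def plane_of(self, pair: Sequence[str]) -> str | None:
        return self.planes.get(frozenset(pair)) if self.planes else None


@dataclass(frozen=True)
class SpinPopulationRecord:
    """Signed per-site spin populations from a broken-symmetry calculation."""

    populations: tuple[float, float, float, float]
    sites: tuple[str, str, str, str] = ("Fe1", "Fe2", "Fe3", "Fe4")
    source: str = ""
    scheme: str = "mulliken"

    #: warn when |sum of populations| exceeds this (an S=1/2 state should
    #: leave roughly one net unpaired electron; scheme-dependent, hence a
    #: warning with a configurable threshold, not an error)
    sum_warn_threshold: float = 2.0

    def __post_init__(self) -> None:
        if len(self.populations) != 4 or len(self.sites) != 4:
            raise ValueError("exactly 4 site populations required")
        pops = tuple(float(p) for p in self.populations)
        if not all(np.isfinite(pops)):
            raise ValueError("populations must be finite")
        object.__setattr__(self, "populations", pops)
        if abs(sum(pops)) > self.sum_warn_threshold:
            warnings.warn(
                f"total spin population {sum(pops):+.2f} is large for an "
                "S=1/2 state; check the population scheme", stacklevel=2)


@dataclass(frozen=True)
class ValenceAssignment:
    """A partition of the four sites into mixed-valence and ferrous pairs."""

    mixed_valence_pair: tuple[str, str]
    ferrous_pair: tuple[str, str]
    margin: float = float("inf")
    plane_label: str | None = None

    def __post_init__(self) -> None:
        mv, fe = set(self.mixed_valence_pair), set(self.ferrous_pair)
        if len(mv) != 2 or len(fe) != 2 or mv & fe:
            raise ValueError("pairs must be disjoint 2-site sets")
        object.__setattr__(self, "mixed_valence_pair",
                           tuple(sorted(self.mixed_valence_pair)))
        object.__setattr__(self, "ferrous_pair", tuple(sorted(self.ferrous_pair)))

    @property
    def partition(self) -> frozenset:
        """Role-blind partition: the two pairs as a set of sets."""
        return frozenset({frozenset(self.mixed_valence_pair),
                          frozenset(self.ferrous_pair)})


def enumerate_valence_isomers(topology: CubaneTopology | None = None) -> list[ValenceAssignment]:
    """All six valence isomers, ordered lexicographically by mixed-valence pair.

    Choosing the two mixed-valence sites fixes the ferrous pair, so the six
    C(4,2) choices are exactly the six energetically inequivalent electronic
    states of the cluster.
    """
    topo = topology or CubaneTopology()
    sites = topo.sites
    out = []
    for mv in combinations(sorted(sites), 2):
        fe = tuple(sorted(set(sites) - set(mv)))
        out.append(ValenceAssignment(mv, fe, plane_label=topo.plane_of(mv)))
    return out


def classify_from_spin_populations(
    rec: SpinPopulationRecord,
    topology: CubaneTopology | None = None,
) -> ValenceAssignment:
    """Infer the pair partition from the signs of four spin populations.

    The two most positive populations form the mixed-valence pair, the two
    most negative the ferrous pair; the margin is the gap between the two
    groups (smallest mixed-valence population minus largest ferrous one).
    Requires the antiferromagnetic 2+/2- sign pattern; anything else (all
    parallel spins, a high-spin record) raises AmbiguousValenceError, and an
    exact tie at the group boundary raises TieError carrying both candidate
    partitions.
    """
    pops = np.asarray(rec.populations)
    if np.sum(pops > 0) != 2 or np.sum(pops < 0) != 2:
        raise AmbiguousValenceError(
            f"expected 2 positive / 2 negative spin populations, got {rec.populations}"
        )
    order = np.argsort(pops)  # ascending
    lo_pair, hi_pair = order[:2], order[2:]
    margin = float(pops[hi_pair].min() - pops[lo_pair].max())
    mv = tuple(rec.sites[i] for i in hi_pair)
    fe = tuple(rec.sites[i] for i in lo_pair)
    topo = topology or CubaneTopology(sites=tuple(rec.sites))
    if margin == 0.0:
        # the tied boundary sites are interchangeable: report both partitions
        alt_mv = tuple(rec.sites[i] for i in (order[3], order[1]))
        alt_fe = tuple(rec.sites[i] for i in (order[0], order[2]))
        cands = [
            ValenceAssignment(mv, fe, margin=0.0, plane_label=topo.plane_of(mv)),
            ValenceAssignment(alt_mv, alt_fe, margin=0.0,
                              plane_label=topo.plane_of(alt_mv)),
        ]
        raise TieError("spin populations tie at the group boundary", cands)
    return ValenceAssignment(mv, fe, margin=margin, plane_label=topo.plane_of(mv))


def compare_assignments(
    a: ValenceAssignment,
    b: ValenceAssignment,
    topology: CubaneTopology | None = None,
) -> str:
    """Relate two assignments on one topology.

    ``identical`` — same partition, same roles; ``plane_interchange`` — same
    partition with mixed-valence and ferrous roles swapped (the signature of
    a lysine-side rearrangement); ``plane_reorientation`` — a different pair
    partition altogether (the larger perturbation, repositioning the
    antiferromagnetically coupled planes).
    """
    topo = topology or CubaneTopology()
    site_set = set(topo.sites)
    for x in (a, b):
        if set(x.mixed_valence_pair) | set(x.ferrous_pair) != site_set:
            raise ValueError("assignment does not cover the topology's sites")
    if a.mixed_valence_pair == b.mixed_valence_pair and a.ferrous_pair == b.ferrous_pair:
        return "identical"
    if a.partition == b.partition:
        return "plane_interchange"
    return "plane_reorientation"
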