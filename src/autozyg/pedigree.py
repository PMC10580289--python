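"""Pedigree templates for parental-relatedness (PR) union classes.

Each union class (sibling, avuncular, first cousins for 1-3 successive
generations, first cousins once removed, second cousins, unrelated) is a
small pedigree template whose focal offspring is the child of the template's
"couple".  The expected inbreeding coefficient of the focal offspring is the
kinship coefficient of the couple, computed exactly by the classical
recursion (equivalent to Wright's path counting, and valid for inbred
common ancestors):

    k(i, i) = (1 + F_i) / 2,  F_i = k(father_i, mother_i)
    k(i, j) = [k(i, father_j) + k(i, mother_j)] / 2   (j added after i)

Multi-generation first-cousin classes chain unions along the central sib
line: the linking siblings of generation g are children of the
generation-(g-1) first-cousin couple, so repeated consanguinity raises the
expected autozygosity above 1/16 (~0.0703 for two generations, ~0.0754 for
three).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

__all__ = [
    "Pedigree",
    "UnionClass",
    "UNION_CLASS_LABELS",
    "get_union_class",
    "expected_inbreeding",
]


class Pedigree:
    """Directed acyclic mating graph; individuals indexed by insertion order."""

    def __init__(self) -> None:
        self.parents: list[tuple[int, int] | None] = []
        self._kin: dict[tuple[int, int], float] = {}

    def add_founder(self) -> int:
        self.parents.append(None)
        return len(self.parents) - 1

    def add_child(self, p1: int, p2: int) -> int:
        n = len(self.parents)
        if not (0 <= p1 < n and 0 <= p2 < n):
            raise ValueError("parents must be added before their child")
        if p1 == p2:
            raise ValueError("selfing not supported")
        self.parents.append((p1, p2))
        return n

    @property
    def n_individuals(self) -> int:
        return len(self.parents)

    @property
    def founders(self) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p is None]

    def is_founder(self, i: int) -> bool:
        return self.parents[i] is None

    def kinship(self, i: int, j: int) -> float:
        """Kinship coefficient phi(i, j); phi(father, mother) is the expected
        inbreeding of their child."""
        key = (min(i, j), max(i, j))
        if key in self._kin:
            return self._kin[key]
        if i == j:
            val = (1.0 + self.inbreeding(i)) / 2.0
        else:
            a, b = key  # b added later; its parents precede it
            if self.parents[b] is None:
                if self.parents[a] is None:
                    val = 0.0  # two distinct founders
                else:
                    pa, ma = self.parents[a]
                    val = (self.kinship(b, pa) + self.kinship(b, ma)) / 2.0
            else:
                pb, mb = self.parents[b]
                val = (self.kinship(a, pb) + self.kinship(a, mb)) / 2.0
        self._kin[key] = val
        return val

    def inbreeding(self, i: int) -> float:
        if self.parents[i] is None:
            return 0.0
        p, m = self.parents[i]
        return self.kinship(p, m)


@dataclass(frozen=True)
class UnionClass:
    """A PR class: pedigree template plus the couple whose child is focal."""

    label: str
    pedigree: Pedigree = field(compare=False)
    father: int = field(compare=False)
    mother: int = field(compare=False)

    @property
    def n_founders(self) -> int:
        return len(self.pedigree.founders)

    @property
    def expected_inbreeding(self) -> float:
        """Path-counting expectation of the focal offspring's autozygous
        genome fraction."""
        return self.pedigree.kinship(self.father, self.mother)


def _unrelated() -> tuple[Pedigree, int, int]:
    ped = Pedigree()
    return ped, ped.add_founder(), ped.add_founder()


def _sibling() -> tuple[Pedigree, int, int]:
    ped = Pedigree()
    a, b = ped.add_founder(), ped.add_founder()
    return ped, ped.add_child(a, b), ped.add_child(a, b)


def _avuncular() -> tuple[Pedigree, int, int]:
    ped = Pedigree()
    a, b = ped.add_founder(), ped.add_founder()
    c, d = ped.add_child(a, b), ped.add_child(a, b)
    e = ped.add_founder()
    return ped, c, ped.add_child(d, e)


def _first_cousin_chain(generations: int) -> tuple[Pedigree, int, int]:
    ped = Pedigree()
    a, b = ped.add_founder(), ped.add_founder()
    for _ in range(generations):
        c, d = ped.add_child(a, b), ped.add_child(a, b)  # linking sibs
        e, f = ped.add_founder(), ped.add_founder()  # marrying-in spouses
        a, b = ped.add_child(c, e), ped.add_child(d, f)  # first cousins
    return ped, a, b


def _first_cousin_once_removed() -> tuple[Pedigree, int, int]:
    ped, x, y = _first_cousin_chain(1)
    z = ped.add_child(y, ped.add_founder())
    return ped, x, z


def _second_cousin() -> tuple[Pedigree, int, int]:
    ped, x, y = _first_cousin_chain(1)
    xx = ped.add_child(x, ped.add_founder())
    yy = ped.add_child(y, ped.add_founder())
    return ped, xx, yy


_BUILDERS = {
    "sibling": _sibling,
    "avuncular": _avuncular,
    "first_cousin_1g": lambda: _first_cousin_chain(1),
    "first_cousin_2g": lambda: _first_cousin_chain(2),
    "first_cousin_3g": lambda: _first_cousin_chain(3),
    "first_cousin_once_removed": _first_cousin_once_removed,
    "second_cousin": _second_cousin,
    "unrelated": _unrelated,
}

#: Declared class order; ties in classifier scores break toward the first.
UNION_CLASS_LABELS = tuple(_BUILDERS)


@lru_cache(maxsize=None)
def get_union_class(label: str) -> UnionClass:
    try:
        builder = _BUILDERS[label]
    except KeyError:
        raise KeyError(
            f"unknown union class {label!r}; known: {', '.join(_BUILDERS)}"
        ) from None
    ped, father, mother = builder()
    return UnionClass(label, ped, father, mother)


def expected_inbreeding(label: str) -> float:
    """Expected inbreeding coefficient of the focal offspring of a union
    class (e.g. 1/16 = 0.0625 for first cousins, 1/64 for second cousins)."""
    return get_union_class(label).expected_inbreeding
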