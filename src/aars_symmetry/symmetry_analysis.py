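"""Isometries of the n-bit Hamming space and symmetry of aaRS colorings.

The isometry group of the Hamming space {0,1}^n is the hyperoctahedral
group: every isometry is a coordinate permutation followed by a XOR
translation, x -> pi(x) + t, giving order 2^n * n!.  For the codon space
(n = 6) that is 46,080 elements, small enough to enumerate outright, so
stabilizers of codon sets, color-preserving subgroups and Class I <->
Class II swap isometries ("mirror symmetries") are all found by
exhaustive filtering over the whole group with the action precomputed as
a table of permutations of the 64 vertices.

A biologically structured subgroup (order 3,072) that respects the codon
position structure — permutations of the three positions combined with
per-position isometries of the 2-bit nucleotide square — is available as
an alternative search universe.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from math import factorial
from typing import Iterable, Sequence

import numpy as np

from .aars_annotation import (
    AMBIGUOUS,
    AarsClassification,
    Coloring,
    color_codons,
    default_classification,
)
from .code_models import STOP, CodeStage, GeneticCodeTable
from .codon_algebra import (
    DEFAULT_SCHEME,
    EncodingScheme,
    codon_to_index,
    index_to_codon,
)

#: largest n for which the full hyperoctahedral group is enumerated
MAX_ENUM_BITS = 6

_OUTSIDE = 0  # sentinel color code for codons outside a coloring's set
_COLOR_CODES = {"I": 1, "II": 2, STOP: 3, AMBIGUOUS: 4}


@dataclass(frozen=True)
class IsometryElement:
    """Signed-permutation isometry x -> pi(x) xor t of {0,1}^n.

    `sigma` gives the source coordinate of each output bit
    (y[j] = x[sigma[j]] ^ t[j]); `flip` packs t with bit 0 most
    significant, matching the codon word layout.
    """

    sigma: tuple[int, ...]
    flip: int

    @property
    def n_bits(self) -> int:
        return len(self.sigma)

    def flip_bits(self) -> tuple[int, ...]:
        n = self.n_bits
        return tuple((self.flip >> (n - 1 - j)) & 1 for j in range(n))

    def apply_index(self, x: int) -> int:
        n = self.n_bits
        y = 0
        for j in range(n):
            bit = (x >> (n - 1 - self.sigma[j])) & 1
            y |= bit << (n - 1 - j)
        return y ^ self.flip

    def apply_codon(self, codon: str, scheme: EncodingScheme = DEFAULT_SCHEME) -> str:
        return index_to_codon(self.apply_index(codon_to_index(codon, scheme)), scheme)

    def compose(self, other: "IsometryElement") -> "IsometryElement":
        """self after other: (self.compose(other))(x) = self(other(x))."""
        n = self.n_bits
        if other.n_bits != n:
            raise ValueError("cannot compose isometries on different bit counts")
        t_other = other.flip_bits()
        sigma = tuple(other.sigma[self.sigma[j]] for j in range(n))
        t = tuple(t_other[self.sigma[j]] ^ ((self.flip >> (n - 1 - j)) & 1) for j in range(n))
        return IsometryElement(sigma, _pack_bits(t))

    def inverse(self) -> "IsometryElement":
        n = self.n_bits
        inv = [0] * n
        for j, k in enumerate(self.sigma):
            inv[k] = j
        t = self.flip_bits()
        t_inv = tuple(t[inv[k]] for k in range(n))
        return IsometryElement(tuple(inv), _pack_bits(t_inv))

    @property
    def is_identity(self) -> bool:
        return self.flip == 0 and self.sigma == tuple(range(self.n_bits))

    def order(self) -> int:
        g = self
        k = 1
        while not g.is_identity:
            g = g.compose(self)
            k += 1
        return k


def _pack_bits(bits: Sequence[int]) -> int:
    n = len(bits)
    return sum(b << (n - 1 - j) for j, b in enumerate(bits))


def identity_element(n_bits: int = 6) -> IsometryElement:
    return IsometryElement(tuple(range(n_bits)), 0)


def wc_complement_element(n_bits: int = 6) -> IsometryElement:
    """Watson-Crick complementation: flip the R/Y bit of every position."""
    if n_bits % 2:
        raise ValueError("codon words have an even number of bits")
    flip = _pack_bits([1, 0] * (n_bits // 2))
    return IsometryElement(tuple(range(n_bits)), flip)


class IsometryGroup:
    """An enumerated group (or subset) of Hamming-space isometries."""

    def __init__(self, n_bits: int, elements: list[IsometryElement], flavor: str):
        self.n_bits = n_bits
        self.elements = elements
        self.flavor = flavor
        self._perm_table: np.ndarray | None = None

    @property
    def order(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    @property
    def perm_table(self) -> np.ndarray:
        """(order, 2^n) array: row g maps vertex x to g(x)."""
        if self._perm_table is None:
            self._perm_table = _build_perm_table(self.n_bits, self.elements)
        return self._perm_table

    def subset(self, mask: np.ndarray, flavor: str) -> "IsometryGroup":
        elements = [e for e, keep in zip(self.elements, mask) if keep]
        sub = IsometryGroup(self.n_bits, elements, flavor)
        if self._perm_table is not None:
            sub._perm_table = self._perm_table[np.asarray(mask, dtype=bool)]
        return sub

    def element_order_multiset(self) -> dict[int, int]:
        """Multiset {element order: count} — a cheap isomorphism invariant."""
        if self.order == 0:
            return {}
        return dict(sorted(Counter(_permutation_orders(self.perm_table)).items()))

    def is_closed(self, sample: int | None = None, seed: int = 0) -> bool:
        """Closure check: exhaustive, or on `sample` random pairs."""
        index = {(e.sigma, e.flip) for e in self.elements}
        elems = self.elements
        if sample is None:
            pairs = itertools.product(elems, repeat=2)
        else:
            rng = np.random.default_rng(seed)
            pairs = (
                (elems[i], elems[j])
                for i, j in zip(
                    rng.integers(0, len(elems), sample),
                    rng.integers(0, len(elems), sample),
                )
            )
        return all((a.compose(b).sigma, a.compose(b).flip) in index for a, b in pairs)


def _build_perm_table(n_bits: int, elements: list[IsometryElement]) -> np.ndarray:
    size = 1 << n_bits
    bit_matrix = ((np.arange(size)[:, None] >> (n_bits - 1 - np.arange(n_bits))) & 1).astype(np.uint8)
    weights = 1 << (n_bits - 1 - np.arange(n_bits))
    table = np.empty((len(elements), size), dtype=np.uint16)
    base_cache: dict[tuple[int, ...], np.ndarray] = {}
    for row, e in enumerate(elements):
        base = base_cache.get(e.sigma)
        if base is None:
            base = (bit_matrix[:, list(e.sigma)] * weights).sum(axis=1)
            base_cache[e.sigma] = base
        table[row] = base ^ e.flip
    return table


def _permutation_orders(perm_rows: np.ndarray) -> np.ndarray:
    m, size = perm_rows.shape
    ident = np.arange(size)
    cur = perm_rows.copy()
    orders = np.zeros(m, dtype=np.int64)
    k = 1
    while (orders == 0).any():
        done = (cur == ident).all(axis=1) & (orders == 0)
        orders[done] = k
        cur = np.take_along_axis(perm_rows, cur.astype(np.intp), axis=1)
        k += 1
    return orders


@lru_cache(maxsize=8)
def isometry_group(n_bits: int = 6, flavor: str = "full") -> IsometryGroup:
    """Enumerate the isometry group of {0,1}^n.

    flavor='full': the hyperoctahedral group, order 2^n * n! (46,080 at
    n = 6).  flavor='codon-structured' (n = 6 only): position
    permutations combined with independent 2-bit isometries per
    position, order 6 * 8^3 = 3,072 — the subgroup respecting codon
    position structure.
    """
    if flavor == "full":
        if n_bits > MAX_ENUM_BITS:
            raise ValueError(
                f"full enumeration is limited to n <= {MAX_ENUM_BITS} bits "
                f"(order 2^n * n! = {2**n_bits * factorial(n_bits)} at n = {n_bits})"
            )
        elements = [
            IsometryElement(sigma, flip)
            for sigma in itertools.permutations(range(n_bits))
            for flip in range(1 << n_bits)
        ]
    elif flavor == "codon-structured":
        if n_bits != 6:
            raise ValueError("codon-structured flavor is defined for n_bits = 6")
        elements = []
        for rho in itertools.permutations(range(3)):
            for inner in itertools.product((0, 1), repeat=3):
                sigma = tuple(
                    2 * rho[j] + (b ^ inner[j]) for j in range(3) for b in (0, 1)
                )
                for flip in range(64):
                    elements.append(IsometryElement(sigma, flip))
        elements.sort(key=lambda e: (e.sigma, e.flip))
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    return IsometryGroup(n_bits, elements, flavor)


def _indicator(codons: Iterable[str], scheme: EncodingScheme, size: int) -> np.ndarray:
    ind = np.zeros(size, dtype=bool)
    for c in codons:
        ind[codon_to_index(c, scheme)] = True
    return ind


def _color_array(coloring: Coloring, scheme: EncodingScheme, size: int) -> np.ndarray:
    arr = np.full(size, _OUTSIDE, dtype=np.int8)
    for codon, color in coloring.colors.items():
        arr[codon_to_index(codon, scheme)] = _COLOR_CODES[color]
    return arr


def stabilizer_of_set(
    codons: Iterable[str],
    group: IsometryGroup,
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> IsometryGroup:
    """Subgroup of `group` mapping the codon set onto itself."""
    ind = _indicator(codons, scheme, 1 << group.n_bits)
    mask = (ind[group.perm_table] == ind).all(axis=1)
    return group.subset(mask, flavor=f"stabilizer<{group.flavor}>")


def color_preserving_group(
    coloring: Coloring,
    group: IsometryGroup,
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> IsometryGroup:
    """Subgroup preserving every color class of the coloring setwise."""
    arr = _color_array(coloring, scheme, 1 << group.n_bits)
    mask = (arr[group.perm_table] == arr).all(axis=1)
    return group.subset(mask, flavor=f"color-preserving<{group.flavor}>")


@dataclass(frozen=True)
class SwapResult:
    """Outcome of the Class I <-> Class II swap search (may be empty)."""

    elements: tuple[IsometryElement, ...]
    reason: str = ""

    @property
    def count(self) -> int:
        return len(self.elements)


def class_swap_isometries(
    coloring: Coloring,
    group: IsometryGroup,
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> SwapResult:
    """All isometries exchanging the Class I and Class II codon sets while
    fixing the STOP and AMBIGUOUS classes setwise.  Emptiness is a valid
    outcome; when nonempty the result is a coset of the color-preserving
    subgroup."""
    n_i = len(coloring.color_class("I"))
    n_ii = len(coloring.color_class("II"))
    if n_i == 0 or n_ii == 0:
        return SwapResult((), reason="a class is empty")
    if n_i != n_ii:
        return SwapResult(
            (), reason=f"cardinality mismatch: |Class I| = {n_i}, |Class II| = {n_ii}"
        )
    arr = _color_array(coloring, scheme, 1 << group.n_bits)
    swapped = arr.copy()
    swapped[arr == _COLOR_CODES["I"]] = _COLOR_CODES["II"]
    swapped[arr == _COLOR_CODES["II"]] = _COLOR_CODES["I"]
    mask = (arr[group.perm_table] == swapped).all(axis=1)
    return SwapResult(tuple(e for e, keep in zip(group.elements, mask) if keep))


@dataclass(frozen=True)
class PartitionMatch:
    element: IsometryElement
    block_map: tuple[int, ...]  # block i of partition a -> block_map[i] of b


@dataclass(frozen=True)
class PartitionResult:
    matches: tuple[PartitionMatch, ...]
    reason: str = ""


def partition_correspondence(
    partition_a: Sequence[Iterable[str]],
    partition_b: Sequence[Iterable[str]],
    group: IsometryGroup,
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> PartitionResult:
    """All isometries carrying each block of partition_a onto some block of
    partition_b (inducing a block bijection)."""
    size = 1 << group.n_bits
    blocks_a = [sorted({codon_to_index(c, scheme) for c in blk}) for blk in partition_a]
    blocks_b = [sorted({codon_to_index(c, scheme) for c in blk}) for blk in partition_b]
    universe_a = sorted(i for blk in blocks_a for i in blk)
    universe_b = sorted(i for blk in blocks_b for i in blk)
    if len(universe_a) != sum(map(len, blocks_a)) or len(universe_b) != sum(map(len, blocks_b)):
        raise ValueError("partition blocks must be pairwise disjoint")
    if universe_a != universe_b:
        raise ValueError("both partitions must cover the same codon universe")
    if sorted(map(len, blocks_a)) != sorted(map(len, blocks_b)):
        return PartitionResult((), reason="block-size multiset mismatch")
    labels_b = np.full(size, -1, dtype=np.int64)
    for k, blk in enumerate(blocks_b):
        labels_b[blk] = k
    composed = labels_b[group.perm_table]  # [g, x] = b-block of g(x)
    ok = np.ones(group.order, dtype=bool)
    reps = np.empty((group.order, len(blocks_a)), dtype=np.int64)
    for k, blk in enumerate(blocks_a):
        sub = composed[:, blk]
        ok &= (sub == sub[:, :1]).all(axis=1) & (sub[:, 0] >= 0)
        reps[:, k] = sub[:, 0]
    ok &= np.apply_along_axis(lambda r: len(set(r)) == len(r), 1, reps)
    matches = tuple(
        PartitionMatch(element=e, block_map=tuple(int(v) for v in reps[g]))
        for g, e in enumerate(group.elements)
        if ok[g]
    )
    return PartitionResult(matches)


@dataclass(frozen=True)
class SymmetryReport:
    """Symmetry summary of one code stage under one configuration."""

    stage: str
    scheme: str
    universe_flavor: str
    universe_order: int
    lys_convention: str
    n_codons: int
    color_counts: dict[str, int]
    stabilizer_order: int
    color_preserving_order: int
    class_swap_count: int
    class_swap_reason: str
    stabilizer_element_orders: dict[int, int]
    color_preserving_element_orders: dict[int, int]
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "stage": self.stage,
            "scheme": self.scheme,
            "universe_flavor": self.universe_flavor,
            "universe_order": self.universe_order,
            "lys_convention": self.lys_convention,
            "n_codons": self.n_codons,
            "color_counts": dict(sorted(self.color_counts.items())),
            "stabilizer_order": self.stabilizer_order,
            "color_preserving_order": self.color_preserving_order,
            "class_swap_count": self.class_swap_count,
            "class_swap_reason": self.class_swap_reason,
            "stabilizer_element_orders": {str(k): v for k, v in self.stabilizer_element_orders.items()},
            "color_preserving_element_orders": {str(k): v for k, v in self.color_preserving_element_orders.items()},
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def mirror_symmetry_report(
    stage: CodeStage,
    table: GeneticCodeTable,
    classification: AarsClassification | None = None,
    *,
    lys_convention: str = "class_II",
    universe: str = "full",
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> SymmetryReport:
    """Full symmetry profile of one stage's aaRS coloring: set stabilizer,
    color-preserving subgroup, class-swap coset, element-order multisets."""
    classification = classification or default_classification()
    group = isometry_group(6, universe)
    coloring = color_codons(stage.codons, table, classification, lys_convention)
    stab = stabilizer_of_set(stage.codons, group, scheme)
    pres = color_preserving_group(coloring, group, scheme)
    swaps = class_swap_isometries(coloring, group, scheme)
    return SymmetryReport(
        stage=stage.name,
        scheme=scheme.name,
        universe_flavor=universe,
        universe_order=group.order,
        lys_convention=lys_convention,
        n_codons=len(stage.codons),
        color_counts=coloring.counts(),
        stabilizer_order=stab.order,
        color_preserving_order=pres.order,
        class_swap_count=swaps.count,
        class_swap_reason=swaps.reason,
        stabilizer_element_orders=stab.element_order_multiset(),
        color_preserving_element_orders=pres.element_order_multiset(),
        provenance=coloring.provenance,
    )
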