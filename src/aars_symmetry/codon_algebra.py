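"""Klein four-group encoding of nucleotides and codons.

The four RNA bases form a Klein four-group under an encoding that sends
each base to a pair of bits in GF(2)^2: the first bit records the
purine/pyrimidine (R/Y) class relative to the scheme's identity base, the
second records the weak/strong (A,U vs C,G) class.  Concatenating the
three per-position pairs embeds the 64 codons as the vertices of the
six-dimensional hypercube {0,1}^6, where edges join codons at bit
Hamming distance 1.  Under every supported scheme the two Watson-Crick
pair sums A+U and G+C equal the same constant vector, so positionwise
complementation is a translation of the cube.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

RNA_BASES = ("A", "C", "G", "U")
PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"C", "U"})
WEAK = frozenset({"A", "U"})      # two hydrogen bonds
STRONG = frozenset({"C", "G"})    # three hydrogen bonds
WC_PAIR = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: number of bits in a codon word
N_BITS = 6

# bit weights: position 1 first, R/Y bit before W/S bit within a position
_BIT_WEIGHTS = tuple(1 << (N_BITS - 1 - j) for j in range(N_BITS))


def ry_class(base: str) -> str:
    """Return 'R' for purines and 'Y' for pyrimidines."""
    if base in PURINES:
        return "R"
    if base in PYRIMIDINES:
        return "Y"
    raise ValueError(f"unknown RNA base {base!r}")


@dataclass(frozen=True)
class KleinVector:
    """Element of GF(2)^2; the image of one nucleotide under a scheme."""

    bits: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.bits) != 2 or any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"bits must be a pair over {{0,1}}, got {self.bits}")

    def __add__(self, other: "KleinVector") -> "KleinVector":
        return KleinVector((self.bits[0] ^ other.bits[0], self.bits[1] ^ other.bits[1]))

    @property
    def is_zero(self) -> bool:
        return self.bits == (0, 0)


KLEIN_ELEMENTS = tuple(KleinVector((a, b)) for a in (0, 1) for b in (0, 1))
KLEIN_ZERO = KleinVector((0, 0))


@dataclass(frozen=True)
class EncodingScheme:
    """One of the four square arrangements of the bases on GF(2)^2.

    A scheme is determined by which base sits at the origin (the Klein
    identity): the first bit of any base is 0 iff it shares the identity's
    purine/pyrimidine class, the second is 0 iff it shares its weak/strong
    class.  All four schemes keep the R/Y split on the first bit of each
    position, so every R/Y pattern set is a coordinate-aligned subspace,
    and all four give the constant Watson-Crick pair sum (1, 0).
    """

    name: str
    identity: str
    mapping: dict[str, KleinVector] = field(compare=False)

    @classmethod
    def from_identity(cls, identity: str) -> "EncodingScheme":
        if identity not in RNA_BASES:
            raise ValueError(f"identity base must be one of {RNA_BASES}, got {identity!r}")
        mapping = {}
        for base in RNA_BASES:
            b_ry = 0 if ry_class(base) == ry_class(identity) else 1
            b_ws = 0 if (base in WEAK) == (identity in WEAK) else 1
            mapping[base] = KleinVector((b_ry, b_ws))
        return cls(name=identity, identity=identity, mapping=mapping)

    def encode_base(self, base: str, *, dna: bool = False) -> KleinVector:
        base = _normalize_base(base, dna=dna)
        return self.mapping[base]

    def decode_bits(self, bits: tuple[int, int]) -> str:
        for base, kv in self.mapping.items():
            if kv.bits == bits:
                return base
        raise ValueError(f"no base encodes to {bits}")


#: the four square arrangements, keyed by their identity (origin) base
SCHEMES: dict[str, EncodingScheme] = {b: EncodingScheme.from_identity(b) for b in RNA_BASES}
DEFAULT_SCHEME = SCHEMES["A"]


def _normalize_base(base: str, *, dna: bool = False) -> str:
    if base == "T":
        if dna:
            return "U"
        raise ValueError(
            "invalid base 'T': input is interpreted as RNA; pass dna=True to map T->U"
        )
    if base not in RNA_BASES:
        raise ValueError(f"invalid RNA base {base!r} (expected one of A, C, G, U)")
    return base


def _validate_codon(codon: str, *, dna: bool = False) -> str:
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    return "".join(_normalize_base(b, dna=dna) for b in codon.upper())


@dataclass(frozen=True)
class CodonVector:
    """A codon together with its 6-bit word and integer index (0-63)."""

    codon: str
    bits: tuple[int, int, int, int, int, int]
    scheme: str

    @property
    def index(self) -> int:
        return sum(b * w for b, w in zip(self.bits, _BIT_WEIGHTS))


def encode_codon(codon: str, scheme: EncodingScheme = DEFAULT_SCHEME, *, dna: bool = False) -> CodonVector:
    """Embed a codon into {0,1}^6: position 1 first, R/Y bit first."""
    codon = _validate_codon(codon, dna=dna)
    bits: list[int] = []
    for base in codon:
        bits.extend(scheme.encode_base(base).bits)
    return CodonVector(codon=codon, bits=tuple(bits), scheme=scheme.name)


def decode_bits(bits: Sequence[int], scheme: EncodingScheme = DEFAULT_SCHEME) -> str:
    if len(bits) != N_BITS:
        raise ValueError(f"expected {N_BITS} bits, got {len(bits)}")
    return "".join(
        scheme.decode_bits((bits[2 * i], bits[2 * i + 1])) for i in range(3)
    )


def codon_to_index(codon: str, scheme: EncodingScheme = DEFAULT_SCHEME) -> int:
    return encode_codon(codon, scheme).index


def index_to_codon(index: int, scheme: EncodingScheme = DEFAULT_SCHEME) -> str:
    if not 0 <= index < 64:
        raise ValueError(f"codon index must be in 0..63, got {index}")
    bits = tuple((index >> (N_BITS - 1 - j)) & 1 for j in range(N_BITS))
    return decode_bits(bits, scheme)


def all_codons() -> list[str]:
    """The 64 codons in canonical alphabetical order (A < C < G < U)."""
    return ["".join(p) for p in itertools.product(RNA_BASES, repeat=3)]


def iter_codons() -> Iterator[str]:
    yield from all_codons()


def hamming_nt(c1: str, c2: str) -> int:
    """Nucleotide Hamming distance: positions at which the bases differ."""
    c1 = _validate_codon(c1)
    c2 = _validate_codon(c2)
    return sum(a != b for a, b in zip(c1, c2))


def hamming_bit(v1: CodonVector, v2: CodonVector) -> int:
    """Bit Hamming distance between two codon words (same scheme only)."""
    if v1.scheme != v2.scheme:
        raise ValueError(
            f"cannot compare words from different schemes ({v1.scheme!r} vs {v2.scheme!r})"
        )
    return sum(a != b for a, b in zip(v1.bits, v2.bits))


def wc_complement(codon: str) -> str:
    """Positionwise Watson-Crick complement (no strand reversal)."""
    codon = _validate_codon(codon)
    return "".join(WC_PAIR[b] for b in codon)


def transversion(codon: str, position: int, kind: str = "ry") -> str:
    """Exchange the base at `position` (1-based) for one of the other class.

    kind='ry' swaps within the Watson-Crick pair (A<->U, C<->G): under the
    default scheme this toggles only the R/Y bit.  kind='full' exchanges
    A<->C and G<->U, toggling both bits.  Either changes the R/Y class.
    """
    codon = _validate_codon(codon)
    if position not in (1, 2, 3):
        raise ValueError(f"position must be 1, 2 or 3, got {position}")
    if kind == "ry":
        swap = WC_PAIR
    elif kind == "full":
        swap = {"A": "C", "C": "A", "G": "U", "U": "G"}
    else:
        raise ValueError(f"kind must be 'ry' or 'full', got {kind!r}")
    i = position - 1
    return codon[:i] + swap[codon[i]] + codon[i + 1 :]


def wc_pair_sum(scheme: EncodingScheme = DEFAULT_SCHEME) -> KleinVector:
    """The constant Klein sum of a Watson-Crick pair under `scheme`."""
    sums = {
        (scheme.encode_base(a) + scheme.encode_base(b)).bits
        for a, b in (("A", "U"), ("G", "C"))
    }
    if len(sums) != 1:
        raise ValueError(f"scheme {scheme.name!r} has non-constant Watson-Crick sums")
    return KleinVector(next(iter(sums)))
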