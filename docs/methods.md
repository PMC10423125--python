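# Methods

## Codon encoding

A codon is encoded as a 6-bit word over GF(2): position 1 first and,
within each position, the purine/pyrimidine (R/Y) bit before the
weak/strong bit. Four encoding schemes are provided, one per choice of
the origin base (A, C, G or U); a scheme maps base *x* to
(same-R/Y-class-as-origin?, same-weak/strong-class-as-origin?). Under
the default scheme the origin is A, so A = (0,0), G = (0,1), U = (1,0),
C = (1,1). Every scheme keeps the R/Y split on the first bit of each
position — which is what makes every R/Y pattern set a
coordinate-aligned subspace — and every scheme gives the constant
Watson–Crick pair sum (1,0), so positionwise complementation is the
translation by (1,0,1,0,1,0), itself an isometry of the cube. The
schemes are named by their origin base because that is the only degree
of freedom once the two bits are tied to the R/Y and weak/strong
partitions. Strict RNA input is the default; `dna=True` maps T to U.

One consequence worth spelling out: which pattern sets are *linear*
subspaces (contain the zero word) depends on the scheme's origin. NNY
is a 5-dimensional coordinate-aligned affine subspace under every
scheme, but it passes through the origin only when the origin base is a
pyrimidine (schemes "C" and "U"). The affine/aligned/dimension fields of
`subspace_report` are scheme-invariant; `contains_zero` is not, and is
reported per scheme.

## Code stages

Stage definitions follow the frame-shift reading for Extended code
type 1 (RNY ∪ NYR ∪ YRN) and the transversion reading for type 2
(RNY ∪ YNY ∪ RNR). The two extended codes each hold 48 codons; the
complement of type 1 is RRR ∪ YYY and that of type 2 is YNR
(= YYR ∪ YRR). STOP is a distinct label throughout, never counted as an
amino acid, so "EXT2 codes 18 amino acids" excludes stops by
construction. `duplication_report` splits a complement's amino acids
into those already coded inside the stage ("duplicated") and those
first introduced by the complement, and exposes both subsets, since the
two readings of "duplication" differ for Lys/Glu/Phe (type 1) and
Gln/Trp (type 2).

## aaRS classification

The shipped classification is: Class Ia Met, Val, Leu, Ile, Cys, Arg;
Ib Glu, Gln, Lys(I); Ic Tyr, Trp; IIa Ser, Thr, Ala, Gly, Pro, His; IIb
Asp, Asn, Lys(II); IIc Phe. Lysine's convention is a parameter:
`ambiguous` (its own color; matches the per-stage figure arithmetic for
RNR), `class_I`, or `class_II` — the latter is the only resolution that
yields the 10 + 10 split of the 20 synthetases, and is the default for
codon colorings. SepRS and PylRS charge non-canonical amino acids
absent from the standard table and are rejected unless extended mode is
enabled. Colorings are codon-level (vertex colors, as in the cube
figures), with STOP codons forming a color class of their own that
symmetry searches must fix setwise.

## Symmetry searches

Every isometry of {0,1}⁶ is a coordinate permutation followed by a XOR
translation; the group has order 2⁶·6! = 46,080 and is enumerated
outright (refusing n > 6), with each element's action on the 64
vertices precomputed into a (46,080 × 64) table. Stabilizers,
color-preserving subgroups, class-swap cosets and partition
correspondences are all exhaustive boolean filters over that table
(milliseconds each). An alternative "codon-structured" universe — the
subgroup respecting codon positions: permutations of the three
positions crossed with per-position isometries of the 2-bit nucleotide
square, order 6·8³ = 3,072 — is selectable, and every report records
which universe was searched. Element enumeration is lexicographic in
(permutation, flip) so all outputs are deterministic.

Swap searches short-circuit when the Class I and Class II codon sets
have different sizes, reporting the mismatch as the reason; when
nonempty, the swap set is necessarily a left coset of the
color-preserving subgroup, and the suite checks exactly that. For the
real classification the codon-level cardinalities never match (e.g.
29 vs 32 in the SGC under Lys→II, 20 vs 28 in EXT2), so the codon-level
mirror is empty at every stage even though the amino-acid-level 10 + 10
mirror exists; the package reports both levels rather than forcing
agreement. Group *comparison* across stages uses order plus the
element-order multiset — cheap isomorphism invariants — rather than
abstract group identification.

The Rodin–Ohno middle-base partition {NAN, NGN, NUN, NCN} does map onto
{RNR, YNR, RNY, YNY} inside the isometry group: `partition_correspondence`
finds 3,072 realizing elements, so the piecewise-defined correspondence
is realizable by genuine cube isometries.

## Null models

Two randomizations bracket the real configuration: `shuffle-classes`
draws a uniform 10 + 10 class partition of the 20 amino acids (the
constraint the real classification satisfies under Lys→II; subclasses
are irrelevant to any symmetry computation and are set to "a"), and
`shuffle-code-table` permutes amino-acid labels among synonym blocks of
equal codon count, so each amino acid keeps its exact degeneracy and
the three stop codons never move. Sample *k* is drawn from a generator
seeded with the pair (seed, k) via SeedSequence spawn keys, so any
sample is reproducible without generating its predecessors. The default
of 200 samples keeps a full-universe run on one CPU in the seconds
range because the search space is first cut to the stage's set
stabilizer, which every color-preserving or swap element must inhabit.

What the null emulates is the *assignment* randomness only: which amino
acids carry which class, or which synonym block carries which label. It
does not model historical code evolution, biochemical constraints on
class membership, or wobble structure, so a significant departure from
the null speaks to the arrangement of classes on the cube, not to any
evolutionary mechanism.

## Numerical and design choices

- All set orderings in outputs are canonical (alphabetical A < C < G < U);
  reports are JSON with sorted keys; reruns with equal analytic
  configuration are byte-identical, and every artifact carries a hash of
  that configuration (output paths excluded from the hash).
- Graph adjacency defaults to bit-Hamming distance 1 (the 6-cube). A
  `nucleotide` adjacency flag (any single-position substitution, i.e.
  the square-with-diagonals base arrangement, 9-regular on the full
  code) is provided because the figure convention cannot be pinned down
  from edge counts alone.
- Layouts are parallel projections with binary weights — x from the
  three R/Y bits, y from the three weak/strong bits — injective on all
  64 vertices and translation-equivariant across hyperfaces; a
  `per-figure-4D` variant first drops each face's fixed coordinates.
  Rendering is out of scope; layouts export as CSV, graphs as GraphML
  with amino-acid/class attributes.
- The affine test translates the set by its first member and checks XOR
  closure; the suite cross-checks it against a brute-force oracle that
  tries all 64 translations and rebuilds GF(2) spans.
- The acceptance script runs the group searches at their full size
  (46,080 elements) and the null calibration at 200 + 500 samples; the
  whole script completes in a few seconds on one CPU.

## Limitations

- The symmetry vocabulary is restricted to Hamming-space isometries;
  piecewise or non-isometric automorphisms are out of scope except as
  partition correspondences that happen to be realizable by isometries.
- Only order and element-order multisets are reported for subgroup
  comparison; two subgroups agreeing on both may still be
  non-isomorphic.
- The built-in tables are the standard nuclear code and the canonical
  20-synthetase classification; organellar codes can be loaded but are
  not shipped, and wobble/isoacceptor structure is not modeled.
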