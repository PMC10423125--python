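# aars-symmetry

Symmetry analysis of how the two structural classes of aminoacyl-tRNA
synthetases (aaRSs) distribute over hypothesized evolutionary stages of
the genetic code, carried out on the six-dimensional codon hypercube.

## The problem

Each of the 20 canonical amino acids is charged onto its tRNA by a
synthetase belonging to one of two unrelated structural superfamilies,
Class I and Class II (with subclasses a–c; lysine alone has a synthetase
in both classes). A long-standing hypothesis holds that the code grew
from a primeval 16-codon **RNY** repertoire (purine, any base,
pyrimidine) through 48-codon intermediates — an **Extended code type 1**
(RNY plus the frame-shifted pattern sets NYR and YRN) and an **Extended
code type 2** (RNY plus the transversion-derived sets YNY and RNR) — to
the full 64-codon standard genetic code (SGC). This package asks, and
answers exactly: *how symmetric is the Class I / Class II coloring of
each stage, and is there a "mirror" isometry exchanging the two
classes?*

## The model

Encoding each base by two bits — purine/pyrimidine (R/Y) and weak/strong
— makes the four bases a Klein four-group in which the Watson–Crick pair
sums A+U and G+C are the same constant, and embeds the 64 codons as the
vertices of the Hamming cube {0,1}⁶. In this geometry:

- every pure R/Y pattern (RRR, RYY, …) is a 3-cube with 12 edges; the
  eight of them partition the codon space;
- RNY, YNY, RNR and YNR are coordinate-aligned 4-dimensional affine
  subspaces (hyperfaces) inducing Q₄ graphs;
- the complement of Extended code 1, RRR ∪ YYY, is an affine but *not*
  coordinate-aligned 4-space — a "hyperprism" of two 3-cubes whose
  closest codons differ at all three positions.

The isometry group of the 6-cube is the hyperoctahedral group of signed
coordinate permutations x ↦ π(x) ⊕ t, of order 2⁶·6! = 46,080 — small
enough to enumerate, so every symmetry question is answered by
exhaustive search: the **stabilizer** of a stage's codon set, the
subgroup **preserving its aaRS coloring** (Class I, Class II, STOP each
fixed setwise), and the coset of **class-swap isometries** with
g(Class I) = Class II and vice versa. A null module re-runs the same
searches over random 10+10 class partitions and degeneracy-preserving
code shuffles, so observed symmetry can be compared with chance.

## Worked example

```sh
aars-symmetry symmetry --stage ext2
```

prints (abridged):

```json
{
  "stage": "EXT2",
  "n_codons": 48,
  "color_counts": {"I": 20, "II": 28},
  "stabilizer_order": 768,
  "color_preserving_order": 2,
  "class_swap_count": 0,
  "class_swap_reason": "cardinality mismatch: |Class I| = 20, |Class II| = 28",
  "universe_order": 46080
}
```

Reading: the 48 codons of Extended code type 2 sit inside the 6-cube
with a set stabilizer of 768 isometries, but only 2 of those preserve
the Class I / Class II coloring, and no isometry can exchange the
classes because 20 Class I codons cannot map onto 28 Class II codons.
At the amino-acid level the split is perfectly mirror-symmetric — with
LysRS counted in Class II, exactly 10 synthetases fall in each class
(`aars-symmetry stages`, `class_counts`) — but at codon level the
degeneracy of the code breaks the mirror, which the exhaustive search
reports honestly.

Other entry points: `aars-symmetry stages --stage rny` (codon and
amino-acid accounting), `aars-symmetry null --stage sgc --seed 1 --n 200`
(null distribution), `aars-symmetry report --out out/` (full per-stage
bundle with GraphML graphs, layouts and a summary CSV),
`aars-symmetry validate` (input checking). Alternative code tables are
loadable as 64-row `codon<TAB>label` TSV files.

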