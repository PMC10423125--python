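"""Hypercube graphs of codon sets and affine-subspace structure over GF(2).

A codon set induces a subgraph of the 6-cube (vertices = 6-bit codon
words, edges = bit Hamming distance 1).  Pattern sets like RNY are
coordinate-aligned affine subspaces — translates of linear subspaces
obtained by fixing some of the six coordinates — and their induced
graphs are lower-dimensional hypercubes.  The complement of the Extended
RNA code type 1 (RRR u YYY) is the exception: affine but not
coordinate-aligned, its graph splits into two 3-cubes at mutual distance
3 (a "hyperprism").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from .aars_annotation import Coloring
from .code_models import STOP, GeneticCodeTable, amino_acids_of, ry_pattern_of
from .codon_algebra import (
    DEFAULT_SCHEME,
    N_BITS,
    EncodingScheme,
    codon_to_index,
    encode_codon,
    hamming_nt,
)


def build_graph(
    codons: Iterable[str],
    scheme: EncodingScheme = DEFAULT_SCHEME,
    adjacency: str = "bit",
) -> nx.Graph:
    """Induced subgraph of the 6-cube (or of the nucleotide-distance graph).

    adjacency='bit' joins codons at bit Hamming distance 1 (the paper-style
    hypercube); adjacency='nucleotide' joins codons differing at exactly
    one position regardless of the substitution (the square-with-diagonals
    arrangement, where transitions and transversions are both one step).
    """
    if adjacency not in ("bit", "nucleotide"):
        raise ValueError(f"adjacency must be 'bit' or 'nucleotide', got {adjacency!r}")
    codons = sorted(set(codons))
    g = nx.Graph(scheme=scheme.name, adjacency=adjacency)
    vectors = {c: encode_codon(c, scheme) for c in codons}
    for c in codons:
        g.add_node(c, index=vectors[c].index, bits="".join(map(str, vectors[c].bits)))
    for i, c1 in enumerate(codons):
        for c2 in codons[i + 1 :]:
            if adjacency == "bit":
                d = bin(vectors[c1].index ^ vectors[c2].index).count("1")
            else:
                d = hamming_nt(c1, c2)
            if d == 1:
                g.add_edge(c1, c2)
    return g


@dataclass(frozen=True)
class SubspaceReport:
    """GF(2) affine structure of a codon set under one encoding scheme."""

    is_affine: bool
    dimension: int | None
    is_coordinate_aligned: bool
    fixed_coordinates: dict[int, int]  # coordinate (0-5) -> shared bit value
    contains_zero: bool


def subspace_report(codons: Iterable[str], scheme: EncodingScheme = DEFAULT_SCHEME) -> SubspaceReport:
    """Test whether a codon set is an affine subspace of {0,1}^6.

    The set is affine iff its translate by any member is closed under
    GF(2) addition (XOR).  It is coordinate-aligned iff coordinates fixed
    across all members account for the full codimension, i.e. the set is
    a hyperface of the 6-cube.
    """
    idx = sorted({codon_to_index(c, scheme) for c in codons})
    if not idx:
        raise ValueError("subspace_report requires a nonempty codon set")
    v0 = idx[0]
    translated = {v ^ v0 for v in idx}
    is_affine = all((a ^ b) in translated for a in translated for b in translated)
    n = len(idx)
    dimension = n.bit_length() - 1 if is_affine else None
    fixed: dict[int, int] = {}
    for j in range(N_BITS):
        values = {(v >> (N_BITS - 1 - j)) & 1 for v in idx}
        if len(values) == 1:
            fixed[j] = values.pop()
    is_aligned = bool(is_affine) and len(fixed) == N_BITS - (dimension or 0)
    return SubspaceReport(
        is_affine=is_affine,
        dimension=dimension,
        is_coordinate_aligned=is_aligned,
        fixed_coordinates=fixed,
        contains_zero=0 in idx,
    )


@dataclass(frozen=True)
class IncidenceReport:
    """How each amino acid of a 3-cube sits in the cube's graph."""

    cube_pattern: str
    edge_amino_acids: frozenset[str]       # codons form exactly one full edge
    singleton_amino_acids: frozenset[str]  # present at exactly one vertex
    components: dict[str, list[int]]       # amino acid -> sizes of its induced components
    stop_edge_count: int
    stop_component_count: int


def amino_acid_incidence(
    cube_codons: Iterable[str],
    table: GeneticCodeTable,
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> IncidenceReport:
    """Classify the amino acids of an 8-codon R/Y pattern cube by the
    structure of their induced subgraphs (edge / singleton / larger)."""
    cube = sorted(set(cube_codons))
    patterns = {ry_pattern_of(c) for c in cube}
    if len(cube) != 8 or len(patterns) != 1:
        raise ValueError(
            "amino_acid_incidence requires one of the 8-codon pure R/Y pattern cubes"
        )
    g = build_graph(cube, scheme)
    aas, _ = amino_acids_of(cube, table)
    components: dict[str, list[int]] = {}
    edge_aas, singleton_aas = set(), set()
    for aa in sorted(aas):
        vertices = [c for c in cube if table.translate(c) == aa]
        sub = g.subgraph(vertices)
        sizes = sorted(len(comp) for comp in nx.connected_components(sub))
        components[aa] = sizes
        if len(vertices) == 1:
            singleton_aas.add(aa)
        elif len(vertices) == 2 and sub.number_of_edges() == 1:
            edge_aas.add(aa)
    stop_vertices = [c for c in cube if table.translate(c) == STOP]
    stop_sub = g.subgraph(stop_vertices)
    return IncidenceReport(
        cube_pattern=patterns.pop(),
        edge_amino_acids=frozenset(edge_aas),
        singleton_amino_acids=frozenset(singleton_aas),
        components=components,
        stop_edge_count=stop_sub.number_of_edges(),
        stop_component_count=nx.number_connected_components(stop_sub) if stop_vertices else 0,
    )


def layout_coordinates(
    graph: nx.Graph, projection: str = "parallel-projection-6to2"
) -> dict[str, tuple[float, float]]:
    """Deterministic 2D coordinates for a codon graph.

    'parallel-projection-6to2' projects the 6 coordinates onto the plane
    with binary weights: x reads the three R/Y bits, y the three W/S
    bits, so the layout is injective on all 64 vertices and hyperfaces
    that differ only in a fixed bit are translates of each other.
    'per-figure-4D' drops each vertex's fixed coordinates first, giving
    the compact Q4 layouts used for the 16-codon pattern figures.
    """
    if projection not in ("parallel-projection-6to2", "per-figure-4D"):
        raise ValueError(f"unknown projection {projection!r}")
    nodes = sorted(graph.nodes)
    bits = {c: [int(b) for b in graph.nodes[c]["bits"]] for c in nodes}
    if projection == "per-figure-4D":
        free = [j for j in range(N_BITS) if len({bits[c][j] for c in nodes}) > 1]
        bits = {c: [bits[c][j] for j in free] for c in nodes}
    layout: dict[str, tuple[float, float]] = {}
    for c in nodes:
        b = bits[c]
        xs = b[0::2]
        ys = b[1::2]
        x = sum(v * 2 ** (len(xs) - 1 - i) for i, v in enumerate(xs))
        y = sum(v * 2 ** (len(ys) - 1 - i) for i, v in enumerate(ys))
        layout[c] = (float(x), float(y))
    return layout


def component_min_distance(graph: nx.Graph, metric: str = "nucleotide") -> int | None:
    """Minimum pairwise distance between distinct connected components."""
    comps = [sorted(c) for c in nx.connected_components(graph)]
    if len(comps) < 2:
        return None
    best: int | None = None
    for i, a in enumerate(comps):
        for b in comps[i + 1 :]:
            for c1 in a:
                for c2 in b:
                    if metric == "nucleotide":
                        d = hamming_nt(c1, c2)
                    else:
                        d = bin(graph.nodes[c1]["index"] ^ graph.nodes[c2]["index"]).count("1")
                    best = d if best is None else min(best, d)
    return best


def annotate_graph(
    graph: nx.Graph, table: GeneticCodeTable, coloring: Coloring | None = None
) -> nx.Graph:
    """Attach amino_acid / aars_class / color vertex attributes in place."""
    for codon in graph.nodes:
        label = table.translate(codon)
        graph.nodes[codon]["amino_acid"] = label
        if coloring is not None and codon in coloring.colors:
            graph.nodes[codon]["aars_class"] = coloring.colors[codon]
            graph.nodes[codon]["color"] = {
                "I": "blue", "II": "red", STOP: "yellow", "AMBIGUOUS": "purple",
            }.get(coloring.colors[codon], "gray")
    return graph


def export_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def export_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon1\tcodon2\n")
        for c1, c2 in sorted(graph.edges):
            fh.write(f"{c1}\t{c2}\n")


def export_layout(layout: dict[str, tuple[float, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon,x,y\n")
        for codon in sorted(layout):
            x, y = layout[codon]
            fh.write(f"{codon},{x:g},{y:g}\n")
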