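"""Randomized null models for the aaRS class distribution.

The observed symmetry of a class coloring is only meaningful against
chance, so this module generates the two natural randomizations:

* ``shuffle-classes`` — keep the code table, reassign the 20 amino acids
  uniformly at random into a 10 + 10 Class I / Class II split (the
  constraint the real classification satisfies under the Lys -> Class II
  convention);
* ``shuffle-code-table`` — keep the classification, permute amino-acid
  labels over the standard code's synonym blocks.  With degeneracy
  preservation on, labels are permuted only among blocks of equal codon
  count, so every amino acid keeps its codon number; stop codons are
  never moved.

Each sample k is drawn from its own generator seeded with (seed, k), so
any sample is reproducible in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from .aars_annotation import (
    AarsClassification,
    AarsRecord,
    color_codons,
    default_classification,
)
from .code_models import (
    AMINO_ACIDS_3,
    STOP,
    CodeStage,
    GeneticCodeTable,
    degeneracy_profile,
    standard_code,
)
from .codon_algebra import DEFAULT_SCHEME, EncodingScheme
from .symmetry_analysis import (
    IsometryGroup,
    class_swap_isometries,
    color_preserving_group,
    isometry_group,
    stabilizer_of_set,
)

NULL_MODES = ("shuffle-classes", "shuffle-code-table")


@dataclass(frozen=True)
class NullConfig:
    seed: int
    n_samples: int = 200
    mode: str = "shuffle-classes"
    preserve_degeneracy: bool = True
    lys_convention: str = "class_II"
    universe: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in NULL_MODES:
            raise ValueError(f"mode must be one of {NULL_MODES}, got {self.mode!r}")
        if self.n_samples < 0:
            raise ValueError("n_samples must be nonnegative")


def _sample_rng(seed: int, sample_index: int) -> np.random.Generator:
    # counter-mixed substream: sample k depends only on (seed, k)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(sample_index,)))


def random_class_partition(seed: int, sample_index: int = 0) -> AarsClassification:
    """Uniformly random 10 + 10 Class I / Class II split of the 20 amino
    acids.  Subclasses carry no weight in the symmetry analysis and are
    set to 'a' throughout."""
    rng = _sample_rng(seed, sample_index)
    order = rng.permutation(len(AMINO_ACIDS_3))
    class_i = {AMINO_ACIDS_3[i] for i in order[:10]}
    records = {
        aa: AarsRecord(aa, "I" if aa in class_i else "II", "a")
        for aa in AMINO_ACIDS_3
    }
    return AarsClassification(records=records, source=f"null(seed={seed},k={sample_index})")


def random_code_table(
    seed: int, sample_index: int = 0, preserve_degeneracy: bool = True
) -> GeneticCodeTable:
    """Randomized code table derived from the standard code.

    With preservation, amino-acid labels are permuted among synonym
    blocks of equal size, leaving the codon count of every amino acid —
    the degeneracy profile — unchanged.  Without it, every sense codon
    independently draws a label, redrawn until all 20 amino acids occur.
    Stop codons stay fixed at the standard three in both modes.
    """
    rng = _sample_rng(seed, sample_index)
    sgc = standard_code()
    mapping = dict(sgc.mapping)
    sense = sorted(c for c in mapping if mapping[c] != STOP)
    if preserve_degeneracy:
        profile = degeneracy_profile(sgc)
        by_size: dict[int, list[str]] = {}
        for aa in sorted(profile):
            by_size.setdefault(profile[aa], []).append(aa)
        relabel: dict[str, str] = {}
        for size in sorted(by_size):
            aas = by_size[size]
            perm = rng.permutation(len(aas))
            for i, aa in enumerate(aas):
                relabel[aa] = aas[perm[i]]
        for codon in sense:
            mapping[codon] = relabel[mapping[codon]]
    else:
        aas = list(AMINO_ACIDS_3)
        while True:
            draw = rng.integers(0, len(aas), size=len(sense))
            if len(set(draw.tolist())) == len(aas):
                break
        for codon, k in zip(sense, draw):
            mapping[codon] = aas[k]
    return GeneticCodeTable(
        mapping=mapping,
        source=f"null(seed={seed},k={sample_index},preserve={preserve_degeneracy})",
    )


@dataclass(frozen=True)
class NullSummary:
    """Null distribution of coloring symmetry for one stage."""

    config: NullConfig
    stage: str
    observed_color_preserving_order: int
    observed_swap_count: int
    color_preserving_orders: tuple[int, ...]
    swap_counts: tuple[int, ...]
    quantiles: dict[str, float]
    swap_nonempty_fraction: float

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "stage": self.stage,
            "observed_color_preserving_order": self.observed_color_preserving_order,
            "observed_swap_count": self.observed_swap_count,
            "color_preserving_orders": list(self.color_preserving_orders),
            "swap_counts": list(self.swap_counts),
            "quantiles": self.quantiles,
            "swap_nonempty_fraction": self.swap_nonempty_fraction,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def symmetry_null_distribution(
    config: NullConfig,
    stage: CodeStage,
    *,
    table: GeneticCodeTable | None = None,
    classification: AarsClassification | None = None,
    scheme: EncodingScheme = DEFAULT_SCHEME,
) -> NullSummary:
    """Distribution of color-preserving subgroup orders and swap-coset
    sizes over randomized colorings, next to the observed values.

    The search universe is restricted once to the stage's set stabilizer
    (colorings share the stage's codon set, so any color-preserving or
    swap element must stabilize the set)."""
    table = table or standard_code()
    classification = classification or default_classification()
    group = isometry_group(6, config.universe)
    stab = stabilizer_of_set(stage.codons, group, scheme)

    def profile(tab: GeneticCodeTable, cls: AarsClassification) -> tuple[int, int]:
        coloring = color_codons(stage.codons, tab, cls, config.lys_convention)
        pres = color_preserving_group(coloring, stab, scheme)
        swaps = class_swap_isometries(coloring, stab, scheme)
        return pres.order, swaps.count

    observed_pres, observed_swaps = profile(table, classification)
    pres_orders: list[int] = []
    swap_counts: list[int] = []
    for k in range(config.n_samples):
        if config.mode == "shuffle-classes":
            sample_cls, sample_tab = random_class_partition(config.seed, k), table
        else:
            sample_cls = classification
            sample_tab = random_code_table(config.seed, k, config.preserve_degeneracy)
        p, s = profile(sample_tab, sample_cls)
        pres_orders.append(p)
        swap_counts.append(s)

    if pres_orders:
        qs = np.quantile(np.array(pres_orders, dtype=float), [0.05, 0.5, 0.95])
        quantiles = {"q05": float(qs[0]), "q50": float(qs[1]), "q95": float(qs[2])}
        swap_frac = float(np.mean([s > 0 for s in swap_counts]))
    else:
        quantiles = {}
        swap_frac = float("nan")
    return NullSummary(
        config=config,
        stage=stage.name,
        observed_color_preserving_order=observed_pres,
        observed_swap_count=observed_swaps,
        color_preserving_orders=tuple(pres_orders),
        swap_counts=tuple(swap_counts),
        quantiles=quantiles,
        swap_nonempty_fraction=swap_frac,
    )


def class_i_frequencies(seed: int, n_samples: int) -> dict[str, float]:
    """Per-amino-acid frequency of landing in Class I across null
    partitions; should hover near 0.5 by symmetry of the 10 + 10 draw."""
    counts = {aa: 0 for aa in AMINO_ACIDS_3}
    for k in range(n_samples):
        cls = random_class_partition(seed, k)
        for aa in cls.class_members("I", "class_II"):
            counts[aa] += 1
    return {aa: counts[aa] / n_samples for aa in AMINO_ACIDS_3}
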