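"""Genetic code tables, R/Y pattern sets and the evolutionary code stages.

The code stages model a hypothesized trajectory of the genetic code:

* ``RNY`` — the primeval RNA code: purine, any base, pyrimidine (16 codons);
* ``EXT1`` — Extended RNA code type 1: RNY plus the second- and
  third-frame pattern sets NYR and YRN (48 codons);
* ``EXT2`` — Extended RNA code type 2: RNY plus the transversion-derived
  sets YNY (first base) and RNR (third base) (48 codons);
* ``SGC`` — the full standard genetic code (64 codons).

``NNY`` and ``NNR`` (the half-spaces by third-base class) are also
available as stages since several accounting statements refer to them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .codon_algebra import PURINES, PYRIMIDINES, RNA_BASES, all_codons, ry_class

STOP = "STOP"

AMINO_ACIDS_3 = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

_PATTERN_CLASSES = {
    "R": PURINES,
    "Y": PYRIMIDINES,
    "N": frozenset(RNA_BASES),
    **{b: frozenset({b}) for b in RNA_BASES},
}

STAGE_NAMES = ("RNY", "EXT1", "EXT2", "NNY", "NNR", "SGC")


def normalize_label(label: str) -> str:
    """Accept a 3-letter, 1-letter or STOP label; return canonical 3-letter."""
    if label.upper() == STOP or label == "*":
        return STOP
    if len(label) == 1:
        if label.upper() not in ONE_TO_THREE:
            raise ValueError(f"unknown one-letter amino acid code {label!r}")
        return ONE_TO_THREE[label.upper()]
    cap = label.capitalize()
    if cap not in THREE_TO_ONE:
        raise ValueError(f"unknown amino acid label {label!r}")
    return cap


@dataclass(frozen=True)
class GeneticCodeTable:
    """Total map codon -> amino acid (3-letter) or STOP over all 64 codons."""

    mapping: dict[str, str] = field(compare=True)
    source: str = "built-in SGC"

    def __post_init__(self) -> None:
        missing = set(all_codons()) - set(self.mapping)
        if missing:
            raise ValueError(f"code table missing codons: {sorted(missing)}")
        extra = set(self.mapping) - set(all_codons())
        if extra:
            raise ValueError(f"code table has invalid codons: {sorted(extra)}")

    def translate(self, codon: str) -> str:
        return self.mapping[codon]

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, a in self.mapping.items() if a == STOP)

    @property
    def amino_acids(self) -> frozenset[str]:
        return frozenset(a for a in self.mapping.values() if a != STOP)

    def codons_of(self, amino_acid: str) -> frozenset[str]:
        aa = normalize_label(amino_acid)
        return frozenset(c for c, a in self.mapping.items() if a == aa)


def standard_code() -> GeneticCodeTable:
    """The built-in standard genetic code (20 amino acids, 3 stops)."""
    text = resources.files("aars_symmetry.data").joinpath("standard_code.tsv").read_text()
    return _parse_code_table(text.splitlines(), source="built-in SGC")


def load_code_table(path: str | Path) -> GeneticCodeTable:
    """Load and validate a 64-row ``codon<TAB>label`` TSV code table."""
    path = Path(path)
    return _parse_code_table(path.read_text().splitlines(), source=str(path))


def _parse_code_table(lines: Iterable[str], source: str) -> GeneticCodeTable:
    mapping: dict[str, str] = {}
    errors: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            errors.append(f"row {lineno}: expected 'codon<TAB>label', got {raw!r}")
            continue
        codon, label = parts[0].strip().upper(), parts[1].strip()
        if codon in mapping:
            errors.append(f"row {lineno}: duplicate codon {codon}")
            continue
        if len(codon) != 3 or any(b not in RNA_BASES for b in codon):
            errors.append(f"row {lineno}: invalid codon {codon!r}")
            continue
        try:
            mapping[codon] = normalize_label(label)
        except ValueError as exc:
            errors.append(f"row {lineno}: {exc}")
    missing = sorted(set(all_codons()) - set(mapping))
    if missing:
        errors.append(f"missing codons: {', '.join(missing)}")
    if errors:
        raise ValueError(f"invalid code table {source!r}: " + "; ".join(errors))
    return GeneticCodeTable(mapping=mapping, source=source)


@dataclass(frozen=True)
class PatternSet:
    """All codons matching a length-3 pattern over {R, Y, N, A, C, G, U}."""

    pattern: str
    members: frozenset[str]


def pattern_set(pattern: str) -> PatternSet:
    if len(pattern) != 3:
        raise ValueError(f"pattern must have length 3, got {pattern!r}")
    classes = []
    for ch in pattern.upper():
        if ch not in _PATTERN_CLASSES:
            raise ValueError(
                f"invalid pattern character {ch!r} in {pattern!r} "
                "(allowed: R, Y, N, A, C, G, U)"
            )
        classes.append(sorted(_PATTERN_CLASSES[ch]))
    members = frozenset("".join(p) for p in itertools.product(*classes))
    return PatternSet(pattern=pattern.upper(), members=members)


def ry_partition() -> list[PatternSet]:
    """The 8 pure R/Y patterns; they partition the 64 codons into 3-cubes."""
    return [
        pattern_set("".join(p))
        for p in itertools.product("RY", repeat=3)
    ]


def ry_pattern_of(codon: str) -> str:
    return "".join(ry_class(b) for b in codon)


_STAGE_PATTERNS = {
    "RNY": ("RNY",),
    "EXT1": ("RNY", "NYR", "YRN"),
    "EXT2": ("RNY", "YNY", "RNR"),
    "NNY": ("NNY",),
    "NNR": ("NNR",),
    "SGC": ("NNN",),
}


@dataclass(frozen=True)
class CodeStage:
    """A named evolutionary stage of the code: a codon set plus accounting."""

    name: str
    codons: frozenset[str]
    amino_acids: frozenset[str]
    stop_codons: frozenset[str]
    complement: frozenset[str]
    table: GeneticCodeTable = field(compare=False)

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def n_amino_acids(self) -> int:
        return len(self.amino_acids)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "codons": sorted(self.codons),
            "amino_acids": sorted(self.amino_acids),
            "stop_codons": sorted(self.stop_codons),
            "complement": sorted(self.complement),
            "table_source": self.table.source,
        }


def build_stage(name: str, table: GeneticCodeTable | None = None) -> CodeStage:
    name = name.upper()
    if name not in _STAGE_PATTERNS:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGE_NAMES}")
    if table is None:
        table = standard_code()
    codons: frozenset[str] = frozenset().union(
        *(pattern_set(p).members for p in _STAGE_PATTERNS[name])
    )
    aas, _ = amino_acids_of(codons, table)
    return CodeStage(
        name=name,
        codons=codons,
        amino_acids=aas,
        stop_codons=codons & table.stop_codons,
        complement=frozenset(all_codons()) - codons,
        table=table,
    )


def amino_acids_of(codons: Iterable[str], table: GeneticCodeTable) -> tuple[frozenset[str], int]:
    """Distinct amino acids coded by `codons`; stops counted separately."""
    labels = [table.translate(c) for c in codons]
    return frozenset(a for a in labels if a != STOP), sum(a == STOP for a in labels)


def new_amino_acids(
    codons: Iterable[str], baseline: Iterable[str], table: GeneticCodeTable
) -> frozenset[str]:
    """Amino acids coded by `codons` but by no codon of `baseline`."""
    aas, _ = amino_acids_of(codons, table)
    base_aas, _ = amino_acids_of(baseline, table)
    return aas - base_aas


@dataclass(frozen=True)
class DuplicationReport:
    """Amino-acid accounting of a stage's complement.

    `duplicated` are complement amino acids already coded inside the stage;
    `new_in_complement` first appear in the complement.  Together they
    partition the complement's amino-acid set.
    """

    stage: str
    duplicated: frozenset[str]
    new_in_complement: frozenset[str]
    complement_stop_count: int

    @property
    def complement_amino_acids(self) -> frozenset[str]:
        return self.duplicated | self.new_in_complement


def duplication_report(stage: CodeStage, table: GeneticCodeTable | None = None) -> DuplicationReport:
    table = table or stage.table
    comp_aas, comp_stops = amino_acids_of(stage.complement, table)
    stage_aas, _ = amino_acids_of(stage.codons, table)
    return DuplicationReport(
        stage=stage.name,
        duplicated=comp_aas & stage_aas,
        new_in_complement=comp_aas - stage_aas,
        complement_stop_count=comp_stops,
    )


def degeneracy_profile(table: GeneticCodeTable) -> dict[str, int]:
    """Codon count per amino acid (stops excluded); sums to 64 - #stops."""
    profile: dict[str, int] = {}
    for codon in all_codons():
        label = table.translate(codon)
        if label != STOP:
            profile[label] = profile.get(label, 0) + 1
    return profile
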