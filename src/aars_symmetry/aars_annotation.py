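"""Aminoacyl-tRNA synthetase class assignments and codon colorings.

Each of the 20 canonical amino acids is charged by a synthetase of
structural Class I or Class II, subdivided into subclasses a-c.  Lysine
is the single exception: LysRS exists in both a class I and a class II
form, so its class is resolved by an explicit convention.  A *coloring*
paints each codon of a set with the class of its amino acid (stop codons
get their own STOP color), which is the object the symmetry machinery
acts on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .code_models import AMINO_ACIDS_3, STOP, GeneticCodeTable, CodeStage, normalize_label

CLASS_I = "I"
CLASS_II = "II"
BOTH = "BOTH"
AMBIGUOUS = "AMBIGUOUS"

LYS_CONVENTIONS = ("class_I", "class_II", "ambiguous")

# Synthetases for non-canonical amino acids (O-phosphoserine, pyrrolysine);
# admitted only in extended mode since their amino acids are outside the SGC.
EXTENDED_RECORDS = {"Sep": (CLASS_II, "c"), "Pyl": (CLASS_II, "c")}


@dataclass(frozen=True)
class AarsRecord:
    amino_acid: str
    aars_class: str   # I, II or BOTH
    subclass: str     # a, b or c
    notes: str = ""


@dataclass(frozen=True)
class AarsClassification:
    """Class/subclass record for each of the 20 amino acids."""

    records: dict[str, AarsRecord] = field(compare=True)
    source: str = "built-in"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS_3) - set(self.records)
        if missing:
            raise ValueError(f"classification missing amino acids: {sorted(missing)}")
        for aa, rec in self.records.items():
            if rec.aars_class == BOTH and aa != "Lys":
                raise ValueError(f"only Lys may carry class BOTH, not {aa}")

    def classify(self, amino_acid: str, lys_convention: str = "ambiguous") -> tuple[str, str]:
        """Resolved (class, subclass) for one amino acid."""
        if lys_convention not in LYS_CONVENTIONS:
            raise ValueError(
                f"lys_convention must be one of {LYS_CONVENTIONS}, got {lys_convention!r}"
            )
        aa = normalize_label(amino_acid)
        if aa == STOP:
            raise ValueError("STOP is not an amino acid")
        rec = self.records[aa]
        if rec.aars_class != BOTH:
            return rec.aars_class, rec.subclass
        resolved = {"class_I": CLASS_I, "class_II": CLASS_II, "ambiguous": BOTH}[lys_convention]
        return resolved, rec.subclass

    def class_members(self, aars_class: str, lys_convention: str = "class_II") -> frozenset[str]:
        return frozenset(
            aa for aa in self.records
            if self.classify(aa, lys_convention)[0] == aars_class
        )


def default_classification() -> AarsClassification:
    text = resources.files("aars_symmetry.data").joinpath("aars_classes.tsv").read_text()
    return _parse_classification(text.splitlines(), source="built-in")


def load_classification(path: str | Path) -> AarsClassification:
    path = Path(path)
    return _parse_classification(path.read_text().splitlines(), source=str(path))


def _parse_classification(lines: Iterable[str], source: str, extended: bool = False) -> AarsClassification:
    records: dict[str, AarsRecord] = {}
    errors: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            errors.append(f"row {lineno}: expected 'amino_acid<TAB>class<TAB>subclass'")
            continue
        label, cls, sub = parts[0].strip(), parts[1].strip(), parts[2].strip()
        if label in EXTENDED_RECORDS and not extended:
            errors.append(
                f"row {lineno}: non-canonical amino acid {label!r} "
                "(enable extended mode to admit it)"
            )
            continue
        try:
            aa = normalize_label(label)
        except ValueError as exc:
            errors.append(f"row {lineno}: {exc}")
            continue
        if cls not in (CLASS_I, CLASS_II, BOTH):
            errors.append(f"row {lineno}: invalid class {cls!r}")
            continue
        if sub not in ("a", "b", "c"):
            errors.append(f"row {lineno}: invalid subclass {sub!r}")
            continue
        if aa in records:
            errors.append(f"row {lineno}: duplicate amino acid {aa}")
            continue
        notes = parts[3].strip() if len(parts) > 3 else ""
        records[aa] = AarsRecord(aa, cls, sub, notes)
    if errors:
        raise ValueError(f"invalid classification {source!r}: " + "; ".join(errors))
    return AarsClassification(records=records, source=source)


@dataclass(frozen=True)
class ClassCounts:
    n_class_I: int
    n_class_II: int
    n_ambiguous: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_class_I, self.n_class_II, self.n_ambiguous)


def class_counts(
    stage: CodeStage,
    classification: AarsClassification | None = None,
    lys_convention: str = "ambiguous",
) -> ClassCounts:
    """Class I / II / ambiguous counts over the *amino acids* of a stage."""
    classification = classification or default_classification()
    tally = {CLASS_I: 0, CLASS_II: 0, BOTH: 0}
    for aa in stage.amino_acids:
        cls, _ = classification.classify(aa, lys_convention)
        tally[cls] += 1
    return ClassCounts(tally[CLASS_I], tally[CLASS_II], tally[BOTH])


@dataclass(frozen=True)
class Coloring:
    """Codon-level class coloring of a codon set.

    Colors are I, II, STOP or AMBIGUOUS; the mapping is total on its
    codon set and depends only on the set, the code table, the
    classification and the Lys convention (never on input order).
    """

    colors: dict[str, str] = field(compare=True)
    provenance: dict = field(compare=False, default_factory=dict)

    @property
    def codons(self) -> frozenset[str]:
        return frozenset(self.colors)

    def color_class(self, color: str) -> frozenset[str]:
        return frozenset(c for c, col in self.colors.items() if col == color)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for col in self.colors.values():
            out[col] = out.get(col, 0) + 1
        return out


def color_codons(
    codons: Iterable[str],
    table: GeneticCodeTable,
    classification: AarsClassification | None = None,
    lys_convention: str = "class_II",
) -> Coloring:
    """Color every codon by the synthetase class of its amino acid."""
    classification = classification or default_classification()
    colors: dict[str, str] = {}
    for codon in sorted(set(codons)):
        label = table.translate(codon)
        if label == STOP:
            colors[codon] = STOP
        else:
            cls, _ = classification.classify(label, lys_convention)
            colors[codon] = AMBIGUOUS if cls == BOTH else cls
    return Coloring(
        colors=colors,
        provenance={
            "table": table.source,
            "classification": classification.source,
            "lys_convention": lys_convention,
        },
    )
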