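"""Run configuration, validation and the one-shot report bundle.

``run_full_analysis`` ties the pipeline together: for every requested
stage it writes ``<out>/<stage>/{stage.json, graph.graphml, layout.csv,
symmetry.json}`` plus a per-stage summary row in ``<out>/summary.csv``
and run metadata (full config, config hash, version) in
``<out>/run_meta.json``.  A rerun with the same config produces a
byte-identical bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .aars_annotation import (
    LYS_CONVENTIONS,
    class_counts,
    color_codons,
    default_classification,
    load_classification,
)
from .code_models import (
    STAGE_NAMES,
    build_stage,
    duplication_report,
    load_code_table,
    standard_code,
)
from .codon_algebra import SCHEMES
from .hypercube_geometry import (
    annotate_graph,
    build_graph,
    export_graphml,
    export_layout,
    layout_coordinates,
    subspace_report,
)
from .symmetry_analysis import mirror_symmetry_report


@dataclass(frozen=True)
class RunConfig:
    scheme: str = "A"
    lys_convention: str = "class_II"
    universe: str = "full"
    stages: tuple[str, ...] = ("RNY", "EXT1", "EXT2", "SGC")
    out_dir: str = "out"
    seed: int = 0
    code_table_path: str | None = None
    classification_path: str | None = None

    def validate(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown encoding scheme {self.scheme!r}")
        if self.lys_convention not in LYS_CONVENTIONS:
            raise ValueError(f"unknown lys convention {self.lys_convention!r}")
        if self.universe not in ("full", "codon-structured"):
            raise ValueError(f"unknown symmetry universe {self.universe!r}")
        bad = [s for s in self.stages if s.upper() not in STAGE_NAMES]
        if bad:
            raise ValueError(f"unknown stages: {bad}")

    def hash(self) -> str:
        """Hash of the analytic configuration (output location excluded):
        equal hashes imply byte-identical analytic content."""
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_inputs(
    code_table_path: str | None = None, classification_path: str | None = None
) -> ValidationReport:
    """Check input resources; collects every violation rather than the first."""
    report = ValidationReport()
    try:
        table = load_code_table(code_table_path) if code_table_path else standard_code()
        if len(table.stop_codons) != 3:
            report.violations.append(
                f"expected 3 stop codons, found {len(table.stop_codons)}"
            )
    except ValueError as exc:
        report.violations.append(str(exc))
    try:
        if classification_path:
            load_classification(classification_path)
        else:
            default_classification()
    except ValueError as exc:
        report.violations.append(str(exc))
    return report


def run_full_analysis(config: RunConfig) -> dict[str, dict]:
    """Run stages, geometry and symmetry for every configured stage and
    write the report bundle.  Returns the per-stage summaries."""
    config.validate()
    table = load_code_table(config.code_table_path) if config.code_table_path else standard_code()
    classification = (
        load_classification(config.classification_path)
        if config.classification_path
        else default_classification()
    )
    scheme = SCHEMES[config.scheme]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, dict] = {}
    for name in config.stages:
        stage = build_stage(name.upper(), table)
        stage_dir = out / stage.name
        stage_dir.mkdir(exist_ok=True)

        dup = duplication_report(stage, table)
        sub = subspace_report(stage.codons, scheme)
        stage_payload = stage.to_dict()
        stage_payload.update(
            {
                "duplicated_in_complement": sorted(dup.duplicated),
                "new_in_complement": sorted(dup.new_in_complement),
                "subspace": {
                    "is_affine": sub.is_affine,
                    "dimension": sub.dimension,
                    "is_coordinate_aligned": sub.is_coordinate_aligned,
                },
                "config_hash": config.hash(),
                "version": __version__,
            }
        )
        (stage_dir / "stage.json").write_text(
            json.dumps(stage_payload, indent=2, sort_keys=True) + "\n"
        )

        coloring = color_codons(stage.codons, table, classification, config.lys_convention)
        graph = build_graph(stage.codons, scheme)
        annotate_graph(graph, table, coloring)
        export_graphml(graph, stage_dir / "graph.graphml")
        export_layout(layout_coordinates(graph), stage_dir / "layout.csv")

        sym = mirror_symmetry_report(
            stage,
            table,
            classification,
            lys_convention=config.lys_convention,
            universe=config.universe,
            scheme=scheme,
        )
        (stage_dir / "symmetry.json").write_text(sym.to_json() + "\n")

        counts = class_counts(stage, classification, config.lys_convention)
        summaries[stage.name] = {
            "stage": stage.name,
            "n_codons": stage.n_codons,
            "n_amino_acids": stage.n_amino_acids,
            "n_stop_codons": len(stage.stop_codons),
            "n_class_I_aa": counts.n_class_I,
            "n_class_II_aa": counts.n_class_II,
            "n_ambiguous_aa": counts.n_ambiguous,
            "n_edges": graph.number_of_edges(),
            "stabilizer_order": sym.stabilizer_order,
            "color_preserving_order": sym.color_preserving_order,
            "class_swap_count": sym.class_swap_count,
        }

    header = list(next(iter(summaries.values())).keys())
    lines = [",".join(header)]
    for name in config.stages:
        row = summaries[name.upper()]
        lines.append(",".join(str(row[h]) for h in header))
    (out / "summary.csv").write_text("\n".join(lines) + "\n")
    meta = {"config": asdict(config), "config_hash": config.hash(), "version": __version__}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return summaries
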