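"""Tabular model archives and result exports.

The native on-disk model format is a directory of SBtab-flavoured TSV
files, one per component collection, plus a JSON manifest. Each table opens
with a ``!!SBtab`` declaration line and a ``!``-prefixed header row:

    !!SBtab TableID='enzyme' TableType='rbakit:enzyme' SBtabVersion='1.0'
    !ID	!Composition	!ForwardEfficiency	!BackwardEfficiency
    uptake_enzyme	uptake_protein:1.0	p_uptake_enzyme__forward

Compositions and stoichiometries are ``id:coefficient`` lists joined with
``;``. Parameter functions live in ``parameters.tsv`` under generated names
and are serialized in the grammar of :mod:`rbakit.parameters`
(``michaelis_menten(vmax=2.0,km=0.1,arg=glc_ext)``). Floats are written with
``repr`` (shortest round-trip form), so one read/write cycle reproduces an
archive byte for byte.

Result exports: tidy CSV or SBtab for solution states and analysis tables,
flat reaction-to-flux JSON for Escher maps, and a two-column mass-share TSV
for Proteomaps.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from .analysis import (
    EnsembleResult,
    ParetoFront,
    ScreenResult,
    SensitivityReport,
    VariabilityResult,
)
from .model import (
    Compartment,
    Enzyme,
    Macromolecule,
    Medium,
    Metabolite,
    Process,
    RBAModel,
    Reaction,
    Target,
    validate_model,
)
from .parameters import ParameterFunction, parse_parameter, serialize_parameter
from .solve import OPTIMAL, SolutionState

__all__ = [
    "ModelArchiveError",
    "write_model",
    "read_model",
    "export_results",
    "export_escher_flux",
    "export_proteomaps",
]

FORMAT_NAME = "rbakit-model"
FORMAT_VERSION = 1

_TABLE_FILES = {
    "compartment": "compartments.tsv",
    "metabolite": "metabolites.tsv",
    "macromolecule": "macromolecules.tsv",
    "reaction": "reactions.tsv",
    "enzyme": "enzymes.tsv",
    "process": "processes.tsv",
    "target": "targets.tsv",
    "parameter": "parameters.tsv",
}


class ModelArchiveError(ValueError):
    """A model archive is malformed; the message carries file/cell context."""


def _fmt(value: float) -> str:
    return repr(float(value))


def _join_map(mapping: Mapping[str, float]) -> str:
    return ";".join(f"{key}:{_fmt(value)}" for key, value in mapping.items())


def _split_map(text: str, where: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not text:
        return out
    for item in text.split(";"):
        if ":" not in item:
            raise ModelArchiveError(f"{where}: expected 'id:coefficient', got {item!r}")
        key, _, raw = item.partition(":")
        try:
            out[key] = float(raw)
        except ValueError:
            raise ModelArchiveError(f"{where}: bad coefficient {raw!r} for {key!r}") from None
    return out


def _write_table(path: Path, table_id: str, columns: list[str], rows: list[list[str]]) -> None:
    lines = [
        f"!!SBtab TableID='{table_id}' TableType='rbakit:{table_id}' SBtabVersion='1.0'",
        "\t".join(f"!{c}" for c in columns),
    ]
    for row in rows:
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_table(path: Path, table_id: str) -> tuple[list[str], list[list[str]]]:
    if not path.exists():
        raise ModelArchiveError(f"missing table file {path}")
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("!!SBtab"):
        raise ModelArchiveError(f"{path}:1: expected an '!!SBtab' declaration line")
    if f"TableID='{table_id}'" not in lines[0]:
        raise ModelArchiveError(f"{path}:1: expected TableID='{table_id}'")
    if len(lines) < 2:
        raise ModelArchiveError(f"{path}: missing header row")
    header = [c.lstrip("!") for c in lines[1].split("\t")]
    rows = []
    for i, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ModelArchiveError(
                f"{path}:{i}: expected {len(header)} cells, found {len(cells)}"
            )
        rows.append(cells)
    return header, rows


class _ParameterRegistry:
    """Assigns stable names to parameter functions while writing an archive."""

    def __init__(self) -> None:
        self.formulas: dict[str, str] = {}

    def register(self, owner: str, role: str, fn: ParameterFunction | None) -> str:
        if fn is None:
            return ""
        name = f"p_{owner}__{role}"
        self.formulas[name] = serialize_parameter(fn)
        return name


def write_model(model: RBAModel, path: str | Path) -> Path:
    """Write ``model`` as a directory of SBtab TSV tables plus a manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    params = _ParameterRegistry()

    _write_table(
        root / "compartments.tsv",
        "compartment",
        ["ID", "DensityCapacity"],
        [
            [c.id, params.register(c.id, "density_capacity", c.density_capacity)]
            for c in model.compartments.values()
        ],
    )
    _write_table(
        root / "metabolites.tsv",
        "metabolite",
        ["ID", "IsExternal"],
        [[m.id, "true" if m.external else "false"] for m in model.metabolites.values()],
    )
    _write_table(
        root / "macromolecules.tsv",
        "macromolecule",
        ["ID", "Weight", "Compartment", "PrecursorCost", "ProducingProcess"],
        [
            [
                m.id,
                _fmt(m.weight),
                m.compartment,
                _join_map(m.precursor_cost),
                m.producing_process or "",
            ]
            for m in model.macromolecules.values()
        ],
    )
    _write_table(
        root / "reactions.tsv",
        "reaction",
        ["ID", "Stoichiometry", "IsReversible", "Enzyme"],
        [
            [
                r.id,
                _join_map(r.stoichiometry),
                "true" if r.reversible else "false",
                r.enzyme or "",
            ]
            for r in model.reactions.values()
        ],
    )
    _write_table(
        root / "enzymes.tsv",
        "enzyme",
        ["ID", "Composition", "ForwardEfficiency", "BackwardEfficiency"],
        [
            [
                e.id,
                _join_map(e.composition),
                params.register(e.id, "forward", e.forward_efficiency),
                params.register(e.id, "backward", e.backward_efficiency),
            ]
            for e in model.enzymes.values()
        ],
    )
    _write_table(
        root / "processes.tsv",
        "process",
        ["ID", "MachineComposition", "Efficiency", "Products", "DemandPerUnit"],
        [
            [
                p.id,
                _join_map(p.machine_composition),
                params.register(p.id, "efficiency", p.efficiency),
                ";".join(sorted(p.products)),
                _join_map(p.demand_per_unit),
            ]
            for p in model.processes.values()
        ],
    )
    _write_table(
        root / "targets.tsv",
        "target",
        ["ID", "Kind", "Subject", "Value"],
        [
            [t.id, t.kind, t.subject, params.register(t.id, "value", t.value)]
            for t in model.targets.values()
        ],
    )
    _write_table(
        root / "parameters.tsv",
        "parameter",
        ["ID", "Formula"],
        [[name, formula] for name, formula in sorted(params.formulas.items())],
    )
    manifest = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "name": model.name,
        "tables": dict(_TABLE_FILES),
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return root


def _require(header: list[str], column: str, path: Path) -> int:
    try:
        return header.index(column)
    except ValueError:
        raise ModelArchiveError(f"{path}: missing column !{column}") from None


def read_model(path: str | Path) -> RBAModel:
    """Read a model archive; all validation diagnostics are raised as errors."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise ModelArchiveError(f"{root}: not a model archive (no manifest.json)")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("format") != FORMAT_NAME:
        raise ModelArchiveError(f"{manifest_path}: unknown format {manifest.get('format')!r}")
    if manifest.get("version") != FORMAT_VERSION:
        raise ModelArchiveError(f"{manifest_path}: unsupported version {manifest.get('version')!r}")

    def load(table: str) -> tuple[list[str], list[list[str]], Path]:
        file_path = root / manifest["tables"][table]
        header, rows = _read_table(file_path, table)
        return header, rows, file_path

    header, rows, ppath = load("parameter")
    i_id, i_f = _require(header, "ID", ppath), _require(header, "Formula", ppath)
    parameters: dict[str, ParameterFunction] = {}
    for row in rows:
        try:
            parameters[row[i_id]] = parse_parameter(row[i_f])
        except ValueError as exc:
            raise ModelArchiveError(f"{ppath}: parameter {row[i_id]!r}: {exc}") from None

    def param(name: str, where: str) -> ParameterFunction | None:
        if not name:
            return None
        if name not in parameters:
            raise ModelArchiveError(f"{where}: dangling parameter reference {name!r}")
        return parameters[name]

    header, rows, fpath = load("compartment")
    i_id = _require(header, "ID", fpath)
    i_dc = _require(header, "DensityCapacity", fpath)
    compartments = [
        Compartment(row[i_id], param(row[i_dc], f"{fpath}: compartment {row[i_id]!r}"))
        for row in rows
    ]

    header, rows, fpath = load("metabolite")
    i_id, i_ext = _require(header, "ID", fpath), _require(header, "IsExternal", fpath)
    metabolites = [Metabolite(row[i_id], row[i_ext] == "true") for row in rows]

    header, rows, fpath = load("macromolecule")
    idx = {c: _require(header, c, fpath) for c in
           ("ID", "Weight", "Compartment", "PrecursorCost", "ProducingProcess")}
    macromolecules = []
    for row in rows:
        where = f"{fpath}: macromolecule {row[idx['ID']]!r}"
        macromolecules.append(
            Macromolecule(
                row[idx["ID"]],
                weight=float(row[idx["Weight"]]),
                compartment=row[idx["Compartment"]],
                precursor_cost=_split_map(row[idx["PrecursorCost"]], where),
                producing_process=row[idx["ProducingProcess"]] or None,
            )
        )

    header, rows, fpath = load("reaction")
    idx = {c: _require(header, c, fpath) for c in ("ID", "Stoichiometry", "IsReversible", "Enzyme")}
    reactions = []
    for row in rows:
        where = f"{fpath}: reaction {row[idx['ID']]!r}"
        reactions.append(
            Reaction(
                row[idx["ID"]],
                stoichiometry=_split_map(row[idx["Stoichiometry"]], where),
                reversible=row[idx["IsReversible"]] == "true",
                enzyme=row[idx["Enzyme"]] or None,
            )
        )

    header, rows, fpath = load("enzyme")
    idx = {c: _require(header, c, fpath) for c in
           ("ID", "Composition", "ForwardEfficiency", "BackwardEfficiency")}
    enzymes = []
    for row in rows:
        where = f"{fpath}: enzyme {row[idx['ID']]!r}"
        enzymes.append(
            Enzyme(
                row[idx["ID"]],
                composition=_split_map(row[idx["Composition"]], where),
                forward_efficiency=param(row[idx["ForwardEfficiency"]], where),
                backward_efficiency=param(row[idx["BackwardEfficiency"]], where),
            )
        )

    header, rows, fpath = load("process")
    idx = {c: _require(header, c, fpath) for c in
           ("ID", "MachineComposition", "Efficiency", "Products", "DemandPerUnit")}
    processes = []
    for row in rows:
        where = f"{fpath}: process {row[idx['ID']]!r}"
        products = frozenset(p for p in row[idx["Products"]].split(";") if p)
        processes.append(
            Process(
                row[idx["ID"]],
                machine_composition=_split_map(row[idx["MachineComposition"]], where),
                efficiency=param(row[idx["Efficiency"]], where),
                products=products,
                demand_per_unit=_split_map(row[idx["DemandPerUnit"]], where),
            )
        )

    header, rows, fpath = load("target")
    idx = {c: _require(header, c, fpath) for c in ("ID", "Kind", "Subject", "Value")}
    targets = []
    for row in rows:
        where = f"{fpath}: target {row[idx['ID']]!r}"
        targets.append(
            Target(row[idx["ID"]], row[idx["Kind"]], row[idx["Subject"]],
                   param(row[idx["Value"]], where))
        )

    model = RBAModel(
        name=manifest.get("name", root.name),
        compartments=compartments,
        metabolites=metabolites,
        macromolecules=macromolecules,
        reactions=reactions,
        enzymes=enzymes,
        processes=processes,
        targets=targets,
    )
    diagnostics = validate_model(model)
    if diagnostics:
        raise ModelArchiveError(
            f"{root}: invalid model: " + "; ".join(str(d) for d in diagnostics)
        )
    return model


# ---------------------------------------------------------------------------
# Result exports
# ---------------------------------------------------------------------------


def _solution_frames(solution: SolutionState) -> dict[str, pd.DataFrame]:
    return {
        "fluxes": pd.DataFrame(
            {"id": list(solution.fluxes), "value": list(solution.fluxes.values())}
        ),
        "enzyme_concentrations": pd.DataFrame(
            {
                "id": list(solution.enzyme_concentrations),
                "value": list(solution.enzyme_concentrations.values()),
            }
        ),
        "machine_concentrations": pd.DataFrame(
            {
                "id": list(solution.machine_concentrations),
                "value": list(solution.machine_concentrations.values()),
            }
        ),
    }


def _result_frames(result) -> dict[str, pd.DataFrame]:
    if isinstance(result, SolutionState):
        return _solution_frames(result)
    if isinstance(result, VariabilityResult):
        return {"variability": result.table}
    if isinstance(result, (ScreenResult,)):
        return {"screen": result.table}
    if isinstance(result, EnsembleResult):
        return {"ensemble": result.table}
    if isinstance(result, SensitivityReport):
        return {"sensitivities": result.table}
    if isinstance(result, ParetoFront):
        return {"pareto": result.table}
    if isinstance(result, pd.DataFrame):
        return {"table": result}
    raise TypeError(f"cannot export result of type {type(result).__name__}")


def export_results(result, path: str | Path, format: str = "csv") -> Path:
    """Export a solution or analysis result as one tidy CSV or SBtab file.

    Deterministic: fixed section order, fixed column order, floats at full
    (shortest round-trip) precision.
    """
    path = Path(path)
    frames = _result_frames(result)

    def full_precision(frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].map(_fmt)
        return out

    if format == "csv":
        if len(frames) == 1:
            frame = next(iter(frames.values()))
            full_precision(frame).to_csv(path, index=False)
        else:
            combined = pd.concat(
                [frame.assign(section=name) for name, frame in frames.items()],
                ignore_index=True,
            )
            combined = combined[["section"] + [c for c in combined.columns if c != "section"]]
            full_precision(combined).to_csv(path, index=False)
        return path
    if format == "sbtab":
        chunks = []
        for name, frame in frames.items():
            lines = [
                f"!!SBtab TableID='{name}' TableType='rbakit:result' SBtabVersion='1.0'",
                "\t".join(f"!{c}" for c in frame.columns),
            ]
            for _, row in frame.iterrows():
                lines.append(
                    "\t".join(_fmt(v) if isinstance(v, float) else str(v) for v in row)
                )
            chunks.append("\n".join(lines))
        path.write_text("\n\n".join(chunks) + "\n")
        return path
    raise ValueError(f"unknown export format {format!r} (expected 'csv' or 'sbtab')")


def export_escher_flux(solution: SolutionState, path: str | Path) -> Path:
    """Write the Escher reaction-data format: a flat ``{reaction: flux}`` JSON.

    Zero-flux reactions are included so the map renders completely.
    """
    if solution.status != OPTIMAL:
        raise ValueError(f"cannot export a non-optimal solution (status {solution.status!r})")
    path = Path(path)
    path.write_text(json.dumps(dict(solution.fluxes), indent=2, sort_keys=True) + "\n")
    return path


def export_proteomaps(
    solution: SolutionState, model: RBAModel, path: str | Path
) -> Path:
    """Write Proteomaps input: macromolecule id vs. proteome mass share (TSV).

    The mass of macromolecule i is ``weight_i`` times its total
    concentration — summed over the catalysts containing it
    (composition-weighted) plus any pinned target pools. Shares are
    normalized to sum to 1; zero-abundance macromolecules are omitted.
    """
    if solution.status != OPTIMAL:
        raise ValueError(f"cannot export a non-optimal solution (status {solution.status!r})")
    path = Path(path)
    medium = solution.medium if solution.medium is not None else Medium({})
    conc: dict[str, float] = {mid: 0.0 for mid in model.macromolecules}
    for enz in model.enzymes.values():
        level = solution.enzyme_concentrations.get(enz.id, 0.0)
        for mac, count in enz.composition.items():
            conc[mac] += count * level
    for proc in model.processes.values():
        level = solution.machine_concentrations.get(proc.id, 0.0)
        for mac, count in proc.machine_composition.items():
            conc[mac] += count * level
    catalyst_macs = model.catalyst_macromolecules()
    for tgt in model.targets.values():
        if tgt.kind.startswith("concentration") and tgt.subject in model.macromolecules:
            if tgt.subject not in catalyst_macs:
                conc[tgt.subject] += tgt.value(solution.mu, medium)
    masses = {
        mid: model.macromolecules[mid].weight * c for mid, c in conc.items() if c > 0.0
    }
    total = sum(masses.values())
    lines = []
    for mid, mass in masses.items():
        share = mass / total if total > 0 else 0.0
        lines.append(f"{mid}\t{_fmt(share)}")
    path.write_text("\n".join(lines) + "\n")
    return path
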