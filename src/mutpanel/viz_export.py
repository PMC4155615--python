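"""Panel exports and end-to-end pipeline orchestration.

The three interactive panels (structure-based alignment with colour-scheme
groups, typed contacts per column, property heatmap) are exported as plain
JSON data contracts: colour codes are group labels, values are raw numbers,
and per-cell details-on-demand records carry residue type, alignment
position, original sequence position and all computed parameters.
``run_pipeline`` chains structure cleanup, SASA, the contact network,
column profiling, the manual filter and the GA into one deterministic run.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .contact_graph import (
    CONTACT_TYPES,
    ContactEdge,
    ResidueGraph,
    centralities,
    residue_graph,
    structure_contacts,
)
from .family_align import (
    GAP,
    SCHEMES,
    Alignment,
    Mutation,
    PropertyRecord,
    call_mutations,
    column_profiles,
    load_alignment,
    manual_filter,
    map_alignment_to_structures,
    parse_active_sites,
    property_table,
)
from .ga_select import GAConfig, build_context, run_ga
from .sasa import atom_sasa, relative_accessibility
from .structure_io import Residue, Structure, annotate_atom_types, clean_set, read_pdb

__all__ = [
    "PanelBundle",
    "PipelineConfig",
    "PipelineResult",
    "PipelineError",
    "export_alignment_panel",
    "contacts_by_column",
    "export_contacts_panel",
    "export_properties_panel",
    "build_details",
    "validate_bundle",
    "run_pipeline",
]

_MEASURES = ("acc", "deg", "bet", "clo")


@dataclass
class PanelBundle:
    alignment_panel: dict
    contacts_panel: dict
    properties_panel: dict
    details: dict


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def export_alignment_panel(
    alignment: Alignment,
    scheme: str = "CINEMA",
    highlight_groups: set[str] | None = None,
) -> dict:
    """Alignment panel: residue, scheme group and highlight flag per cell.

    An empty/None filter highlights every residue cell; otherwise only
    cells whose group is in the filter are highlighted, the rest are
    attenuated.  Gap cells carry a null group and are never highlighted.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    sch = SCHEMES[scheme]
    known = {label for label, _ in sch.groups}
    filt = set(highlight_groups or [])
    unknown = filt - known
    if unknown:
        raise ValueError(f"unknown group(s) {sorted(unknown)} for scheme {scheme}")
    rows = []
    for rid, seq in alignment.rows:
        cells = []
        for aa in seq:
            if aa == GAP:
                cells.append({"aa": GAP, "group": None, "highlighted": False})
                continue
            group = sch.group_of(aa)
            highlighted = (not filt) or (group in filt)
            cells.append({"aa": aa, "group": group, "highlighted": highlighted})
        rows.append({"id": rid, "cells": cells})
    return {
        "panel": "alignment",
        "scheme": scheme,
        "highlight": sorted(filt),
        "n_columns": alignment.length,
        "rows": rows,
    }


def contacts_by_column(
    contacts: list[ContactEdge], column_of: Mapping[tuple, int]
) -> list[dict]:
    """Flatten typed contacts of the reference structure to column pairs.

    ``column_of`` maps residue keys (chain, number, icode) to 1-based
    alignment columns; contacts whose residues fall outside the mapping are
    skipped.
    """
    records = []
    for c in contacts:
        ci = column_of.get(c.residue_i.key)
        cj = column_of.get(c.residue_j.key)
        if ci is None or cj is None:
            continue
        lo, hi = sorted((ci, cj))
        for ctype in sorted(c.types):
            records.append(
                {
                    "column_i": lo,
                    "column_j": hi,
                    "type": ctype,
                    "distance": round(c.distance, 3),
                    "atom_i": c.atom_i.name if lo == ci else c.atom_j.name,
                    "atom_j": c.atom_j.name if lo == ci else c.atom_i.name,
                }
            )
    records.sort(key=lambda r: (r["column_i"], r["column_j"], r["type"]))
    return records


def export_contacts_panel(
    column_contacts: list[dict],
    mode: str = "all_types_one_column",
    column: int | None = None,
    contact_type: str | None = None,
) -> dict:
    """Contacts panel in one of its three selection modes."""
    modes = ("one_type_one_column", "all_types_one_column", "one_type_all_columns")
    if mode not in modes:
        raise ValueError(f"mode must be one of {modes}")
    if mode in ("one_type_one_column", "all_types_one_column") and column is None:
        raise ValueError(f"mode {mode!r} requires a column")
    if mode in ("one_type_one_column", "one_type_all_columns") and contact_type is None:
        raise ValueError(f"mode {mode!r} requires a contact type")
    if contact_type is not None and contact_type not in CONTACT_TYPES:
        raise ValueError(f"unknown contact type {contact_type!r}")

    def touches(rec, col):
        return rec["column_i"] == col or rec["column_j"] == col

    if mode == "one_type_one_column":
        selected = [
            r for r in column_contacts
            if touches(r, column) and r["type"] == contact_type
        ]
    elif mode == "all_types_one_column":
        selected = [r for r in column_contacts if touches(r, column)]
    else:
        selected = [r for r in column_contacts if r["type"] == contact_type]
    return {
        "panel": "contacts",
        "mode": mode,
        "column": column,
        "type": contact_type,
        "contacts": selected,
    }


def export_properties_panel(
    alignment: Alignment,
    properties: Mapping[str, Mapping[int, PropertyRecord]],
) -> dict:
    """Property heatmap: one raw-valued layer per measure, nulls for gaps."""
    layers: dict[str, Any] = {}
    row_ids = [rid for rid, _ in alignment.rows]
    for measure in _MEASURES:
        cells = []
        for rid, seq in alignment.rows:
            row_props = properties.get(rid, {})
            row_cells = []
            for col in range(1, alignment.length + 1):
                rec = row_props.get(col)
                row_cells.append(None if rec is None else getattr(rec, measure))
            cells.append(row_cells)
        flat = [v for row in cells for v in row if v is not None]
        layers[measure] = {
            "cells": cells,
            "min": min(flat) if flat else None,
            "max": max(flat) if flat else None,
        }
    return {
        "panel": "properties",
        "row_ids": row_ids,
        "n_columns": alignment.length,
        "layers": layers,
    }


def build_details(
    alignment: Alignment,
    properties: Mapping[str, Mapping[int, PropertyRecord]],
) -> dict:
    """Details-on-demand records per non-gap cell."""
    rows = []
    for rid, seq in alignment.rows:
        row_props = properties.get(rid, {})
        cells = []
        pos = 0
        for col, aa in enumerate(seq, start=1):
            if aa == GAP:
                cells.append(None)
                continue
            pos += 1
            rec = row_props.get(col)
            cells.append(
                {
                    "aa": aa,
                    "column": col,
                    "seq_pos": pos,
                    "acc": None if rec is None else rec.acc,
                    "deg": None if rec is None else rec.deg,
                    "bet": None if rec is None else rec.bet,
                    "clo": None if rec is None else rec.clo,
                }
            )
        rows.append({"id": rid, "cells": cells})
    return {"panel": "details", "rows": rows}


def validate_bundle(bundle: PanelBundle, alignment: Alignment) -> None:
    """Structural validation of the exported documents.

    Checks panel dimensions against the alignment, cell-by-cell agreement
    of residue identity between the alignment panel and the details
    records, layer min/max consistency, and contact record sanity.
    Raises ``ValueError`` on the first violation.
    """
    n_rows, n_cols = alignment.n_rows, alignment.length
    ap = bundle.alignment_panel
    if len(ap["rows"]) != n_rows:
        raise ValueError("alignment panel row count mismatch")
    for row, (rid, seq) in zip(ap["rows"], alignment.rows):
        if row["id"] != rid or len(row["cells"]) != n_cols:
            raise ValueError(f"alignment panel shape mismatch in row {row['id']}")
        for cell, aa in zip(row["cells"], seq):
            if cell["aa"] != aa:
                raise ValueError(f"alignment panel residue mismatch in row {rid}")
    pp = bundle.properties_panel
    for measure, layer in pp["layers"].items():
        if len(layer["cells"]) != n_rows or any(
            len(r) != n_cols for r in layer["cells"]
        ):
            raise ValueError(f"properties layer {measure} has wrong shape")
        flat = [v for row in layer["cells"] for v in row if v is not None]
        if flat and (layer["min"] != min(flat) or layer["max"] != max(flat)):
            raise ValueError(f"properties layer {measure} min/max inconsistent")
    det = bundle.details
    if len(det["rows"]) != n_rows:
        raise ValueError("details row count mismatch")
    for drow, arow, (rid, seq) in zip(det["rows"], ap["rows"], alignment.rows):
        for dcell, acell in zip(drow["cells"], arow["cells"]):
            if (dcell is None) != (acell["aa"] == GAP):
                raise ValueError(f"details/alignment gap disagreement in row {rid}")
            if dcell is not None and dcell["aa"] != acell["aa"]:
                raise ValueError(f"details/alignment residue mismatch in row {rid}")
    for rec in bundle.contacts_panel.get("contacts", []):
        if not (1 <= rec["column_i"] <= rec["column_j"] <= n_cols):
            raise ValueError("contact record column out of range")
        if rec["type"] not in CONTACT_TYPES:
            raise ValueError(f"contact record with unknown type {rec['type']!r}")


@dataclass
class PipelineConfig:
    """Inputs and knobs of one end-to-end run."""

    alignment_file: str
    mutant_id: str
    reference_id: str
    structure_files: dict[str, str]  # alignment row id -> PDB path
    active_sites_file: str | None = None
    scheme: str = "CINEMA"
    closeness: str = "inverse_sum"
    probe: float = 1.4
    sasa_points: int = 960
    max_edge_length: float = 8.0
    exclude_backbone_neighbors: bool = True
    keep_duplicates: bool = False
    require_complete: bool = True
    t_rare: float = 0.10
    t_very_rare: float = 0.02
    ga_n_positions: int | None = None  # default: min(22, #mutated columns)
    ga_population: int = 50
    ga_generations: int = 100
    ga_tournament_k: int = 3
    ga_crossover_rate: float = 0.9
    ga_mutation_rate: float = 0.05
    ga_clone_rate: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        base = path.parent

        def resolve(p):
            return str((base / p).resolve()) if p else p

        raw["alignment_file"] = resolve(raw["alignment_file"])
        raw["structure_files"] = {
            k: resolve(v) for k, v in raw.get("structure_files", {}).items()
        }
        if raw.get("active_sites_file"):
            raw["active_sites_file"] = resolve(raw["active_sites_file"])
        if raw.get("out_dir"):
            raw["out_dir"] = resolve(raw["out_dir"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    alignment: Alignment
    structures: dict[str, Structure]
    graphs: dict[str, ResidueGraph]
    properties: dict[str, dict[int, PropertyRecord]]
    profiles: list
    mutations: list[Mutation]
    manual_selection: list[Mutation]
    ga_literal: dict
    ga_corrected: dict
    bundle: PanelBundle
    manifest: dict = field(default_factory=dict)


def _mutation_record(m: Mutation) -> dict:
    return {
        "label": m.label,
        "column": m.column,
        "ref_aa": m.ref_aa,
        "mut_aa": m.mut_aa,
        "ref_seq_pos": m.ref_seq_pos,
        "mut_seq_pos": m.mut_seq_pos,
        "conservative": dict(sorted(m.conservative_by_scheme.items())),
        "rarity": m.rarity,
        "is_active_site": m.is_active_site,
        "contacts_active_site": m.contacts_active_site,
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; optionally write all exports to disk.

    Stage failures raise :class:`PipelineError` naming the stage.  Output
    documents are deterministic for a fixed config and seed (the manifest,
    which carries a timestamp, is written separately).
    """
    # --- structures -------------------------------------------------
    try:
        structures: dict[str, Structure] = {}
        for rid, pdb_path in sorted(config.structure_files.items()):
            cleaned = clean_set(
                read_pdb(pdb_path),
                keep_duplicates=config.keep_duplicates,
                require_complete=config.require_complete,
            )
            structures[rid] = annotate_atom_types(cleaned[0])
    except Exception as exc:
        raise PipelineError("structure_io", exc) from exc

    # --- solvent accessibility --------------------------------------
    try:
        for st in structures.values():
            relative_accessibility(
                atom_sasa(st, probe=config.probe, n_points=config.sasa_points)
            )
    except Exception as exc:
        raise PipelineError("sasa", exc) from exc

    # --- contact networks -------------------------------------------
    try:
        graphs: dict[str, ResidueGraph] = {}
        for rid, st in structures.items():
            contacts = structure_contacts(
                st,
                max_edge_length=config.max_edge_length,
                exclude_backbone_neighbors=config.exclude_backbone_neighbors,
                seed=config.seed,
            )
            rg = residue_graph(contacts, nodes=st.residues)
            graphs[rid] = centralities(rg, closeness=config.closeness)
    except Exception as exc:
        raise PipelineError("contact_graph", exc) from exc

    # --- alignment, profiles, manual selection ----------------------
    try:
        alignment = load_alignment(
            config.alignment_file, config.mutant_id, config.reference_id
        )
        column_maps = map_alignment_to_structures(alignment, structures)
        properties = {
            rid: property_table(column_maps[rid], graphs[rid])
            for rid in structures
        }
        active_sites = (
            parse_active_sites(config.active_sites_file)
            if config.active_sites_file
            else []
        )
        ref_id = config.reference_id
        profiles = column_profiles(
            alignment,
            properties,
            active_sites=active_sites,
            ref_graph=graphs.get(ref_id),
            ref_column_map=column_maps.get(ref_id),
        )
        mutations = call_mutations(alignment)
        manual = manual_filter(
            mutations, profiles,
            scheme=config.scheme,
            t_very_rare=config.t_very_rare, t_rare=config.t_rare,
        )
    except Exception as exc:
        raise PipelineError("family_align", exc) from exc

    # --- GA selection ------------------------------------------------
    try:
        n_mut = len({m.column for m in mutations})
        ga_docs = {}
        if n_mut:
            n_pos = config.ga_n_positions or min(22, n_mut)
            mut_by_col = {m.column: m for m in mutations}
            ctx = build_context(profiles, mutations)
            for mode in ("literal", "corrected"):
                ga_cfg = GAConfig(
                    n_positions=n_pos,
                    population_size=config.ga_population,
                    generations=config.ga_generations,
                    tournament_k=config.ga_tournament_k,
                    crossover_rate=config.ga_crossover_rate,
                    mutation_rate=config.ga_mutation_rate,
                    clone_rate=config.ga_clone_rate,
                    seed=config.seed,
                    fitness_mode=mode,
                )
                best = run_ga(ga_cfg, profiles, mutations, ctx=ctx)
                ga_docs[mode] = {
                    "mode": mode,
                    "n_positions": n_pos,
                    "seed": config.seed,
                    "fitness": best.fitness,
                    "genes": [
                        {
                            "column": col,
                            "label": mut_by_col[col].label,
                            "partial_fitness": best.partials[col],
                        }
                        for col in best.genes
                    ],
                }
        else:
            ga_docs = {
                "literal": {"mode": "literal", "genes": [], "fitness": 0.0},
                "corrected": {"mode": "corrected", "genes": [], "fitness": 0.0},
            }
    except Exception as exc:
        raise PipelineError("ga_select", exc) from exc

    # --- exports -----------------------------------------------------
    try:
        ref_map = column_maps.get(config.reference_id, {})
        column_of = {res.key: col for col, res in ref_map.items()}
        col_contacts = contacts_by_column(
            graphs[config.reference_id].contacts, column_of
        ) if config.reference_id in graphs else []
        bundle = PanelBundle(
            alignment_panel=export_alignment_panel(alignment, config.scheme),
            contacts_panel={
                "panel": "contacts",
                "mode": "all",
                "column": None,
                "type": None,
                "contacts": col_contacts,
            },
            properties_panel=export_properties_panel(alignment, properties),
            details=build_details(alignment, properties),
        )
        validate_bundle(bundle, alignment)
    except Exception as exc:
        raise PipelineError("viz_export", exc) from exc

    cfg_dict = asdict(config)
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_structures": len(structures),
        "n_mutations": len(mutations),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    result = PipelineResult(
        config=config,
        alignment=alignment,
        structures=structures,
        graphs=graphs,
        properties=properties,
        profiles=profiles,
        mutations=mutations,
        manual_selection=manual,
        ga_literal=ga_docs["literal"],
        ga_corrected=ga_docs["corrected"],
        bundle=bundle,
        manifest=manifest,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _dump(doc, path: Path) -> None:
    path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _dump(result.bundle.alignment_panel, out_dir / "alignment_panel.json")
    _dump(result.bundle.contacts_panel, out_dir / "contacts_panel.json")
    _dump(result.bundle.properties_panel, out_dir / "properties_panel.json")
    _dump(result.bundle.details, out_dir / "details.json")
    _dump(result.ga_literal, out_dir / "ga_literal.json")
    _dump(result.ga_corrected, out_dir / "ga_corrected.json")
    _dump(
        [_mutation_record(m) for m in result.mutations],
        out_dir / "mutations.json",
    )
    _dump(
        [_mutation_record(m) for m in result.manual_selection],
        out_dir / "manual_selection.json",
    )
    profile_rows = [
        {
            "column": p.column,
            "res_freq_mut": p.res_freq_mut,
            "acc_avg": p.acc_avg,
            "deg_avg": p.deg_avg,
            "bet_avg": p.bet_avg,
            "clo_avg": p.clo_avg,
            "is_active_site": p.is_active_site,
            "contacts_active_site": p.contacts_active_site,
        }
        for p in result.profiles
    ]
    _dump(profile_rows, out_dir / "profiles.json")
    _dump(result.manifest, out_dir / "manifest.json")
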