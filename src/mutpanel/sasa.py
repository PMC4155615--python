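"""Solvent accessible surface area.

Per-atom areas are computed by sphere sampling (Shrake–Rupley): each atom's
van der Waals sphere is inflated by the probe radius (water, 1.4 A by
default) and covered with a deterministic Fibonacci point lattice; the
accessible area is the sphere area times the fraction of points not buried
inside any neighbouring inflated sphere.  Per-residue relative
accessibility divides the summed atomic area by the residue's maximum area
in an extended Ala-X-Ala tripeptide, expressed as a percentage (values
above 100% are reported as computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import atom_data
from .structure_io import Atom, Residue, Structure

__all__ = ["SasaResult", "sphere_points", "atom_sasa", "relative_accessibility"]

DEFAULT_PROBE = 1.4  # A, water
DEFAULT_POINTS = 960


@dataclass
class SasaResult:
    probe_radius: float
    n_points: int
    per_atom: dict[Atom, float] = field(default_factory=dict)
    per_residue_abs: dict[Residue, float] = field(default_factory=dict)
    per_residue_rel: dict[Residue, float] = field(default_factory=dict)


def sphere_points(n: int) -> np.ndarray:
    """Deterministic Fibonacci lattice of ``n`` points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def atom_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> SasaResult:
    """Compute per-atom and per-residue absolute SASA for one chain."""
    if probe < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for usable quadrature")
    atoms = structure.atoms
    if not atoms:
        raise ValueError(f"{structure.source_id}: structure has no atoms")
    for at in atoms:
        if at.vdw_radius <= 0:
            raise ValueError(
                f"atom {at.name} has no vdW radius; run annotate_atom_types first"
            )
    coords = np.array([at.coords for at in atoms])
    radii = np.array([at.vdw_radius for at in atoms]) + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    result = SasaResult(probe_radius=probe, n_points=n_points)
    max_r = radii.max()
    candidates = tree.query_ball_point(coords, radii + max_r)
    for i, at in enumerate(atoms):
        cand = np.array([j for j in candidates[i] if j != i], dtype=int)
        if cand.size:
            d = np.linalg.norm(coords[cand] - coords[i], axis=1)
            cand = cand[d < radii[i] + radii[cand]]
        if cand.size:
            pts = coords[i] + radii[i] * unit
            d2 = ((pts[:, None, :] - coords[cand][None, :, :]) ** 2).sum(-1)
            buried = (d2 < (radii[cand] ** 2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        result.per_atom[at] = exposed_frac * 4.0 * np.pi * radii[i] ** 2
    for res in structure.residues:
        area = float(sum(result.per_atom[a] for a in res.atoms))
        result.per_residue_abs[res] = area
        res.sasa_abs = area
    return result


def relative_accessibility(
    result: SasaResult,
    ref_table: dict[str, float] | None = None,
) -> SasaResult:
    """Fill per-residue relative accessibility (% of the Ala-X-Ala maximum)."""
    ref_table = ref_table if ref_table is not None else atom_data.sasa_reference()
    for res, area in result.per_residue_abs.items():
        ref = ref_table.get(res.aa)
        if ref is None:
            raise KeyError(f"residue type {res.aa!r} missing from reference table")
        rel = 100.0 * area / ref
        result.per_residue_rel[res] = rel
        res.sasa_rel = rel
    return result
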