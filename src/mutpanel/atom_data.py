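"""Packaged configuration tables: atom typing, vdW radii, SASA references.

All tables ship as plain TSV under ``mutpanel/data`` and can be overridden
by passing a path to the corresponding loader.  The atom-class table doubles
as the expected heavy-atom complement used by the missing-atom chain filter
(every listed atom except the optional terminal ``OXT``).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

PHYS_CLASSES = frozenset(
    {"positive", "negative", "aromatic", "hydrophobic", "donor", "acceptor"}
)

#: three-letter -> one-letter code, 20 standard residues
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: common non-standard residues mapped to their standard parent
NONSTANDARD_PARENT = {
    "MSE": "MET",
    "SEC": "CYS",
    "PYL": "LYS",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS",
}

#: atom renames applied together with a residue mapping
NONSTANDARD_ATOM_RENAME = {"MSE": {"SE": "SD"}}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_DATA = resources.files("mutpanel") / "data"


def _read_tsv(path) -> list[list[str]]:
    rows = []
    for line in Path(str(path)).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def atom_class_table(path: str | None = None) -> dict[tuple[str, str], frozenset[str]]:
    """(residue name, atom name) -> set of physicochemical classes."""
    src = path or str(_DATA / "atom_classes.tsv")
    table: dict[tuple[str, str], frozenset[str]] = {}
    for res, atom, classes in _read_tsv(src):
        cls = frozenset() if classes == "-" else frozenset(classes.split(","))
        unknown = cls - PHYS_CLASSES
        if unknown:
            raise ValueError(f"unknown class(es) {sorted(unknown)} for {res} {atom}")
        table[(res, atom)] = cls
    # every residue additionally allows a charged terminal carboxylate oxygen
    for res in THREE_TO_ONE:
        table[(res, "OXT")] = frozenset({"negative", "acceptor"})
    return table


@lru_cache(maxsize=None)
def expected_heavy_atoms(path: str | None = None) -> dict[str, frozenset[str]]:
    """Residue name -> heavy atoms a complete residue must contain."""
    per_res: dict[str, set[str]] = {}
    for (res, atom) in atom_class_table(path):
        if atom != "OXT":
            per_res.setdefault(res, set()).add(atom)
    return {res: frozenset(atoms) for res, atoms in per_res.items()}


@lru_cache(maxsize=None)
def vdw_radii(path: str | None = None) -> dict[str, float]:
    """Element symbol (upper case) -> van der Waals radius in A."""
    src = path or str(_DATA / "vdw_radii.tsv")
    return {elem.upper(): float(radius) for elem, radius in _read_tsv(src)}


@lru_cache(maxsize=None)
def sasa_reference(path: str | None = None) -> dict[str, float]:
    """One-letter residue code -> Ala-X-Ala maximum accessible area (A^2)."""
    src = path or str(_DATA / "sasa_reference.tsv")
    table = {aa: float(area) for aa, area in _read_tsv(src)}
    missing = set(ONE_TO_THREE) - set(table)
    if missing:
        raise ValueError(f"SASA reference table misses residues {sorted(missing)}")
    return table


@lru_cache(maxsize=None)
def contact_rules(path: str | None = None) -> tuple[tuple[str, str, str, float], ...]:
    """Typed-contact rules as (type, class_a, class_b, max_distance) tuples."""
    src = path or str(_DATA / "contact_rules.tsv")
    return tuple(
        (ctype, a, b, float(dist)) for ctype, a, b, dist in _read_tsv(src)
    )
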