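"""Read and sanitize protein structures.

PDB files are parsed with :mod:`gemmi` and converted into light-weight
chain-level records.  The cleanup mirrors common pre-processing practice:
chain separation, removal of duplicate chains within an entry, exclusion of
chains with missing heavy atoms, and use of only the first model of
multi-model (NMR-style) files.  Atoms are then annotated with van der Waals
radii and physicochemical classes from the packaged typing table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from . import atom_data

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "PDBParseError",
    "CleanError",
    "read_pdb",
    "read_pdb_string",
    "clean_set",
    "annotate_atom_types",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed or holds no protein atoms."""


class CleanError(ValueError):
    """Raised when cleanup rejects every chain; carries per-chain reasons."""

    def __init__(self, reasons: dict[str, str]):
        self.reasons = dict(reasons)
        lines = ", ".join(f"{cid}: {why}" for cid, why in sorted(reasons.items()))
        super().__init__(f"no chain survived cleanup ({lines})")


@dataclass(eq=False)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    vdw_radius: float = 0.0  # filled by annotate_atom_types
    phys_classes: frozenset[str] = frozenset()
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite numbers")


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    aa: str  # one-letter code, 'X' if unmappable
    name: str  # three-letter PDB residue name (after parent mapping)
    atoms: list[Atom] = field(default_factory=list)
    sasa_abs: float | None = None  # A^2, filled by the sasa stage
    sasa_rel: float | None = None  # percent of Ala-X-Ala reference

    @property
    def key(self) -> tuple[str, int, str]:
        """Stable identifier (chain, PDB number, insertion code)."""
        return (self.chain_id, self.seq_number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.seq_number}{self.insertion_code}".strip()

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.label} has no atom {name}")


@dataclass(eq=False)
class Structure:
    """A single protein chain (one chain per structure after reading)."""

    source_id: str  # "<entry>:<chain>", e.g. "1ABC:A"
    entry_id: str
    chain_id: str
    residues: list[Residue]
    model_index: int = 1

    @property
    def chains(self) -> list[list[Residue]]:
        return [self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]


_WATERS = {"HOH", "WAT", "DOD"}


def _convert_residue(res: gemmi.Residue, chain_id: str) -> Residue | None:
    """Map a gemmi residue to ours; None if it is not a protein residue."""
    name = res.name.strip().upper()
    if name in _WATERS:
        return None
    mapped = atom_data.NONSTANDARD_PARENT.get(name)
    if name in atom_data.THREE_TO_ONE:
        std_name = name
    elif mapped is not None:
        std_name = mapped
    elif res.het_flag == "A":
        std_name = None  # unknown polymer residue: keep, flag as 'X'
    else:
        return None  # HETATM ligand
    renames = atom_data.NONSTANDARD_ATOM_RENAME.get(name, {})
    atoms = []
    for at in res:
        if at.altloc not in ("", "\x00", "A"):
            continue
        atom_name = renames.get(at.name, at.name)
        element = at.element.name.upper()
        if element == "SE" and atom_name == "SD":
            element = "S"
        if element == "H" or element == "D":
            continue
        atoms.append(
            Atom(
                serial=at.serial,
                name=atom_name,
                element=element,
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                altloc="" if at.altloc in ("", "\x00") else at.altloc,
            )
        )
    if not atoms:
        return None
    aa = atom_data.THREE_TO_ONE.get(std_name, "X") if std_name else "X"
    return Residue(
        chain_id=chain_id,
        seq_number=res.seqid.num,
        insertion_code=(res.seqid.icode or "").strip(),
        aa=aa,
        name=std_name or name,
        atoms=atoms,
    )


def read_pdb(path: str | Path) -> list[Structure]:
    """Read a PDB file into one :class:`Structure` per chain.

    Only the first model of multi-model files is used; waters, ligand
    HETATM records and hydrogens are dropped; alternate locations other
    than blank/'A' are discarded.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"{path}: file does not exist")
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    return _from_gemmi(st, fallback_name=path.stem.upper(), origin=str(path))


def read_pdb_string(text: str, name: str = "INMEM") -> list[Structure]:
    """Parse PDB-format text (same conventions as :func:`read_pdb`)."""
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"<string>: {exc}") from exc
    return _from_gemmi(st, fallback_name=name.upper(), origin="<string>")


def _from_gemmi(st: gemmi.Structure, fallback_name: str, origin: str) -> list[Structure]:
    if len(st) == 0:
        raise PDBParseError(f"{origin}: no models found")
    model = st[0]
    entry = (st.name or "").strip().upper() or fallback_name
    structures = []
    for chain in model:
        residues = [
            r for r in (_convert_residue(res, chain.name) for res in chain) if r
        ]
        if residues:
            structures.append(
                Structure(
                    source_id=f"{entry}:{chain.name}",
                    entry_id=entry,
                    chain_id=chain.name,
                    residues=residues,
                    model_index=1,
                )
            )
    if not structures:
        raise PDBParseError(f"{origin}: no protein atoms")
    return structures


def _missing_atoms(structure: Structure, expected) -> str | None:
    for res in structure.residues:
        if res.aa == "X":
            return f"unmappable residue {res.name} at {res.label}"
        want = expected.get(res.name)
        if want is None:
            return f"no atom template for residue {res.name}"
        have = {a.name for a in res.atoms}
        missing = want - have
        if missing:
            return (
                f"missing atoms {','.join(sorted(missing))} in "
                f"{res.name} {res.label}"
            )
    return None


def clean_set(
    structures: list[Structure],
    *,
    keep_duplicates: bool = False,
    require_complete: bool = True,
) -> list[Structure]:
    """Apply the cleanup procedures to a set of single-chain structures.

    Chains with identical sequence from the same entry are collapsed to one
    representative; chains with missing heavy atoms (or unmappable
    residues) are excluded when ``require_complete``.  Survivors are sorted
    by ``source_id``.  Raises :class:`CleanError` if nothing survives.
    """
    expected = atom_data.expected_heavy_atoms()
    reasons: dict[str, str] = {}
    survivors: list[Structure] = []
    seen: set[tuple[str, str]] = set()
    for st in sorted(structures, key=lambda s: s.source_id):
        if require_complete:
            why = _missing_atoms(st, expected)
            if why is not None:
                reasons[st.source_id] = f"missing atoms: {why}"
                continue
        sig = (st.entry_id, st.sequence)
        if not keep_duplicates and sig in seen:
            reasons[st.source_id] = "duplicate chain within entry"
            continue
        seen.add(sig)
        survivors.append(st)
    if not survivors:
        raise CleanError(reasons or {"-": "empty input"})
    return survivors


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a (cleaned) single-chain structure back to PDB via gemmi."""
    st = gemmi.Structure()
    st.name = structure.entry_id
    model = gemmi.Model("1")
    chain = gemmi.Chain(structure.chain_id)
    for res in structure.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
        for at in res.atoms:
            gat = gemmi.Atom()
            gat.name = at.name
            gat.serial = at.serial
            gat.element = gemmi.Element(at.element.capitalize())
            gat.pos = gemmi.Position(*at.coords)
            gat.occ = 1.0
            gres.add_atom(gat)
        chain.add_residue(gres)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def annotate_atom_types(
    structure: Structure,
    rules: dict[tuple[str, str], frozenset[str]] | None = None,
    radii: dict[str, float] | None = None,
) -> Structure:
    """Assign vdW radii and physicochemical classes to every atom (in place)."""
    rules = rules if rules is not None else atom_data.atom_class_table()
    radii = radii if radii is not None else atom_data.vdw_radii()
    for res in structure.residues:
        for at in res.atoms:
            radius = radii.get(at.element)
            if radius is None:
                logger.warning(
                    "no vdW radius for element %s (%s %s); using carbon",
                    at.element, res.name, at.name,
                )
                radius = radii["C"]
            at.vdw_radius = radius
            classes = rules.get((res.name, at.name))
            if classes is None:
                logger.warning(
                    "untyped atom %s in residue %s %s", at.name, res.name, res.label
                )
                classes = frozenset()
            at.phys_classes = classes
    return structure
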