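"""Synthetic structures, families and planted-signal datasets.

Toy protein chains are built on ideal internal coordinates: the backbone
is grown atom by atom (NeRF construction) with standard bond lengths and
angles, either as an alpha-helix (phi = -57, psi = -47; rise ~1.5 A and
~100 degrees per residue) or as a fully extended strand (phi = psi = 180).
Full heavy-atom side chains are grafted from the ideal-coordinate residue
templates bundled with biotite, superimposed on each residue's N/CA/C
frame, so the chains pass the missing-atom filter and exercise every
contact rule.  Families are sampled with exact per-column residue counts
so frequency-dependent tests are exact rather than statistical, and
planted datasets construct mutated columns whose partial fitness provably
dominates all decoys.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import biotite.structure as bst
import biotite.structure.info as bstinfo
import biotite.structure.io.pdb as bstpdb
import numpy as np

from . import atom_data, ga_select
from .family_align import (
    Alignment,
    ColumnProfile,
    Mutation,
    PropertyRecord,
    call_mutations,
    column_profiles,
)
from .structure_io import Structure, read_pdb_string

__all__ = [
    "FamilySpec",
    "PlantedDataset",
    "make_toy_structure",
    "make_family",
    "make_planted_dataset",
    "packaged_tables",
    "TableRow",
]

# ideal backbone internal coordinates (lengths in A, angles in degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.2, 121.7, 120.8
_GEOMETRIES = {"helix": (-57.0, -47.0), "extended": (180.0, 180.0)}


def _place(a, b, c, length, angle_deg, torsion_deg):
    """NeRF: position of atom D bonded to C, given frame A-B-C."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -length * np.cos(angle),
            length * np.sin(angle) * np.cos(torsion),
            length * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _backbone(sequence: str, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates per residue."""
    coords: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c = ca + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    coords.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, len(sequence)):
        n_next = _place(coords[-1]["N"], coords[-1]["CA"], coords[-1]["C"],
                        _B_C_N, _A_CA_C_N, psi)
        ca_next = _place(coords[-1]["CA"], coords[-1]["C"], n_next,
                         _B_N_CA, _A_C_N_CA, 180.0)  # omega trans
        c_next = _place(coords[-1]["C"], n_next, ca_next,
                        _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            # carbonyl O trans to the next amide nitrogen
            res["O"] = _place(coords[i + 1]["N"], res["CA"], res["C"],
                              _B_C_O, _A_CA_C_O, 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"],
                              _B_C_O, _A_CA_C_O, psi + 180.0)
    return coords


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Rotation + translation superimposing ``mobile`` onto ``target``."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


_GAMMA_ATOMS = ("CG", "CG1", "OG", "OG1", "SG")
_CHI1_FIXED = ("N", "CA", "C", "CB")


@lru_cache(maxsize=32)
def _template(res3: str):
    """Heavy-atom ideal-coordinate template (cached; treated as read-only)."""
    template = bstinfo.residue(res3)
    return template[template.element != "H"]


def _torsion(p1, p2, p3, p4) -> float:
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(m @ n2, n1 @ n2)))


def _side_chain(
    res3: str, frame: dict[str, np.ndarray], chi1: float | None = -60.0
) -> list[tuple[str, str, np.ndarray]]:
    """Heavy side-chain atoms from the ideal template, fitted on N/CA/C.

    ``chi1`` (degrees) rotates the side chain beyond CB about the CA-CB
    axis to the requested first torsion; the gauche(-) default is the most
    common rotamer and lets e.g. leucine helices form native-like
    hydrophobic packing.  ``None`` keeps the template rotamer.  Proline is
    left untouched (its ring fixes chi1).
    """
    template = _template(res3)
    names = list(template.atom_name)
    try:
        idx = [names.index(a) for a in ("N", "CA", "C")]
    except ValueError as exc:
        raise ValueError(f"template for {res3} lacks backbone atoms") from exc
    rot, shift = _kabsch(
        template.coord[idx],
        np.stack([frame["N"], frame["CA"], frame["C"]]),
    )
    placed = {
        name: (name, element, rot @ coord + shift)
        for name, element, coord in zip(
            template.atom_name, template.element, template.coord
        )
        if name not in ("O", "OXT")
    }
    gamma = next((g for g in _GAMMA_ATOMS if g in placed), None)
    if chi1 is not None and gamma is not None and res3 != "PRO":
        n, ca, cb = (placed[a][2] for a in ("N", "CA", "CB"))
        current = _torsion(n, ca, cb, placed[gamma][2])
        axis = cb - ca
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(chi1 - current)
        k = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        rmat = np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)
        for name, (_, element, coord) in list(placed.items()):
            if name not in _CHI1_FIXED:
                placed[name] = (name, element, ca + rmat @ (coord - ca))
    return [rec for name, rec in placed.items() if name not in ("N", "CA", "C")]


def make_toy_structure(
    sequence: str,
    geometry: str = "helix",
    seed: int = 0,
    noise: float = 0.0,
    chi1: float | None = -60.0,
    path: str | Path | None = None,
) -> tuple[Structure, str]:
    """Build an ideal-geometry chain; returns (parsed Structure, PDB text).

    ``noise`` adds a uniform coordinate perturbation of that amplitude (A)
    drawn from ``seed``; the default 0 gives the ideal geometry, identical
    for identical seeds either way.
    """
    sequence = sequence.upper()
    if len(sequence) < 3:
        raise ValueError("sequence must have length >= 3")
    bad = [aa for aa in sequence if aa not in atom_data.ONE_TO_THREE]
    if bad:
        raise ValueError(f"invalid residue letter(s) {sorted(set(bad))}")
    if geometry not in _GEOMETRIES:
        raise ValueError(f"geometry must be one of {sorted(_GEOMETRIES)}")
    phi, psi = _GEOMETRIES[geometry]
    backbone = _backbone(sequence, phi, psi)
    rng = np.random.default_rng(seed)

    atoms = []  # (res_id, res_name, atom_name, element, coord)
    for i, aa in enumerate(sequence):
        res3 = atom_data.ONE_TO_THREE[aa]
        frame = backbone[i]
        for name in ("N", "CA", "C", "O"):
            element = name[0]
            atoms.append((i + 1, res3, name, element, frame[name]))
        for name, element, coord in _side_chain(res3, frame, chi1):
            atoms.append((i + 1, res3, name, element, coord))

    coords = np.stack([a[4] for a in atoms])
    if noise > 0:
        coords = coords + rng.uniform(-noise, noise, size=coords.shape)

    array = bst.AtomArray(len(atoms))
    array.coord = coords.astype(np.float32)
    array.chain_id = np.array(["A"] * len(atoms))
    array.res_id = np.array([a[0] for a in atoms])
    array.res_name = np.array([a[1] for a in atoms])
    array.atom_name = np.array([a[2] for a in atoms])
    array.element = np.array([a[3] for a in atoms])
    array.hetero = np.array([False] * len(atoms))

    pdb_file = bstpdb.PDBFile()
    pdb_file.set_structure(array)
    buffer = io.StringIO()
    pdb_file.write(buffer)
    text = buffer.getvalue()
    if path is not None:
        Path(path).write_text(text)
    name = Path(path).stem.upper() if path is not None else "TOY"
    structure = read_pdb_string(text, name=name)[0]
    return structure, text


@dataclass
class FamilySpec:
    """Recipe for a synthetic aligned family with exact column compositions."""

    reference_seq: str
    n_rows: int  # sampled family rows (mutant and reference are added on top)
    column_spec: dict[int, dict[str, float]] = field(default_factory=dict)
    mutant_edits: list[tuple[int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for col, dist in self.column_spec.items():
            if not 1 <= col <= len(self.reference_seq):
                raise ValueError(f"column {col} outside the reference sequence")
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"column {col}: frequencies sum to {total}, not 1")
        for col, aa in self.mutant_edits:
            if not 1 <= col <= len(self.reference_seq):
                raise ValueError(f"mutant edit column {col} out of range")
            if aa == self.reference_seq[col - 1]:
                raise ValueError(
                    f"mutant edit at column {col} equals the reference residue"
                )


def make_family(
    spec: FamilySpec, path: str | Path | None = None
) -> tuple[Alignment, str]:
    """Sample the family; returns (Alignment, FASTA text).

    Rows: ``mutant`` (reference with edits applied), ``reference``, then
    ``fam001..`` sampled with exact per-column counts, placement shuffled
    by the seed.  Columns without a spec copy the reference residue.
    """
    rng = np.random.default_rng(spec.seed)
    length = len(spec.reference_seq)
    fam_rows = [list(spec.reference_seq) for _ in range(spec.n_rows)]
    for col, dist in sorted(spec.column_spec.items()):
        pool: list[str] = []
        for aa, freq in sorted(dist.items()):
            count = freq * spec.n_rows
            if abs(count - round(count)) > 1e-9:
                raise ValueError(
                    f"column {col}: {aa} frequency {freq} times {spec.n_rows} rows "
                    f"is not integral; adjust n_rows"
                )
            pool.extend([aa] * int(round(count)))
        order = rng.permutation(spec.n_rows)
        for row_idx, aa in zip(order, pool):
            fam_rows[row_idx][col - 1] = aa
    mutant = list(spec.reference_seq)
    for col, aa in spec.mutant_edits:
        mutant[col - 1] = aa
    rows = [("mutant", "".join(mutant)), ("reference", spec.reference_seq)]
    rows += [
        (f"fam{i + 1:03d}", "".join(fam_rows[i])) for i in range(spec.n_rows)
    ]
    fasta = "".join(f">{rid}\n{seq}\n" for rid, seq in rows)
    if path is not None:
        Path(path).write_text(fasta)
    return Alignment(rows=rows, mutant_row=0, reference_row=1), fasta


@dataclass
class PlantedDataset:
    """Synthetic GA instance with a provably optimal gene set."""

    alignment: Alignment
    properties: dict[str, dict[int, PropertyRecord]]
    profiles: list[ColumnProfile]
    mutations: list[Mutation]
    optimum: tuple[int, ...]  # planted columns (the unique best gene set)
    optimum_fitness: float  # direct arithmetic evaluation, literal mode
    reference_structure: Structure | None = None


# property levels for planted (high partial fitness) vs decoy columns
_PLANTED = PropertyRecord(acc=5.0, deg=1.0, bet=5.0, clo=0.001)
_DECOY = PropertyRecord(acc=80.0, deg=8.0, bet=200.0, clo=0.01)
_BASELINE = PropertyRecord(acc=40.0, deg=4.0, bet=50.0, clo=0.005)


def make_planted_dataset(
    k: int, m: int, seed: int = 0, with_structure: bool = False
) -> PlantedDataset:
    """Plant ``k`` dominant mutated columns among ``m``.

    Planted columns carry a rare, strongly penalized substitution (G -> W)
    on a structurally "quiet" column (low accessibility/centrality, hence a
    high literal-mode partial fitness); decoys carry a frequent,
    well-scoring substitution (I -> L) on columns at the property maxima.
    Every planted column's T_i exceeds every decoy's by construction, so
    the planted set is the unique fitness optimum for N = k.
    """
    if not 0 < k < m:
        raise ValueError("need 0 < k < m")
    rng = np.random.default_rng(seed)
    n_rows = 8
    length = 2 * m + 8
    background = "".join(rng.choice(list("ADEFHKNQRSTY"), size=length))
    columns = sorted(rng.choice(np.arange(1, length + 1), size=m, replace=False))
    planted = sorted(rng.choice(columns, size=k, replace=False).tolist())
    seq = list(background)
    column_spec: dict[int, dict[str, float]] = {}
    edits: list[tuple[int, str]] = []
    for col in columns:
        if col in planted:
            seq[col - 1] = "G"
            column_spec[col] = {"G": 1.0}
            edits.append((col, "W"))
        else:
            seq[col - 1] = "I"
            column_spec[col] = {"L": 0.75, "I": 0.25}
            edits.append((col, "L"))
    reference_seq = "".join(seq)
    spec = FamilySpec(
        reference_seq=reference_seq, n_rows=n_rows,
        column_spec=column_spec, mutant_edits=edits, seed=seed,
    )
    alignment, _ = make_family(spec)

    properties = {
        rid: {
            col: (
                _PLANTED if col in planted
                else _DECOY if col in set(columns)
                else _BASELINE
            )
            for col in range(1, length + 1)
        }
        for rid, _ in alignment.rows
    }
    profiles = column_profiles(alignment, properties)
    mutations = call_mutations(alignment)
    ctx = ga_select.build_context(profiles, mutations)

    # direct arithmetic evaluation of the planted set (independent of the
    # GA code path): T_i = (1-Res_freq) + (1-Score) + (1-SRM)
    prof_by_col = {p.column: p for p in profiles}
    pam = ga_select.pam250()
    total = 0.0
    for col in planted:
        p = prof_by_col[col]
        res_freq = p.freq.get("W", 0.0)
        score = (pam[("G", "W")] - ctx.pam_min) / (ctx.pam_max - ctx.pam_min)
        srm = (
            p.acc_avg / ctx.acc_max + p.deg_avg / ctx.deg_max
            + p.bet_avg / ctx.bet_max + p.clo_avg / ctx.clo_max
        ) / 4.0
        total += (1.0 - res_freq) + (1.0 - score) + (1.0 - srm)

    ref_structure = None
    if with_structure:
        ref_structure, _ = make_toy_structure(reference_seq, "helix", seed=seed)
    return PlantedDataset(
        alignment=alignment,
        properties=properties,
        profiles=profiles,
        mutations=mutations,
        optimum=tuple(planted),
        optimum_fitness=total,
        reference_structure=ref_structure,
    )


#: 24-residue reference used by the packaged end-to-end dataset
_PIPELINE_REF = "MKVLITGAHEFWDRSYQNPECTIG"


def make_pipeline_dataset(work_dir: str | Path, seed: int = 0):
    """Write a complete synthetic study to ``work_dir``; returns its config.

    The family has 10 sampled rows plus mutant and reference (all with
    helical toy structures, 24 residues).  The mutant carries three edits:
    L4K (rare, non-conservative under every scheme — the expected
    manual-selection hit), A8G (rare but conservative) and E20Q
    (non-conservative but frequent in the family), plus an annotated
    active site at H9.  Deterministic for a fixed seed.
    """
    from .viz_export import PipelineConfig  # local import, avoids a cycle

    work = Path(work_dir)
    work.mkdir(parents=True, exist_ok=True)
    spec = FamilySpec(
        reference_seq=_PIPELINE_REF,
        n_rows=10,
        column_spec={
            4: {"L": 1.0},
            8: {"A": 1.0},
            20: {"Q": 0.5, "E": 0.5},
        },
        mutant_edits=[(4, "K"), (8, "G"), (20, "Q")],
        seed=seed,
    )
    alignment, _ = make_family(spec, path=work / "family.fasta")
    structure_files = {}
    for rid, seq in alignment.rows:
        pdb_path = work / f"{rid}.pdb"
        make_toy_structure(seq, "helix", seed=seed, path=pdb_path)
        structure_files[rid] = str(pdb_path)
    (work / "active_sites.txt").write_text("H9\n")
    return PipelineConfig(
        alignment_file=str(work / "family.fasta"),
        mutant_id="mutant",
        reference_id="reference",
        structure_files=structure_files,
        active_sites_file=str(work / "active_sites.txt"),
        seed=seed,
        out_dir=str(work / "out"),
    )


@dataclass(frozen=True)
class TableRow:
    mutation: str
    deg_avg: float
    bet_avg: float
    clo_avg_e4: float
    acc_avg: float


def packaged_tables() -> tuple[list[TableRow], list[TableRow]]:
    """The two packaged 22-row prediction tables (manual and GA selection)."""
    from importlib import resources

    tables = []
    for fname in ("table1.tsv", "table2.tsv"):
        rows = []
        text = (resources.files("mutpanel") / "data" / fname).read_text()
        lines = [
            ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
        ]
        for line in lines[1:]:  # skip header
            label, deg, bet, clo, acc = line.split("\t")
            rows.append(
                TableRow(
                    mutation=label, deg_avg=float(deg), bet_avg=float(bet),
                    clo_avg_e4=float(clo), acc_avg=float(acc),
                )
            )
        tables.append(rows)
    return tables[0], tables[1]
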