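"""Alignment-level profiles, mutation calling and rule-based prioritization.

A structure-based multiple alignment (aligned multi-FASTA) with designated
mutant and reference rows is mapped onto per-residue structural properties
(relative accessibility, degree, betweenness, closeness).  Per-column
profiles carry residue frequencies, property averages and active-site
flags.  Point mutations (substitution columns between mutant and
reference) are classified as conservative/non-conservative under the
CINEMA, CLUSTAL and LESK residue-grouping schemes and as
frequent/rare/very-rare in the family; the manual-selection rule keeps
non-conservative rare or very rare mutations, ordered by structural
importance (high degree and betweenness, low accessibility).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from .contact_graph import ResidueGraph
from .structure_io import Residue, Structure

__all__ = [
    "Alignment",
    "Mutation",
    "ColumnProfile",
    "ColorScheme",
    "PropertyRecord",
    "SCHEMES",
    "load_alignment",
    "map_alignment_to_structures",
    "call_mutations",
    "classify_substitution",
    "column_profiles",
    "rarity_class",
    "manual_filter",
    "parse_mutation_label",
    "parse_active_sites",
    "property_table",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"


@dataclass(frozen=True)
class ColorScheme:
    """Residue grouping used both for colouring and conservativeness."""

    name: str
    groups: tuple[tuple[str, frozenset[str]], ...]

    def group_of(self, aa: str) -> str | None:
        for label, members in self.groups:
            if aa in members:
                return label
        return None


def _scheme(name, *groups):
    return ColorScheme(
        name, tuple((label, frozenset(members)) for label, members in groups)
    )


SCHEMES: dict[str, ColorScheme] = {
    "CINEMA": _scheme(
        "CINEMA",
        ("polar_positive", "HKR"),
        ("polar_negative", "DE"),
        ("polar_neutral", "NQST"),
        ("nonpolar_aliphatic", "AGILMV"),
        ("nonpolar_ring", "FPWY"),
        ("cysteine", "C"),
    ),
    "CLUSTAL": _scheme(
        "CLUSTAL",
        ("small_polar", "GPST"),
        ("positive", "HKR"),
        ("aromatic", "FWY"),
        ("aliphatic", "ILMV"),
    ),
    "LESK": _scheme(
        "LESK",
        ("small_nonpolar", "AGST"),
        ("hydrophobic", "CFILMPVWY"),
        ("polar", "HNQ"),
        ("negative", "DE"),
        ("positive", "KR"),
    ),
}


@dataclass
class Alignment:
    """Aligned family; mutant row first, reference (wild type) second."""

    rows: list[tuple[str, str]]
    mutant_row: int = 0
    reference_row: int = 1

    @property
    def length(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def mutant(self) -> tuple[str, str]:
        return self.rows[self.mutant_row]

    @property
    def reference(self) -> tuple[str, str]:
        return self.rows[self.reference_row]

    def column(self, col: int) -> list[str]:
        """Residues of 1-based column ``col`` across rows (gaps included)."""
        return [seq[col - 1] for _, seq in self.rows]


@dataclass
class Mutation:
    column: int  # 1-based alignment column
    ref_aa: str
    mut_aa: str
    ref_seq_pos: int  # 1-based ungapped position in the reference sequence
    mut_seq_pos: int
    conservative_by_scheme: dict[str, bool] = field(default_factory=dict)
    rarity: str | None = None
    is_active_site: bool = False
    contacts_active_site: bool = False

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.ref_seq_pos}{self.mut_aa}"


def parse_mutation_label(label: str) -> tuple[str, int, str]:
    """'I20A' -> ('I', 20, 'A'); inverse of :attr:`Mutation.label`."""
    if len(label) < 3 or label[0] not in AA20 or label[-1] not in AA20:
        raise ValueError(f"malformed mutation label {label!r}")
    return label[0], int(label[1:-1]), label[-1]


@dataclass
class ColumnProfile:
    column: int
    freq: dict[str, float]
    res_freq_mut: float
    acc_avg: float | None
    deg_avg: float | None
    bet_avg: float | None
    clo_avg: float | None
    is_active_site: bool = False
    contacts_active_site: bool = False


@dataclass(frozen=True)
class PropertyRecord:
    """Structural properties of one mapped residue."""

    acc: float  # relative accessibility, percent
    deg: float
    bet: float
    clo: float


def load_alignment(
    path: str | Path, mutant_id: str, reference_id: str
) -> Alignment:
    """Load an aligned multi-FASTA; reorder so mutant is row 1, reference row 2."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if len(records) < 2:
        raise ValueError(f"{path}: alignment needs at least 2 rows")
    lengths = {len(seq) for _, seq in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment (row lengths {sorted(lengths)})")
    ids = [rid for rid, _ in records]
    for needed in (mutant_id, reference_id):
        if needed not in ids:
            raise ValueError(f"{path}: row id {needed!r} not found in alignment")
    by_id = dict(records)
    rest = [(rid, seq) for rid, seq in records if rid not in (mutant_id, reference_id)]
    rows = [(mutant_id, by_id[mutant_id]), (reference_id, by_id[reference_id])] + rest
    return Alignment(rows=rows, mutant_row=0, reference_row=1)


def map_alignment_to_structures(
    alignment: Alignment, structures: Mapping[str, Structure]
) -> dict[str, dict[int, Residue]]:
    """Per row: 1-based non-gap column -> structure residue.

    Requires each structure's sequence to equal the row's ungapped sequence;
    the first discordant (ungapped) position is reported otherwise.
    """
    out: dict[str, dict[int, Residue]] = {}
    by_id = dict(alignment.rows)
    for row_id, st in structures.items():
        if row_id not in by_id:
            raise KeyError(f"structure id {row_id!r} has no alignment row")
        gapped = by_id[row_id]
        ungapped = gapped.replace(GAP, "")
        seq = st.sequence
        if ungapped != seq:
            upto = min(len(ungapped), len(seq))
            pos = next(
                (k + 1 for k in range(upto) if ungapped[k] != seq[k]), upto + 1
            )
            raise ValueError(
                f"row {row_id}: alignment/structure sequence mismatch at "
                f"ungapped position {pos} "
                f"(alignment {ungapped[pos - 1:pos] or '?'} vs "
                f"structure {seq[pos - 1:pos] or '?'})"
            )
        mapping: dict[int, Residue] = {}
        k = 0
        for col, aa in enumerate(gapped, start=1):
            if aa != GAP:
                mapping[col] = st.residues[k]
                k += 1
        out[row_id] = mapping
    return out


def call_mutations(alignment: Alignment) -> list[Mutation]:
    """Substitution columns where mutant and reference are non-gap and differ."""
    _, mut_seq = alignment.mutant
    _, ref_seq = alignment.reference
    mutations = []
    mut_pos = ref_pos = 0
    for col, (m, r) in enumerate(zip(mut_seq, ref_seq), start=1):
        if m != GAP:
            mut_pos += 1
        if r != GAP:
            ref_pos += 1
        if m == GAP or r == GAP or m == r:
            continue
        mutation = Mutation(
            column=col, ref_aa=r, mut_aa=m,
            ref_seq_pos=ref_pos, mut_seq_pos=mut_pos,
        )
        mutation.conservative_by_scheme = {
            name: classify_substitution(scheme, r, m)
            for name, scheme in SCHEMES.items()
        }
        mutations.append(mutation)
    return mutations


def classify_substitution(scheme: ColorScheme, a: str, b: str) -> bool:
    """True iff the a -> b substitution is conservative under ``scheme``."""
    for aa in (a, b):
        if aa not in AA20:
            raise ValueError(f"unknown residue {aa!r}")
    if a == b:
        return True
    ga, gb = scheme.group_of(a), scheme.group_of(b)
    if ga is None or gb is None:  # ungrouped (CLUSTAL 'other') residues
        return False
    return ga == gb


def parse_active_sites(source: str | Path | list[str]) -> list[tuple[str, int]]:
    """Active-site file: one 'N10'-style entry (aa + reference position) per line."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        lines = Path(str(source)).read_text().splitlines()
    elif isinstance(source, list):
        lines = source
    else:
        lines = str(source).splitlines()
    sites = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, pos = line[0].upper(), int(line[1:])
        if aa not in AA20:
            raise ValueError(f"bad active-site entry {line!r}")
        sites.append((aa, pos))
    return sites


def column_profiles(
    alignment: Alignment,
    properties: Mapping[str, Mapping[int, PropertyRecord]],
    active_sites: list[tuple[str, int]] | None = None,
    ref_graph: ResidueGraph | None = None,
    ref_column_map: Mapping[int, Residue] | None = None,
) -> list[ColumnProfile]:
    """Per-column residue frequencies, property averages and site flags.

    ``properties`` maps row id -> column -> :class:`PropertyRecord` for rows
    backed by a structure.  Frequencies run over all non-gap rows (mutant
    included); averages run over mapped rows only and are ``None`` for
    columns with no mapped residue.  Active-site flags are evaluated on the
    reference row; ``contacts_active_site`` additionally needs the
    reference residue graph and column map.
    """
    _, ref_seq = alignment.reference
    _, mut_seq = alignment.mutant

    # reference ungapped position per column, for active-site lookup
    ref_pos_of_col: dict[int, int] = {}
    pos = 0
    for col, aa in enumerate(ref_seq, start=1):
        if aa != GAP:
            pos += 1
            ref_pos_of_col[col] = pos

    active_positions: dict[int, str] = {}
    for aa, p in active_sites or []:
        active_positions[p] = aa
    active_cols = set()
    for col, p in ref_pos_of_col.items():
        if p in active_positions:
            expect = active_positions[p]
            got = ref_seq[col - 1]
            if got != expect:
                raise ValueError(
                    f"active site {expect}{p}: reference has {got} at position {p}"
                )
            active_cols.add(col)

    active_residues = set()
    if ref_graph is not None and ref_column_map is not None:
        active_residues = {
            ref_column_map[c] for c in active_cols if c in ref_column_map
        }

    profiles = []
    for col in range(1, alignment.length + 1):
        residues = [aa for aa in alignment.column(col) if aa != GAP]
        freq: dict[str, float] = {}
        if residues:
            n = len(residues)
            for aa in residues:
                freq[aa] = freq.get(aa, 0.0) + 1.0 / n
        mut_aa = mut_seq[col - 1]
        res_freq_mut = freq.get(mut_aa, 0.0) if mut_aa != GAP else 0.0

        vals = [
            props[col] for props in properties.values() if col in props
        ]
        if vals:
            avg = lambda key: sum(getattr(v, key) for v in vals) / len(vals)
            acc_avg, deg_avg = avg("acc"), avg("deg")
            bet_avg, clo_avg = avg("bet"), avg("clo")
        else:
            acc_avg = deg_avg = bet_avg = clo_avg = None

        contacts_active = False
        ref_res = (ref_column_map or {}).get(col)
        if ref_graph is not None and ref_res is not None and active_residues:
            contacts_active = any(
                nb in active_residues for nb in ref_graph.neighbors(ref_res)
            )
        profiles.append(
            ColumnProfile(
                column=col, freq=freq, res_freq_mut=res_freq_mut,
                acc_avg=acc_avg, deg_avg=deg_avg,
                bet_avg=bet_avg, clo_avg=clo_avg,
                is_active_site=col in active_cols,
                contacts_active_site=contacts_active,
            )
        )
    return profiles


def rarity_class(
    profile: ColumnProfile,
    mut_aa: str,
    t_very_rare: float = 0.02,
    t_rare: float = 0.10,
) -> str:
    """Frequency band of ``mut_aa`` in the column: frequent / rare / very_rare."""
    f = profile.freq.get(mut_aa, 0.0)
    if f < t_very_rare:
        return "very_rare"
    if f < t_rare:
        return "rare"
    return "frequent"


def property_table(
    column_map: Mapping[int, Residue], graph: ResidueGraph
) -> dict[int, PropertyRecord]:
    """Column -> property record for one row, from its mapped residues."""
    table = {}
    for col, res in column_map.items():
        if res.sasa_rel is None:
            raise ValueError(f"residue {res.label}: SASA not computed")
        table[col] = PropertyRecord(
            acc=res.sasa_rel,
            deg=float(graph.degree.get(res, 0)),
            bet=float(graph.betweenness.get(res, 0.0)),
            clo=float(graph.closeness.get(res, 0.0)),
        )
    return table


def manual_filter(
    mutations: list[Mutation],
    profiles: list[ColumnProfile],
    scheme: str = "CINEMA",
    t_very_rare: float = 0.02,
    t_rare: float = 0.10,
) -> list[Mutation]:
    """Rule-based prioritization of candidate harmful mutations.

    Keeps mutations that are non-conservative under ``scheme`` and rare or
    very rare in the family, ordered by descending average degree, then
    descending average betweenness, then ascending average accessibility
    (ties broken by column index).  Rarity and active-site flags are filled
    on the mutations as a side effect.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    by_col = {p.column: p for p in profiles}
    selected = []
    for mut in mutations:
        prof = by_col[mut.column]
        mut.rarity = rarity_class(prof, mut.mut_aa, t_very_rare, t_rare)
        mut.is_active_site = prof.is_active_site
        mut.contacts_active_site = prof.contacts_active_site
        if mut.conservative_by_scheme.get(scheme, True):
            continue
        if mut.rarity == "frequent":
            continue
        selected.append(mut)

    def sort_key(m: Mutation):
        p = by_col[m.column]
        return (
            -(p.deg_avg if p.deg_avg is not None else 0.0),
            -(p.bet_avg if p.bet_avg is not None else 0.0),
            p.acc_avg if p.acc_avg is not None else math.inf,
            m.column,
        )

    return sorted(selected, key=sort_key)
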