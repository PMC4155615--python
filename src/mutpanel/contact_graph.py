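"""Atomic contact detection and residue interaction networks.

Candidate atomic contacts are the edges of the 3-D Delaunay tessellation of
the heavy-atom coordinates (a cutoff-independent neighbour definition).
Edges longer than ``max_edge_length`` (default 8 A) are discarded to
suppress spurious surface tetrahedra that, in a solvated system, would be
broken up by water.  Each remaining inter-residue atom pair is tested
against the typed-contact rules (charged attractive/repulsive, aromatic,
hydrophobic, hydrogen bond); a pair may carry several types.  Contacts are
then collapsed onto an undirected residue graph on which degree,
betweenness and closeness centralities are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay, QhullError

from . import atom_data
from .structure_io import Atom, Residue, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "ContactEdge",
    "ResidueGraph",
    "delaunay_edges",
    "classify_contacts",
    "structure_contacts",
    "residue_graph",
    "centralities",
]

DEFAULT_MAX_EDGE = 8.0  # A
CONTACT_TYPES = (
    "charged_attractive",
    "charged_repulsive",
    "aromatic",
    "hydrophobic",
    "hydrogen_bond",
)


@dataclass(eq=False)
class ContactEdge:
    atom_i: Atom
    atom_j: Atom
    residue_i: Residue
    residue_j: Residue
    distance: float
    types: frozenset[str]


@dataclass(eq=False)
class ResidueGraph:
    """Residue-level contact network with centrality annotations."""

    graph: nx.Graph
    degree: dict[Residue, int] = field(default_factory=dict)
    betweenness: dict[Residue, float] = field(default_factory=dict)
    closeness: dict[Residue, float] = field(default_factory=dict)
    closeness_variant: str = "inverse_sum"
    contacts: list[ContactEdge] = field(default_factory=list)

    @property
    def nodes(self) -> list[Residue]:
        return list(self.graph.nodes)

    def neighbors(self, res: Residue) -> list[Residue]:
        return list(self.graph.neighbors(res))


def delaunay_edges(
    atoms: list[Atom],
    max_edge_length: float | None = DEFAULT_MAX_EDGE,
    jitter: bool = False,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Edge set (index pairs, i<j) of the Delaunay tessellation of the atoms.

    ``max_edge_length=None`` returns the raw tessellation edges.  Degenerate
    (e.g. coplanar) inputs raise unless ``jitter`` is set, in which case
    coordinates are perturbed by at most 1e-6 A using ``seed``.
    """
    if len(atoms) < 5:
        raise ValueError("Delaunay tessellation needs at least 5 atoms")
    coords = np.array([a.coords for a in atoms], dtype=float)
    if jitter:
        rng = np.random.default_rng(seed)
        coords = coords + rng.uniform(-1e-6, 1e-6, size=coords.shape)
    try:
        tri = Delaunay(coords)
    except QhullError as exc:
        raise ValueError(
            "degenerate atom coordinates for Delaunay tessellation; "
            "retry with jitter=True"
        ) from exc
    edges = set()
    for simplex in tri.simplices:
        for i, j in combinations(sorted(int(v) for v in simplex), 2):
            edges.add((i, j))
    if max_edge_length is not None:
        edges = {
            (i, j)
            for i, j in edges
            if np.linalg.norm(coords[i] - coords[j]) <= max_edge_length
        }
    return sorted(edges)


def _pair_types(a: Atom, b: Atom, dist: float, rules) -> frozenset[str]:
    types = set()
    for ctype, cls_a, cls_b, max_dist in rules:
        if dist > max_dist:
            continue
        if (cls_a in a.phys_classes and cls_b in b.phys_classes) or (
            cls_b in a.phys_classes and cls_a in b.phys_classes
        ):
            types.add(ctype)
    return frozenset(types)


def classify_contacts(
    atom_pairs: list[tuple[Atom, Residue, Atom, Residue]],
    rules=None,
    exclude_backbone_neighbors: bool = True,
) -> list[ContactEdge]:
    """Type the candidate atom pairs; pairs firing no rule are dropped.

    ``exclude_backbone_neighbors`` suppresses backbone-backbone pairs of
    sequence-adjacent residues, whose peptide-bond geometry would otherwise
    fire the hydrogen-bond rule for every consecutive residue pair.
    """
    rules = rules if rules is not None else atom_data.contact_rules()
    contacts = []
    n_dropped = 0
    for atom_i, res_i, atom_j, res_j in atom_pairs:
        if res_i is res_j:
            continue
        if (
            exclude_backbone_neighbors
            and res_i.chain_id == res_j.chain_id
            and abs(res_i.seq_number - res_j.seq_number) == 1
            and atom_i.name in atom_data.BACKBONE_ATOMS
            and atom_j.name in atom_data.BACKBONE_ATOMS
        ):
            continue
        dist = float(np.linalg.norm(atom_i.coords - atom_j.coords))
        types = _pair_types(atom_i, atom_j, dist, rules)
        if not types:
            n_dropped += 1
            continue
        contacts.append(
            ContactEdge(
                atom_i=atom_i, atom_j=atom_j,
                residue_i=res_i, residue_j=res_j,
                distance=dist, types=types,
            )
        )
    logger.debug("classified %d contacts (%d untyped pairs)", len(contacts), n_dropped)
    return contacts


def structure_contacts(
    structure: Structure,
    rules=None,
    max_edge_length: float | None = DEFAULT_MAX_EDGE,
    exclude_backbone_neighbors: bool = True,
    jitter: bool = False,
    seed: int = 0,
) -> list[ContactEdge]:
    """Delaunay edge detection + typing for one annotated structure."""
    atoms = structure.atoms
    owner = {id(a): r for r in structure.residues for a in r.atoms}
    edges = delaunay_edges(atoms, max_edge_length, jitter=jitter, seed=seed)
    pairs = [
        (atoms[i], owner[id(atoms[i])], atoms[j], owner[id(atoms[j])])
        for i, j in edges
    ]
    return classify_contacts(
        pairs, rules, exclude_backbone_neighbors=exclude_backbone_neighbors
    )


def residue_graph(
    contacts: list[ContactEdge],
    nodes: list[Residue] | None = None,
) -> ResidueGraph:
    """Collapse typed atomic contacts onto a simple undirected residue graph.

    ``nodes`` (typically all residues of the chain) preserves isolated
    residues; edge existence is type-agnostic, the typed contact list is
    retained for the contacts panel.
    """
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for c in contacts:
        g.add_edge(c.residue_i, c.residue_j)
    return ResidueGraph(graph=g, contacts=list(contacts))


def _indicator_betweenness(g: nx.Graph) -> dict:
    """Betweenness summing 1 per unordered pair whose SOME geodesic passes i."""
    nodes = list(g.nodes)
    dist = dict(nx.all_pairs_shortest_path_length(g))
    bet = {v: 0.0 for v in nodes}
    for idx_s, s in enumerate(nodes):
        for t in nodes[idx_s + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v is s or v is t:
                    continue
                if (
                    v in dist[s]
                    and t in dist[v]
                    and dist[s][v] + dist[v][t] == d_st
                ):
                    bet[v] += 1.0
    return bet


def centralities(
    rg: ResidueGraph,
    closeness: str = "inverse_sum",
    betweenness: str = "fractional",
) -> ResidueGraph:
    """Annotate the graph with degree, betweenness and closeness (in place).

    Betweenness ``fractional`` is the standard shortest-path betweenness
    (pair dependencies sigma_st(i)/sigma_st, endpoints excluded, each
    unordered pair once); ``indicator`` counts 1 whenever the node lies on
    any geodesic of the pair.  Closeness ``inverse_sum`` is 1/sum_j d_ij
    (component-restricted); ``mean_distance`` is the literal mean geodesic
    distance sum_j d_ij / n with n the graph size.
    """
    if closeness not in ("inverse_sum", "mean_distance"):
        raise ValueError(f"unknown closeness variant {closeness!r}")
    if betweenness not in ("fractional", "indicator"):
        raise ValueError(f"unknown betweenness mode {betweenness!r}")
    g = rg.graph
    n = g.number_of_nodes()
    rg.degree = {v: int(d) for v, d in g.degree()}
    if betweenness == "fractional":
        rg.betweenness = nx.betweenness_centrality(g, normalized=False)
    else:
        rg.betweenness = _indicator_betweenness(g)
    rg.closeness = {}
    rg.closeness_variant = closeness
    for v in g.nodes:
        dists = nx.single_source_shortest_path_length(g, v)
        total = float(sum(dists.values()))  # component-restricted, d_vv = 0
        if closeness == "inverse_sum":
            rg.closeness[v] = 1.0 / total if total > 0 else 0.0
        else:
            rg.closeness[v] = total / n if n else 0.0
    return rg
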