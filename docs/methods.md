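# Methods

This note records how each stage of the pipeline is computed, the knobs
that matter, and the design decisions taken where more than one
reasonable choice existed. All defaults live in plain TSV/config files
under `mutpanel/data` and in the stage signatures, and are user-overridable.

## Structure preparation

PDB files are parsed with gemmi. Only the first model of multi-model
files is kept; waters, unmappable HETATM groups and hydrogens are
dropped; alternate locations other than blank/'A' are discarded. A small
set of non-standard residues is mapped to its standard parent (MSE→MET
with SE→SD, SEC→CYS, PYL→LYS, the HIS protonation variants), so
downstream one-letter logic stays total; anything else marks the chain
unmappable. Cleanup then (1) treats every chain as its own structure,
(2) collapses chains with identical sequence *within the same entry* to
one representative — identical sequences from different entries are
distinct family members and are retained — and (3) excludes chains in
which any residue lacks one of its expected heavy atoms (the atom-typing
table doubles as the completeness reference; the terminal OXT is
optional). Survivors are ordered by source id so every later stage is
deterministic.

Atom annotation assigns per-element van der Waals radii (C 1.70, N 1.55,
O 1.52, S 1.80 Å) and per-(residue, atom) physicochemical classes:
positive (Lys NZ, Arg NE/NH1/NH2, His ring N treated as positive because
protonation is unknown), negative (Asp/Glu carboxylates, OXT), aromatic
(Phe/Tyr/Trp/His ring atoms), hydrophobic (carbon and thioether atoms not
bonded to N/O), donor/acceptor per standard backbone and side-chain
chemistry. Atoms missing from the table get an empty class set and a
logged warning — they still occupy volume for SASA and tessellation.

## Solvent accessibility

Per-atom SASA uses Shrake–Rupley sphere sampling: each vdW sphere is
inflated by the probe radius (default 1.4 Å, water) and covered with a
deterministic Fibonacci lattice (default 960 points; no RNG, so outputs
are bit-reproducible). A point is buried if it falls inside any
neighbouring inflated sphere; the accessible area is the exposed fraction
times the sphere area. Residue areas are exact sums of their atoms'.
At 960 points the quadrature resolution is about 0.13 Å² per lattice
cell; agreement with closed-form single-sphere and two-sphere solutions
is at the 1–2 % level (tested), and refining 960→4000 points moves
per-residue areas by well under 2 %.

Relative accessibility divides by the same residue's area in an extended
Ala-X-Ala tripeptide. The shipped reference table was computed once with
the package's own tripeptide builder (φ = ψ = 180°, χ₁ = −60°, probe
1.4 Å, 4000 points), making the percentage internally consistent with the
pipeline's SASA convention; the values run some 10–20 % below
conformer-maximum tables (e.g. Tien et al. 2013), which is expected for a
single fixed conformation, and the table is swappable if a user prefers a
published convention. Values above 100 % (e.g. chain termini) are
reported as computed, never clipped.

## Contact network and centralities

Candidate atomic contacts are the edges of the 3-D Delaunay tessellation
of all heavy atoms (scipy/Qhull), a cutoff-independent neighbour
definition. Two filters follow:

- **Edge-length cap** (`max_edge_length`, default 8 Å). Spurious long
  edges arise between surface atoms across empty space; in an explicit-
  solvent setup water molecules would break these tetrahedra. The cap
  implements the same intent without a solvent model.
- **Adjacent-backbone exclusion** (`exclude_backbone_neighbors`, default
  on). The peptide bond places N(i+1) ~2.2 Å from O(i), so every
  consecutive residue pair would otherwise fire the hydrogen-bond rule;
  these are covalent-geometry artifacts, not interactions. Only
  backbone–backbone pairs of sequence-adjacent residues are suppressed —
  genuine i,i+4 helical hydrogen bonds and side-chain contacts of
  neighbours survive.

Each remaining inter-residue pair is tested against distance-gated class
rules (heavy-atom distances): charged attractive, positive×negative
≤ 6 Å; charged repulsive, like×like charges ≤ 6 Å; aromatic,
aromatic×aromatic ≤ 6 Å; hydrophobic, hydrophobic×hydrophobic ≤ 4.5 Å;
hydrogen bond, donor×acceptor ≤ 3.5 Å. A pair may carry several types;
pairs firing no rule are dropped. The residue graph keeps a single,
type-agnostic edge wherever at least one typed atomic contact joins two
residues (the typed list is retained for the contacts panel).

Centralities on the residue graph:

- degree — row sums of the adjacency;
- betweenness — standard fractional shortest-path betweenness
  (pair dependencies σ_st(i)/σ_st, endpoints excluded, each unordered
  pair counted once, equivalent to counting both directions and halving).
  A 0/1 indicator definition ("node lies on *some* geodesic") is
  ill-defined as a per-path indicator when geodesics are multiple; it is
  available as `betweenness="indicator"` for comparison;
- closeness — default `inverse_sum`, `c_i = 1/Σ_j d_ij`; this matches the
  10⁻³–10⁻⁴ magnitude of the closeness columns in the packaged prediction
  tables for ~250-residue chains, whereas the mean geodesic distance
  `l_i = (1/n) Σ_j d_ij` (also provided, with the literal denominator n)
  is O(1)–O(10). For disconnected graphs sums run over the node's
  component; isolated nodes get closeness 0.

Tests verify all measures against an independent Floyd–Warshall +
path-enumeration oracle on random graphs.

## Column profiles, mutation calling and the manual rule

Alignment columns are structurally equivalent positions; rows are family
members, the mutant first and the reference (wild type) second. Mutations
are substitution columns only — both rows non-gap and different; indels
are out of scope. Labels use the reference's own ungapped 1-based
numbering ("I20A" style).

Per column: residue frequencies over all non-gap rows (the mutant row
included — the denominator question is genuinely open; including it is
the literal reading and changes frequencies by ~1/n_rows); property
averages over the rows with a mapped residue; an `is_active_site` flag if
the reference residue is in the user-supplied active-site list (entries
like "N10" are validated against the reference sequence), and a
`contacts_active_site` flag if the reference residue has a graph edge to
any active-site residue.

Conservativeness uses three standard colour-scheme groupings: CINEMA
(polar positive HKR, polar negative DE, polar neutral NQST, aliphatic
AGILMV, ring FPWY, cysteine C), CLUSTAL (GPST / HKR / FWY / ILMV, the
rest ungrouped: two ungrouped residues are non-conservative unless
identical) and LESK (AGST / CFILMPVWY / HNQ / DE / KR). Identity is
always conservative.

Rarity bands the mutant residue's column frequency: very rare < 2 %,
rare < 10 %, else frequent. The qualitative categories are standard; the
numeric boundaries are this package's defaults and are config-exposed.
The manual rule keeps non-conservative, rare-or-very-rare mutations and
sorts them by descending average degree, then descending average
betweenness, then ascending average accessibility (ties: lowest column).

## GA fitness and operators

`T_i = (1 − Res_freq) + (1 − Score) + (1 − SRM)` with `Score` the min–max
normalized PAM250 entry ((s − s_min)/(s_max − s_min) over the 20×20
standard submatrix: −8 at C/W, +17 at W/W) and `SRM` the mean of the four
property ratios `X_avg/X_max`. Decisions taken here:

- **`*_max` scope.** "The highest average of each parameter" is read as a
  per-dataset maximum over all mutated columns; a per-column reading
  would make every ratio 1. Any all-zero property across the mutated
  columns is a hard error rather than a silent 0/0.
- **The /4 in SRM.** The four ratios sum to at most 4; dividing by 4
  keeps SRM — and hence each of the three T_i terms — in [0, 1] and
  T_i in [0, 3].
- **Literal vs corrected orientation.** As written, `1 − SRM` is largest
  for columns with *low* accessibility and *low* centrality. Low
  accessibility raising the danger score is right; low centrality raising
  it contradicts the premise that buried, highly connected residues are
  the dangerous ones. Because both readings are defensible the package
  computes both: `literal` (default, the formula as printed) and
  `corrected`, where SRM uses `1 − Acc_avg/Acc_max` for the accessibility
  term and T_i takes `+ SRM`. Pipeline runs report the two side by side.

The GA itself: random initial population of valid N-subsets of the
mutated columns; per generation, the top ⌈clone_rate·pop⌉ individuals are
copied unchanged (elitism — clones skip mutation, which makes the
best-of-generation fitness provably non-decreasing), and the rest of the
next generation is bred by tournament selection (size K, best fitness
wins), uniform set crossover (deal the shuffled union of the parents'
genes alternately into two children, top up with random unused columns)
and per-gene replacement mutation. All randomness flows from one seeded
generator; ties (tournament, elitist ranking, best-of-run) break toward
the lexicographically smallest gene tuple, so runs are exactly
reproducible. Defaults: population 100, 200 generations, K = 3, crossover
0.9, mutation 0.05, cloning 0.05.

## Panel exports

Exports are data contracts, not pixels: colour codes are scheme-group
labels, heatmap cells carry raw values with per-layer min/max for
client-side scaling, gap cells are null, and every non-gap cell has a
details record (residue, alignment column, original sequence position,
all computed parameters). Contact records are keyed by alignment columns
of the reference chain and can be sliced in the three panel modes (one
type × one column, all types × one column, one type × all columns).
`validate_bundle` enforces the structural invariants (dimensions,
cell-by-cell agreement between panels, layer min/max consistency).
Pipeline outputs are JSON with sorted keys; two runs with the same config
and seed are byte-identical (the manifest, which carries a timestamp, is
a separate file). Interactive behaviours (zoom, scroll, expansion) are
client concerns with no export counterpart.

## Synthetic data: what it emulates, what it does not

Toy chains are grown on ideal internal coordinates (N–CA 1.458, CA–C
1.525, C–N 1.329 Å; standard angles; ω trans) as α-helices (φ −57°,
ψ −47°; ≈1.5 Å rise and ≈100°/residue) or extended strands (φ = ψ =
180°), with full heavy-atom side chains grafted from biotite's bundled
ideal-coordinate residue templates onto each N/CA/C frame and set to the
most common rotamer (χ₁ = −60°). Full side chains are used — rather than
a single representative atom — so the fixtures satisfy the same
missing-atom rule as real chains and exercise every contact rule.
Families are sampled with *exact* per-column residue counts (not
multinomially), so frequency-dependent expectations in tests are exact.
Planted GA instances construct k mutated columns whose partial fitness
provably dominates all decoys (rare, heavily penalized G→W exchanges on
structurally quiet columns vs frequent, well-scoring I→L exchanges on
columns at the property maxima), with the optimum's fitness evaluated by
direct arithmetic, independent of the GA code path.

These fixtures are single-rotamer, idealized, ~10–30-residue chains with
families of ~10 rows: they validate the computations, determinism and
selection logic, not biological realism. Passing tests say nothing about
rotamer diversity, loop geometry, multi-chain interfaces, alignment
quality or family sizes in the hundreds. The two packaged 22-row
prediction tables are fixed published-style records used for set-level
checks (cardinality, overlap), not recomputed from structures.

## Problem sizes in tests

The suite and the acceptance script run at desk scale by design:
centrality oracles on 100 random graphs of ≤ 12 nodes; Delaunay oracles
on 20 clouds of 50 points (checked against an exact bisector-plane
clipping feasibility test); GA studies with populations of 20 over 50
generations and 20 seeds on 6–10 mutated columns; the end-to-end study on
a 12-member family of 24-residue chains. A full-size run (hundreds of
chains of ~250 residues) is a few minutes of SASA and tessellation per
chain and is embarrassingly parallel across chains.

## Known limitations

- Protonation states are not predicted; His is treated as positive.
- The atom-class table is a documented, user-overridable convention;
  published contact-typing criteria differ in detail.
- SASA is solvent-accessible (not molecular) surface, and the reference
  tripeptide is one fixed conformation.
- The residue graph is unweighted and type-agnostic; no eigenvector or
  weighted centralities.
- The GA's fitness terms are equally weighted; learning weights is out
  of scope, as is any alternative metaheuristic.
- Computing the structure-based alignment itself is out of scope; the
  aligned FASTA is an input.
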