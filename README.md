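# mutpanel

Structure-based profiling and prioritization of point mutations in protein
families.

Given a set of cleaned protein structures and a structure-based multiple
sequence alignment whose first two rows are a mutant and its wild-type
reference, `mutpanel` asks: **which of the mutant's substitutions are
likely to damage protein function?** It answers by combining, per
alignment column, family conservation with structural features of the
corresponding residues — solvent accessibility and contact-network
centralities — and by prioritizing candidates with both a transparent
rule-based filter and a genetic algorithm. The machine-readable exports
mirror three interactive panels (colour-coded alignment, typed contacts,
property heatmap) so that a front-end can render them directly.

## The quantities at the core

For each chain the pipeline computes:

- **Relative solvent accessibility** `acc_i = 100 · SASA_i / SASA_ref(aa_i)`,
  where SASA is obtained by Shrake–Rupley sphere sampling (probe 1.4 Å,
  deterministic Fibonacci lattice) and the reference is the same residue's
  area in an extended Ala-X-Ala tripeptide.
- **A residue interaction network** whose candidate atomic contacts are the
  edges of the 3-D Delaunay tessellation of the heavy atoms (capped at
  8 Å), classified as charged attractive / charged repulsive / aromatic /
  hydrophobic / hydrogen bond from per-atom physicochemical classes and
  distance rules, then collapsed to residue level. On this graph:
  degree `k_i = Σ_j A_ij`; betweenness `x_i = Σ_{s<t} σ_st(i)/σ_st`
  (endpoints excluded); closeness `c_i = 1 / Σ_j d_ij` (a mean-distance
  variant `l_i = (1/n) Σ_j d_ij` is also available).

Columns aggregate these over the family (`Acc_avg`, `Deg_avg`, `Bet_avg`,
`Clo_avg`) together with residue frequencies. A substitution at column *i*
contributes the partial fitness

```
T_i = (1 − Res_freq) + (1 − Score) + (1 − SRM)
SRM = ( Acc_avg/Acc_max + Deg_avg/Deg_max + Bet_avg/Bet_max + Clo_avg/Clo_max ) / 4
```

where `Res_freq` is the family frequency of the mutant residue in the
column, `Score` the min–max normalized PAM250 score of the exchange, and
the `*_max` are the largest column averages over all mutated columns. The
GA maximizes `Fitness = Σ_i T_i` over sets of N mutated columns
(tournament selection, elitist cloning, uniform set crossover, per-gene
replacement mutation). As printed above, `1 − SRM` rewards *low*
centrality; a `corrected` mode that inverts the structural term (buried,
highly connected columns score high) is computed alongside — see
`docs/methods.md`.

The rule-based filter keeps substitutions that are **non-conservative**
(CINEMA / CLUSTAL / LESK residue groupings) and **rare or very rare** in
the family, sorted by structural importance (high degree, high
betweenness, low accessibility).

## Worked example

The package ships a synthetic-study generator so the whole pipeline runs
without downloads: a 12-member family of 24-residue helical toy proteins
in which the mutant carries three planted substitutions.

```python
from mutpanel import synth_fixtures, viz_export

config = synth_fixtures.make_pipeline_dataset("demo", seed=1)
result = viz_export.run_pipeline(config)

for m in result.mutations:
    print(f"{m.label}: conservative(CINEMA)={m.conservative_by_scheme['CINEMA']}, "
          f"rarity={m.rarity}")
print("manual selection:", [m.label for m in result.manual_selection])
print(f"GA (literal): fitness={result.ga_literal['fitness']:.4f}, "
      f"genes={[g['label'] for g in result.ga_literal['genes']]}")
```

prints

```
L4K: conservative(CINEMA)=False, rarity=rare
A8G: conservative(CINEMA)=True, rarity=rare
E20Q: conservative(CINEMA)=False, rarity=frequent
manual selection: ['L4K']
GA (literal): fitness=4.8829, genes=['L4K', 'A8G', 'E20Q']
```

Exactly as designed into the dataset: L4K is rare in the family and
crosses physicochemical groups, so the manual rule keeps it; A8G is a
conservative aliphatic exchange and E20Q is common among the relatives,
so both are dropped. The GA, asked for the best 3-column set of the 3
mutated columns, reports their summed partial fitness. All panel exports,
profiles and the run manifest are written under `demo/out/`.

The same stages are available from the shell via the `mutpanel` console
script (`prep`, `sasa`, `contacts`, `net`, `profile`, `ga`, and `run
--config run.toml` for the whole pipeline).

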