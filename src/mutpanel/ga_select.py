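"""Genetic-algorithm selection of potentially harmful mutation sets.

A candidate solution is a set of N distinct mutated alignment columns.
Each column i contributes a partial fitness

    T_i = (1 - Res_freq) + (1 - Score) + (1 - SRM)          (literal mode)

where Res_freq is the family frequency of the mutant residue in the
column, Score the min-max normalized PAM250 substitution score of the
reference -> mutant exchange, and SRM the structural term combining the
column-average relative accessibility, degree, betweenness and closeness,
each normalized by the highest column average of that property across all
mutated columns, then divided by 4 so SRM (and hence every T_i term) lies
in [0, 1].  As printed, the (1 - SRM) term rewards LOW centrality, which
contradicts the stated rationale that buried, highly central residues are
the dangerous ones; a ``corrected`` mode flips the structural term
(accessibility inverted inside SRM and + SRM in T_i) and is reported side
by side.  Total fitness is the sum of T_i over the solution's columns and
is maximized by a steady-state GA with tournament selection, elitist
cloning, uniform set crossover and per-gene replacement mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .family_align import AA20, ColumnProfile, Mutation

__all__ = [
    "GAConfig",
    "GASolution",
    "NormalizationContext",
    "pam250",
    "build_context",
    "normalized_substitution_score",
    "compute_srm",
    "partial_fitness",
    "fitness",
    "run_ga",
]


@dataclass(frozen=True)
class GAConfig:
    n_positions: int
    population_size: int = 100
    generations: int = 200
    tournament_k: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    clone_rate: float = 0.05
    seed: int = 0
    fitness_mode: str = "literal"  # or "corrected"
    substitution_matrix: str = "PAM250"

    def __post_init__(self):
        if self.n_positions < 1:
            raise ValueError("n_positions must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.tournament_k < 1:
            raise ValueError("tournament_k must be >= 1")
        for name in ("crossover_rate", "mutation_rate", "clone_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fitness_mode not in ("literal", "corrected"):
            raise ValueError(f"unknown fitness mode {self.fitness_mode!r}")


@dataclass
class GASolution:
    genes: tuple[int, ...]  # sorted, distinct mutated-column indices
    fitness: float = 0.0
    partials: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        genes = tuple(sorted(self.genes))
        if len(set(genes)) != len(genes):
            raise ValueError("solution genes must be distinct")
        self.genes = genes


@dataclass(frozen=True)
class NormalizationContext:
    acc_max: float
    deg_max: float
    bet_max: float
    clo_max: float
    pam_min: float
    pam_max: float

    def __post_init__(self):
        for name in ("acc_max", "deg_max", "bet_max", "clo_max"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"{name} must be > 0 (degenerate all-zero property column)"
                )


_PAM_CACHE: dict[str, dict[tuple[str, str], float]] = {}


def pam250(name: str = "PAM250") -> dict[tuple[str, str], float]:
    """Substitution matrix restricted to the 20 standard residues."""
    if name not in _PAM_CACHE:
        mat = substitution_matrices.load(name)
        _PAM_CACHE[name] = {
            (a, b): float(mat[a][b]) for a in AA20 for b in AA20
        }
    return _PAM_CACHE[name]


def build_context(
    profiles: list[ColumnProfile],
    mutations: list[Mutation],
    matrix: str = "PAM250",
) -> NormalizationContext:
    """Per-dataset maxima of the four properties over all mutated columns."""
    cols = {m.column for m in mutations}
    selected = [p for p in profiles if p.column in cols]
    if not selected:
        raise ValueError("no profiles for mutated columns")

    def prop_max(key):
        vals = [getattr(p, key) for p in selected if getattr(p, key) is not None]
        return max(vals) if vals else 0.0

    scores = pam250(matrix).values()
    return NormalizationContext(
        acc_max=prop_max("acc_avg"),
        deg_max=prop_max("deg_avg"),
        bet_max=prop_max("bet_avg"),
        clo_max=prop_max("clo_avg"),
        pam_min=min(scores),
        pam_max=max(scores),
    )


def normalized_substitution_score(
    a: str, b: str, ctx: NormalizationContext, matrix: str = "PAM250"
) -> float:
    """Min-max normalized substitution score in [0, 1] (1 = most favorable)."""
    if a not in AA20 or b not in AA20:
        raise ValueError(f"unknown residue in pair ({a!r}, {b!r})")
    s = pam250(matrix)[(a, b)]
    return (s - ctx.pam_min) / (ctx.pam_max - ctx.pam_min)


def compute_srm(
    profile: ColumnProfile, ctx: NormalizationContext, mode: str = "literal"
) -> float:
    """Structural term of the partial fitness, in [0, 1].

    ``literal``: mean of the four normalized column averages.  ``corrected``:
    the accessibility ratio is inverted (buried columns score high) before
    averaging.
    """
    acc = (profile.acc_avg or 0.0) / ctx.acc_max
    deg = (profile.deg_avg or 0.0) / ctx.deg_max
    bet = (profile.bet_avg or 0.0) / ctx.bet_max
    clo = (profile.clo_avg or 0.0) / ctx.clo_max
    if mode == "literal":
        return (acc + deg + bet + clo) / 4.0
    if mode == "corrected":
        return ((1.0 - acc) + deg + bet + clo) / 4.0
    raise ValueError(f"unknown fitness mode {mode!r}")


def partial_fitness(
    profile: ColumnProfile,
    mutation: Mutation,
    ctx: NormalizationContext,
    mode: str = "literal",
    matrix: str = "PAM250",
) -> float:
    """T_i of one mutated column; lies in [0, 3] in both modes."""
    score = normalized_substitution_score(mutation.ref_aa, mutation.mut_aa, ctx, matrix)
    srm = compute_srm(profile, ctx, mode)
    structural = (1.0 - srm) if mode == "literal" else srm
    return (1.0 - profile.res_freq_mut) + (1.0 - score) + structural


def fitness(
    solution: GASolution,
    profiles: list[ColumnProfile],
    mutations: list[Mutation],
    ctx: NormalizationContext,
    mode: str = "literal",
    matrix: str = "PAM250",
) -> GASolution:
    """Evaluate a solution: fitness = sum of T_i; partials stored per gene."""
    prof_by_col = {p.column: p for p in profiles}
    mut_by_col = {m.column: m for m in mutations}
    partials = {}
    for col in solution.genes:
        if col not in mut_by_col:
            raise ValueError(f"gene {col} is not a mutated column")
        partials[col] = partial_fitness(
            prof_by_col[col], mut_by_col[col], ctx, mode, matrix
        )
    solution.partials = partials
    solution.fitness = float(sum(partials.values()))
    return solution


def _better(a: GASolution, b: GASolution) -> GASolution:
    """Deterministic comparison: higher fitness, ties to smaller gene tuple."""
    if a.fitness != b.fitness:
        return a if a.fitness > b.fitness else b
    return a if a.genes <= b.genes else b


def _tournament(pop: list[GASolution], k: int, rng: np.random.Generator) -> GASolution:
    picks = rng.integers(0, len(pop), size=k)
    best = pop[picks[0]]
    for idx in picks[1:]:
        best = _better(best, pop[idx])
    return best


def _fill(genes: set[int], n: int, columns: tuple[int, ...], rng) -> tuple[int, ...]:
    unused = [c for c in columns if c not in genes]
    while len(genes) < n:
        pick = unused.pop(int(rng.integers(0, len(unused))))
        genes.add(pick)
    return tuple(sorted(genes))


def _crossover(
    p1: GASolution, p2: GASolution, n: int, columns, rng
) -> tuple[set[int], set[int]]:
    """Uniform set crossover: deal the shuffled union alternately."""
    union = sorted(set(p1.genes) | set(p2.genes))
    order = rng.permutation(len(union))
    c1: set[int] = set()
    c2: set[int] = set()
    for rank, idx in enumerate(order):
        (c1 if rank % 2 == 0 else c2).add(union[idx])
    # alternate dealing of a union of <= 2n genes never overfills a child,
    # but guard against n shrinking between calls
    for child in (c1, c2):
        while len(child) > n:
            child.pop()
    return c1, c2


def _mutate(genes: tuple[int, ...], rate: float, columns, rng) -> tuple[int, ...]:
    gene_set = set(genes)
    for g in genes:
        if rng.random() < rate:
            unused = [c for c in columns if c not in gene_set]
            if not unused:
                continue
            gene_set.remove(g)
            gene_set.add(unused[int(rng.integers(0, len(unused)))])
    return tuple(sorted(gene_set))


def run_ga(
    config: GAConfig,
    profiles: list[ColumnProfile],
    mutations: list[Mutation],
    ctx: NormalizationContext | None = None,
    history: list[float] | None = None,
) -> GASolution:
    """Run the GA and return the best individual of the final generation.

    Loop: random initial population; per generation, elitist clones plus
    offspring from tournament-selected parents and crossover; replacement
    mutation applied to offspring (clones are copied unchanged); fully
    deterministic under ``config.seed``.  ``history``, if given, collects
    the best fitness of each generation (including the initial one).
    """
    columns = tuple(sorted({m.column for m in mutations}))
    n = config.n_positions
    if n > len(columns):
        raise ValueError(
            f"n_positions={n} exceeds the {len(columns)} mutated columns"
        )
    if ctx is None:
        ctx = build_context(profiles, mutations, config.substitution_matrix)
    rng = np.random.default_rng(config.seed)
    mode, matrix = config.fitness_mode, config.substitution_matrix

    def evaluate(sol: GASolution) -> GASolution:
        return fitness(sol, profiles, mutations, ctx, mode, matrix)

    pop = [
        evaluate(
            GASolution(
                tuple(
                    columns[i]
                    for i in rng.choice(len(columns), size=n, replace=False)
                )
            )
        )
        for _ in range(config.population_size)
    ]

    def best_of(population):
        best = population[0]
        for sol in population[1:]:
            best = _better(best, sol)
        return best

    if history is not None:
        history.append(best_of(pop).fitness)

    n_clones = int(np.ceil(config.clone_rate * config.population_size))
    for _ in range(config.generations):
        ranked = sorted(pop, key=lambda s: (-s.fitness, s.genes))
        new_pop: list[GASolution] = [
            GASolution(sol.genes) for sol in ranked[:n_clones]
        ]
        while len(new_pop) < config.population_size:
            p1 = _tournament(pop, config.tournament_k, rng)
            p2 = _tournament(pop, config.tournament_k, rng)
            if rng.random() < config.crossover_rate:
                g1, g2 = _crossover(p1, p2, n, columns, rng)
            else:
                g1, g2 = set(p1.genes), set(p2.genes)
            for genes in (g1, g2):
                if len(new_pop) >= config.population_size:
                    break
                child = _fill(set(genes), n, columns, rng)
                child = _mutate(child, config.mutation_rate, columns, rng)
                new_pop.append(GASolution(child))
        # clones are elitist copies and skip mutation (first n_clones entries)
        pop = [evaluate(sol) for sol in new_pop]
        if history is not None:
            history.append(best_of(pop).fitness)
    return best_of(pop)
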