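"""Design of minimal degenerate RBS libraries by genetic-algorithm search.

The design problem is mini-max: a degenerate RBS sequence should *maximize*
the coverage C of a targeted translation-rate range — the log10 rate space
between r_min and r_max is discretized into bins of width W (the search
resolution), and a bin is "filled" when at least one library variant's
predicted rate lands in its window — while *minimizing* the number of
variants N in the library.  Both criteria combine into one objective,

    F = C - 0.02 * N,

whose maximum, 1 - 0.02 * B_total, is attained when every bin is filled by
exactly one variant.

A genetic algorithm evolves a population of degenerate sequences through
mutation, recombination and fitness-proportional selection with the operator
schedule: 40% recombination, 15% degeneracy increase, 15% degeneracy
decrease, 15% non-degenerate substitution, 10% unmodified elites, 5% fresh
random sequences.  Three modes are supported: Search (wide range), Zoom
(narrowed range, finer resolution — a pure re-parameterization) and Genome
Editing (candidates must differ from a wild-type RBS only within one short
contiguous window, so the library is reachable by few adjacent genomic
mutations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import degenerate as dg
from .biophysics import (
    FoldingEngine,
    MRNAContext,
    RibosomeModel,
    predict_library_rates,
)
from .degenerate import DegenerateSequence, NoOpEditError

__all__ = [
    "DesignSpec",
    "BinGrid",
    "LibrarySolution",
    "total_bins",
    "coverage",
    "objective",
    "optimize",
    "genome_edit_feasible",
    "multi_dim_coverage",
    "monte_carlo_coverage",
    "OPERATOR_SCHEDULE",
    "draw_operator",
    "VARIANT_WEIGHT",
]

#: Weight of the library-size term in the objective F = C - weight * N.
VARIANT_WEIGHT = 0.02

#: GA operator schedule (operator -> draw probability).
OPERATOR_SCHEDULE: dict[str, float] = {
    "recombine": 0.40,
    "increase_degeneracy": 0.15,
    "decrease_degeneracy": 0.15,
    "substitute": 0.15,
    "elite": 0.10,
    "fresh_random": 0.05,
}

_OPS = tuple(OPERATOR_SCHEDULE)
_OP_P = np.array([OPERATOR_SCHEDULE[o] for o in _OPS])


def draw_operator(rng: np.random.Generator) -> str:
    """Draw one GA operator according to the fixed schedule."""
    return _OPS[rng.choice(len(_OPS), p=_OP_P)]


# -- binning and coverage ----------------------------------------------------

def total_bins(r_min: float, r_max: float, W: float) -> int:
    """Number of log10 bins covering [r_min, r_max] at resolution W."""
    if not (0 < r_min < r_max):
        raise ValueError("require 0 < r_min < r_max")
    if W <= 0:
        raise ValueError("search resolution W must be positive")
    span = math.log10(r_max / r_min)
    # guard against float noise when span is an exact multiple of W
    return max(1, math.ceil(round(span / W, 9)))


@dataclass(frozen=True)
class BinGrid:
    """Log-spaced coverage bins: centers y_k = r_min * 10^(W*(k+1/2)).

    A bin at position y is filled by a rate r iff y/10^W <= r <= y*10^W
    (boundaries inclusive); windows of adjacent bins overlap by construction,
    so one rate may fill several bins.
    """

    r_min: float
    r_max: float
    W: float

    @property
    def B_total(self) -> int:
        return total_bins(self.r_min, self.r_max, self.W)

    @property
    def centers(self) -> np.ndarray:
        k = np.arange(self.B_total)
        return self.r_min * 10.0 ** (self.W * (k + 0.5))

    def filled_mask(self, rates: Sequence[float]) -> np.ndarray:
        """Boolean mask over bins: filled by at least one of ``rates``."""
        mask = np.zeros(self.B_total, dtype=bool)
        if len(rates) == 0:
            return mask
        log_c = np.log10(self.centers)
        eps = 1e-9  # boundary ties count as filled
        for r in rates:
            if r <= 0:
                continue
            mask |= np.abs(math.log10(r) - log_c) <= self.W + eps
        return mask

    def bins_filled_by(self, rate: float) -> list[int]:
        return list(np.nonzero(self.filled_mask([rate]))[0])


def coverage(rates: Sequence[float], grid: BinGrid) -> float:
    """Fraction of grid bins filled by at least one rate; in [0, 1]."""
    return float(grid.filled_mask(rates).sum()) / grid.B_total


def objective(C: float, n_variants: int, weight: float = VARIANT_WEIGHT) -> float:
    """Mini-max objective F = C - weight * N_variants."""
    if not (0.0 <= C <= 1.0):
        raise ValueError("coverage must lie in [0, 1]")
    if n_variants < 1:
        raise ValueError("a library has at least one variant")
    return C - weight * n_variants


# -- design spec and solutions -----------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """User-facing specification of one library-design run."""

    mode: str = "search"               # search | zoom | genome_edit
    r_min: float = 10.0
    r_max: float = 100000.0
    resolution_W: float = 0.30
    population_size: int = 100
    max_iterations: int = 500
    stagnation_limit: int = 50
    seed: int = 0
    wild_type_rbs: str | None = None   # genome_edit only
    max_window: int = 12               # genome_edit only, nt
    rbs_length: int = 35
    expand_limit: int = 10**4          # candidate libraries above this are subsampled

    def __post_init__(self) -> None:
        if self.mode not in ("search", "zoom", "genome_edit"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.10 <= self.r_min < self.r_max):
            raise ValueError("require 0.10 <= r_min < r_max")
        if self.resolution_W <= 0:
            raise ValueError("resolution_W must be positive")
        if self.mode == "genome_edit" and not self.wild_type_rbs:
            raise ValueError("genome_edit mode requires wild_type_rbs")

    @property
    def grid(self) -> BinGrid:
        return BinGrid(self.r_min, self.r_max, self.resolution_W)

    @property
    def max_objective(self) -> float:
        return 1.0 - VARIANT_WEIGHT * self.grid.B_total


@dataclass
class LibrarySolution:
    """One designed degenerate RBS with its audit trail."""

    dseq: DegenerateSequence
    variant_rates: dict[str, float]
    coverage_C: float
    n_variants: int
    objective_F: float
    exhaustive: bool = True
    range_reached: bool = True
    window: tuple[int, int] | None = None   # genome_edit mutation window

    def as_row(self) -> dict:
        return {
            "degenerate_rbs": self.dseq.letters,
            "n_variants": self.n_variants,
            "coverage": self.coverage_C,
            "objective": self.objective_F,
        }


# -- genome-editing feasibility ----------------------------------------------

def genome_edit_feasible(
    candidate: DegenerateSequence | str,
    wild_type: str,
    max_window: int,
) -> tuple[bool, tuple[int, int]]:
    """Whether all candidate/wild-type differences fit one contiguous window.

    A position differs when the candidate letter is not identical to the
    wild-type base (degeneracy relative to the wild type counts as a
    difference).  Returns (feasible, (start, stop)) with the minimal 0-based
    half-open window; the window is (0, 0) when the candidate equals the wild
    type.
    """
    cand = candidate.letters if isinstance(candidate, DegenerateSequence) else dg._normalize(candidate)
    wt = dg._normalize(wild_type)
    if len(cand) != len(wt):
        raise ValueError(f"candidate length {len(cand)} != wild-type length {len(wt)}")
    diffs = [i for i, (a, b) in enumerate(zip(cand, wt)) if a != b]
    if not diffs:
        return True, (0, 0)
    window = (diffs[0], diffs[-1] + 1)
    return (window[1] - window[0]) <= max_window, window


# -- the genetic algorithm ---------------------------------------------------

RateFunction = Callable[[DegenerateSequence], "tuple[dict[str, float], bool]"]


def _default_rate_fn(
    context: MRNAContext,
    model: RibosomeModel,
    engine: FoldingEngine,
    limit: int,
    rng: np.random.Generator,
    cache: dict[str, float],
) -> RateFunction:
    def fn(dseq: DegenerateSequence) -> tuple[dict[str, float], bool]:
        lr = predict_library_rates(context, dseq, model, engine,
                                   limit=limit, rng=rng, cache=cache)
        return lr.rates, lr.exhaustive
    return fn


def optimize(
    spec: DesignSpec,
    context: MRNAContext | None = None,
    model: RibosomeModel | None = None,
    engine: FoldingEngine | None = None,
    rate_fn: RateFunction | None = None,
    rng: np.random.Generator | None = None,
    n_solutions: int = 5,
    progress: Callable[[int, float], None] | None = None,
) -> list[LibrarySolution]:
    """Run the library-design genetic algorithm; returns the top solutions.

    The population is initialized from random non-degenerate RBS sequences
    (or from the wild-type RBS in genome-editing mode).  Each generation a
    new population of ``population_size`` is bred by drawing operators from
    the fixed schedule with fitness-proportional parent selection; the best
    sequence found so far is always carried over (elitism), so the best
    objective is non-decreasing.  Termination: the objective maximum
    1 - 0.02*B_total is reached, the best objective stagnates for
    ``stagnation_limit`` generations, or ``max_iterations`` generations pass.

    ``rate_fn`` maps a degenerate sequence to (variant -> rate, exhaustive);
    when omitted it is built from (context, model, engine).  Injecting it
    decouples the search from any folding engine, e.g. for tests.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if rate_fn is None:
        if context is None or model is None or engine is None:
            raise ValueError("provide either rate_fn or (context, model, engine)")
        rate_fn = _default_rate_fn(context, model, engine, spec.expand_limit, rng, {})

    grid = spec.grid
    length = len(spec.wild_type_rbs) if spec.mode == "genome_edit" else spec.rbs_length
    wild_type = dg._normalize(spec.wild_type_rbs) if spec.wild_type_rbs else None

    eval_cache: dict[str, tuple[float, int, float, dict[str, float], bool]] = {}

    def evaluate(d: DegenerateSequence):
        hit = eval_cache.get(d.letters)
        if hit is None:
            rates, exhaustive = rate_fn(d)
            C = coverage(list(rates.values()), grid)
            n = dg.count_variants(d)
            F = objective(C, n)
            hit = (F, n, C, rates, exhaustive)
            eval_cache[d.letters] = hit
        return hit

    def feasible(d: DegenerateSequence) -> bool:
        if spec.mode != "genome_edit":
            return True
        ok, _ = genome_edit_feasible(d, wild_type, spec.max_window)
        return ok

    # --- init population
    if spec.mode == "genome_edit":
        population = [DegenerateSequence(wild_type) for _ in range(spec.population_size)]
    else:
        population = [dg.random_concrete_sequence(length, rng)
                      for _ in range(spec.population_size)]
    fitness = np.array([evaluate(d)[0] for d in population])

    # archive of the best distinct sequences seen
    archive: dict[str, float] = {}

    def archive_update(pop, fits):
        for d, f in zip(pop, fits):
            prev = archive.get(d.letters)
            if prev is None or f > prev:
                archive[d.letters] = f

    archive_update(population, fitness)
    best_F = float(fitness.max())
    best_seq = population[int(fitness.argmax())]
    stagnant = 0

    def select(k: int) -> list[DegenerateSequence]:
        w = fitness - fitness.min() + 1e-9
        p = w / w.sum()
        idx = rng.choice(len(population), size=k, p=p, replace=True)
        return [population[i] for i in idx]

    for generation in range(spec.max_iterations):
        if best_F >= spec.max_objective - 1e-12:
            break
        new_pop: list[DegenerateSequence] = [best_seq]  # elitism
        attempts = 0
        while len(new_pop) < spec.population_size:
            attempts += 1
            if attempts > 50 * spec.population_size:  # pathological feasibility
                new_pop.append(best_seq)
                continue
            op = draw_operator(rng)
            try:
                if op == "recombine":
                    a, b = select(2)
                    child = dg.edit(a, "recombine", rng, partner=b)
                elif op == "elite":
                    (child,) = select(1)
                elif op == "fresh_random":
                    child = dg.random_concrete_sequence(length, rng)
                else:
                    (parent,) = select(1)
                    child = dg.edit(parent, op, rng)
            except NoOpEditError:
                continue
            if not feasible(child):
                continue
            new_pop.append(child)
        population = new_pop
        fitness = np.array([evaluate(d)[0] for d in population])
        archive_update(population, fitness)
        gen_best = float(fitness.max())
        if gen_best > best_F + 1e-12:
            best_F = gen_best
            best_seq = population[int(fitness.argmax())]
            stagnant = 0
        else:
            stagnant += 1
        if progress is not None:
            progress(generation, best_F)
        if stagnant >= spec.stagnation_limit:
            break

    # --- assemble top-n solutions from the archive
    top = sorted(archive.items(), key=lambda kv: (-kv[1], kv[0]))[:n_solutions]
    solutions: list[LibrarySolution] = []
    for letters, F in top:
        d = DegenerateSequence(letters)
        F, n, C, rates, exhaustive = evaluate(d)
        window = None
        if spec.mode == "genome_edit":
            _, window = genome_edit_feasible(d, wild_type, spec.max_window)
        reached = any(r >= spec.r_max / 10**spec.resolution_W for r in rates.values())
        solutions.append(LibrarySolution(
            dseq=d, variant_rates=rates, coverage_C=C, n_variants=n,
            objective_F=F, exhaustive=exhaustive,
            range_reached=reached, window=window,
        ))
    return solutions


# -- multi-dimensional coverage ----------------------------------------------

def multi_dim_coverage(
    tuples: Sequence[Sequence[float]],
    grids: Sequence[BinGrid],
) -> float:
    """Coverage of a D-dimensional expression space.

    A cell of the Cartesian bin grid is filled when some rate tuple fills
    every coordinate's bin window simultaneously.  With D = 1 this reduces to
    :func:`coverage`.
    """
    D = len(grids)
    if D < 1:
        raise ValueError("need at least one grid")
    shape = tuple(g.B_total for g in grids)
    filled = np.zeros(shape, dtype=bool)
    for t in tuples:
        if len(t) != D:
            raise ValueError(f"rate tuple {t!r} does not have dimension {D}")
        masks = [g.filled_mask([r]) for g, r in zip(grids, t)]
        if any(not m.any() for m in masks):
            continue
        cell = masks[0]
        for m in masks[1:]:
            cell = np.multiply.outer(cell, m)
        filled |= cell
    return float(filled.sum()) / filled.size


def monte_carlo_coverage(
    dseqs: Sequence[DegenerateSequence | str],
    contexts: Sequence[MRNAContext],
    grids: Sequence[BinGrid],
    n_clones: int,
    replicates: int,
    model: RibosomeModel,
    engine: FoldingEngine,
    rng: np.random.Generator,
    rate_fns: Sequence[Callable[[str], float]] | None = None,
) -> tuple[float, float]:
    """Monte Carlo estimate of the coverage reached by picking random clones.

    Per replicate, ``n_clones`` random variant combinations (one uniform
    variant per gene) are drawn, their rates predicted, and the
    multi-dimensional coverage computed; returns (mean, sd) across
    replicates.  ``rate_fns`` (one per gene, variant -> rate) may replace the
    biophysics pipeline.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    ds = [d if isinstance(d, DegenerateSequence) else DegenerateSequence(d) for d in dseqs]
    caches: list[dict[str, float]] = [{} for _ in ds]

    def rate_of(gene: int, variant: str) -> float:
        c = caches[gene]
        r = c.get(variant)
        if r is None:
            if rate_fns is not None:
                r = rate_fns[gene](variant)
            else:
                from .biophysics import predict_rate
                r = predict_rate(contexts[gene].with_rbs(variant), model, engine)
            c[variant] = r
        return r

    covs = []
    for _ in range(replicates):
        tuples = []
        for _ in range(n_clones):
            tuples.append(tuple(
                rate_of(g, ds[g].sample_variant(rng)) for g in range(len(ds))
            ))
        covs.append(multi_dim_coverage(tuples, grids))
    arr = np.asarray(covs)
    return float(arr.mean()), float(arr.std(ddof=1)) if replicates > 1 else 0.0
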