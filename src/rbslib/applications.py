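"""Downstream analyses over an identified sequence-expression-activity map.

A :class:`SEAMAP` couples the identified kinetic model of the crtEBI pathway
to its reference state: ``predict`` maps a pathway variant — a transcription
multiplier plus (crtE, crtB, crtI) translation rates — to a neurosporene
productivity, with ``predict(reference) = 196`` ug/gDCW/h by construction.

On top of predict() this module implements:

* flux control coefficients (FCCs), d ln(productivity) / d ln(enzyme ratio),
  by central finite differences in log space — a pathway variant is
  optimally balanced when its enzymes' FCCs vanish at the activity maximum;
* transcription-induction response curves via a configurable Hill model of
  inducer -> transcription multiplier;
* precursor-supply sweeps (the dxs knob);
* evolutionary-landscape histograms: random 1-3 nt mutations of the three
  35-nt RBSs are re-scored through the translation biophysics and the kinetic
  model to ask how likely random mutation is to lower productivity;
* Zoom-mode targeting: a grid search around the current best variant that
  returns the per-gene translation-rate windows holding the top-decile
  predictions, ready to parameterize a Zoom design run.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biophysics import FoldingEngine, MRNAContext, RibosomeModel, predict_rate
from .degenerate import BASES
from .kinetics import (
    CRT_GENES,
    PathwayVariant,
    ReactionNetwork,
    ReferenceState,
    enzyme_ratio,
    productivity,
    simulate,
)

__all__ = [
    "SEAMAP",
    "InductionModel",
    "fcc",
    "response_curve",
    "precursor_sweep",
    "evolutionary_landscape",
    "LandscapeResult",
    "zoom_target",
    "greedy_sequence_ascent",
]

_ENZYME_INDEX = {"CrtE": 0, "CrtB": 1, "CrtI": 2}


@dataclass
class SEAMAP:
    """Identified kinetic model + reference state = productivity predictor."""

    network: ReactionNetwork
    params: dict[str, float]
    reference: ReferenceState = field(default_factory=ReferenceState)
    sim_rtol: float = 1e-8
    sim_atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.reference.r_p_ref is None:
            self.reference.r_p_ref = simulate(
                self.network, self.params, ratios=(1.0, 1.0, 1.0),
                rtol=self.sim_rtol, atol=self.sim_atol,
            ).r_p
        self._cache: dict[tuple, float] = {}

    @property
    def parameter_hash(self) -> str:
        """Stable digest of the identified parameter set; stamped on every
        output table so results are traceable to one model."""
        blob = ",".join(f"{k}={self.params[k]:.12g}"
                        for k in sorted(self.params))
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def predict_ratios(self, ratios: tuple[float, float, float],
                       precursor_supply: float = 1.0) -> float:
        key = (ratios, precursor_supply)
        hit = self._cache.get(key)
        if hit is None:
            r_p = simulate(self.network, self.params, ratios=ratios,
                           precursor_supply=precursor_supply,
                           rtol=self.sim_rtol, atol=self.sim_atol).r_p
            hit = productivity(r_p, self.reference)
            self._cache[key] = hit
        return hit

    def predict(self, variant: PathwayVariant) -> float:
        """Neurosporene productivity (ug/gDCW/h) of a pathway variant."""
        ratios = enzyme_ratio(variant, self.reference)
        return self.predict_ratios(ratios, variant.precursor_supply)


@dataclass(frozen=True)
class InductionModel:
    """Hill mapping from inducer concentration to transcription multiplier."""

    basal: float = 0.05
    max: float = 3.0
    K: float = 50.0       # inducer units (e.g. uM IPTG)
    n: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.basal <= self.max):
            raise ValueError("require 0 < basal <= max")
        if self.K <= 0 or self.n <= 0:
            raise ValueError("K and n must be positive")

    def multiplier(self, inducer: float) -> float:
        if inducer < 0:
            raise ValueError("inducer concentration must be >= 0")
        x = inducer**self.n
        return self.basal + (self.max - self.basal) * x / (self.K**self.n + x)


# -- flux control ------------------------------------------------------------

def fcc(seamap: SEAMAP, variant: PathwayVariant, enzyme: str,
        rel_step: float = 0.01) -> float:
    """Flux control coefficient of ``enzyme`` at ``variant``.

    Central finite difference of ln(productivity) with respect to
    ln(enzyme ratio), the other ratios fixed.  Returns NaN when the
    productivity vanishes at an evaluation point (coefficient undefined).
    """
    if enzyme not in _ENZYME_INDEX:
        raise ValueError(f"enzyme must be one of {tuple(_ENZYME_INDEX)}")
    if not (0 < rel_step < 1):
        raise ValueError("rel_step must be a small positive fraction")
    i = _ENZYME_INDEX[enzyme]
    base = list(enzyme_ratio(variant, seamap.reference))
    h = 1.0 + rel_step

    def prod_at(factor: float) -> float:
        r = list(base)
        r[i] = base[i] * factor
        return seamap.predict_ratios(tuple(r), variant.precursor_supply)

    p_hi, p_lo = prod_at(h), prod_at(1.0 / h)
    if p_hi <= 0 or p_lo <= 0:
        return float("nan")
    return (math.log(p_hi) - math.log(p_lo)) / (2.0 * math.log(h))


def response_curve(seamap: SEAMAP, variant: PathwayVariant,
                   induction: InductionModel,
                   inducer_grid: np.ndarray) -> pd.DataFrame:
    """Productivity along a transcription-induction curve.

    Returns a frame (inducer, transcription_multiplier, productivity) with
    the arg-max multiplier in ``df.attrs['argmax_multiplier']``.
    """
    inducer_grid = np.asarray(inducer_grid, dtype=float)
    if inducer_grid.size == 0:
        raise ValueError("inducer grid must be non-empty")
    rows = []
    for ind in inducer_grid:
        m = induction.multiplier(float(ind))
        p = seamap.predict(replace(variant, transcription_multiplier=m))
        rows.append({"inducer": float(ind), "transcription_multiplier": m,
                     "productivity_ug_gDCW_h": p})
    df = pd.DataFrame(rows)
    best = df["productivity_ug_gDCW_h"].idxmax()
    df.attrs["argmax_multiplier"] = float(df.loc[best, "transcription_multiplier"])
    df.attrs["parameter_hash"] = seamap.parameter_hash
    return df


def precursor_sweep(seamap: SEAMAP, variant: PathwayVariant,
                    supply_grid: np.ndarray) -> pd.DataFrame:
    """Productivity as the precursor pool level is swept (the dxs knob);
    fold improvement is reported relative to supply = 1."""
    supply_grid = np.asarray(supply_grid, dtype=float)
    if np.any(supply_grid <= 0):
        raise ValueError("precursor supplies must be positive")
    baseline = seamap.predict(replace(variant, precursor_supply=1.0))
    rows = []
    for s in supply_grid:
        p = seamap.predict(replace(variant, precursor_supply=float(s)))
        rows.append({"precursor_supply": float(s),
                     "productivity_ug_gDCW_h": p,
                     "fold_improvement": p / baseline if baseline > 0 else np.nan})
    df = pd.DataFrame(rows)
    df.attrs["parameter_hash"] = seamap.parameter_hash
    return df


# -- evolutionary landscape --------------------------------------------------

@dataclass
class LandscapeResult:
    """Productivity ratios of random RBS mutants vs the unmutated pathway."""

    ratios: np.ndarray
    n_mutations: int
    baseline_productivity: float
    parameter_hash: str

    @property
    def fraction_decreased(self) -> float:
        return float(np.mean(self.ratios < 1.0 - 1e-9))

    def histogram(self, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        """(counts, edges) over log10 productivity ratio; zero-productivity
        mutants are clamped to the lowest edge."""
        safe = np.clip(self.ratios, 1e-12, None)
        return np.histogram(np.log10(safe), bins=bins)


def _mutate_rbss(rbss: list[str], positions: np.ndarray, rng: np.random.Generator,
                 lengths: list[int]) -> list[str]:
    out = [list(s) for s in rbss]
    bounds = np.cumsum([0] + lengths)
    for pos in positions:
        g = int(np.searchsorted(bounds, pos, side="right") - 1)
        local = int(pos - bounds[g])
        current = out[g][local]
        choices = [b for b in BASES if b != current]
        out[g][local] = choices[rng.integers(3)]
    return ["".join(s) for s in out]


def evolutionary_landscape(
    seamap: SEAMAP,
    contexts: list[MRNAContext],
    rbss: list[str],
    n_mutations: int,
    samples: int,
    model: RibosomeModel,
    engine: FoldingEngine,
    rng: np.random.Generator,
    rate_caches: list[dict[str, float]] | None = None,
) -> LandscapeResult:
    """Distribution of productivity changes under random RBS mutations.

    Per sample, ``n_mutations`` distinct positions are drawn uniformly over
    the concatenated RBS nucleotides of the three genes, each mutated to a
    uniformly chosen different base; the mutant's three translation rates are
    re-predicted through the biophysics model and its productivity through
    the kinetic model.  Ratios to the unmutated pathway are returned.
    """
    if samples < 1:
        raise ValueError("samples must be >= 1")
    if len(contexts) != 3 or len(rbss) != 3:
        raise ValueError("expected one context and one RBS per crt gene")
    rbss = [c.with_rbs(r).rbs for c, r in zip(contexts, rbss)]
    lengths = [len(r) for r in rbss]
    total_nt = sum(lengths)
    if n_mutations > total_nt:
        raise ValueError("more mutations than RBS nucleotides")
    caches = rate_caches if rate_caches is not None else [{}, {}, {}]

    def rate(g: int, rbs: str) -> float:
        r = caches[g].get(rbs)
        if r is None:
            r = predict_rate(contexts[g].with_rbs(rbs), model, engine)
            caches[g][rbs] = r
        return r

    base_rates = tuple(rate(g, rbss[g]) for g in range(3))
    baseline = seamap.predict(PathwayVariant(base_rates))
    if baseline <= 0:
        raise ValueError("baseline pathway has zero productivity")

    ratios = np.ones(samples)
    if n_mutations > 0:
        for k in range(samples):
            positions = rng.choice(total_nt, size=n_mutations, replace=False)
            mutant = _mutate_rbss(rbss, positions, rng, lengths)
            rates = tuple(
                base_rates[g] if mutant[g] == rbss[g] else rate(g, mutant[g])
                for g in range(3)
            )
            ratios[k] = seamap.predict(PathwayVariant(rates)) / baseline
    return LandscapeResult(
        ratios=ratios, n_mutations=n_mutations,
        baseline_productivity=baseline, parameter_hash=seamap.parameter_hash,
    )


def greedy_sequence_ascent(
    seamap: SEAMAP,
    contexts: list[MRNAContext],
    rbss: list[str],
    model: RibosomeModel,
    engine: FoldingEngine,
    max_steps: int = 60,
    rate_caches: list[dict[str, float]] | None = None,
) -> tuple[list[str], float]:
    """Coordinate ascent to a single-mutation local optimum in sequence space.

    Repeatedly applies the best productivity-improving single-nucleotide
    mutation across the three RBSs until no single mutation improves (a
    strict local optimum of the mutation landscape) or ``max_steps`` is
    exhausted.  Returns (rbss, productivity).
    """
    rbss = [c.with_rbs(r).rbs for c, r in zip(contexts, rbss)]
    caches = rate_caches if rate_caches is not None else [{}, {}, {}]

    def rate(g: int, rbs: str) -> float:
        r = caches[g].get(rbs)
        if r is None:
            r = predict_rate(contexts[g].with_rbs(rbs), model, engine)
            caches[g][rbs] = r
        return r

    rates = [rate(g, rbss[g]) for g in range(3)]
    best_p = seamap.predict(PathwayVariant(tuple(rates)))
    for _ in range(max_steps):
        improved = False
        best_move = None
        for g in range(3):
            for pos in range(len(rbss[g])):
                for b in BASES:
                    if b == rbss[g][pos]:
                        continue
                    cand = rbss[g][:pos] + b + rbss[g][pos + 1:]
                    new_rates = list(rates)
                    new_rates[g] = rate(g, cand)
                    p = seamap.predict(PathwayVariant(tuple(new_rates)))
                    if p > best_p * (1 + 1e-9):
                        best_p = p
                        best_move = (g, cand, new_rates[g])
                        improved = True
        if not improved:
            break
        g, cand, r_new = best_move
        rbss[g] = cand
        rates[g] = r_new
    return rbss, best_p


def synthetic_crt_contexts(
    seed: int = 0,
    organism: str = "E. coli",
    cds_length: int = 36,
) -> tuple[list[MRNAContext], list[str]]:
    """Synthetic stand-in mRNA contexts for the three crt genes.

    The real crtE/crtB/crtI coding sequences are not bundled; desk-scale
    landscape and design studies use seeded random CDSs (AUG followed by
    random codons) and random initial 35-nt RBSs.  Returns (contexts, rbss).
    """
    rng = np.random.default_rng(seed)
    contexts, rbss = [], []
    for _ in CRT_GENES:
        cds = "AUG" + "".join(BASES[i] for i in rng.integers(4, size=cds_length - 3))
        rbs = "".join(BASES[i] for i in rng.integers(4, size=35))
        contexts.append(MRNAContext(pre_sequence="", rbs=rbs, cds=cds,
                                    organism=organism))
        rbss.append(rbs)
    return contexts, rbss


# -- zoom targeting ----------------------------------------------------------

def zoom_target(
    seamap: SEAMAP,
    best_rates: tuple[float, float, float],
    expansion_factor: float = 10.0,
    grid_points: int = 7,
    top_fraction: float = 0.10,
    rate_floor: float = 0.10,
    rate_ceiling: float = 5e6,
) -> dict[str, tuple[float, float]]:
    """Per-gene translation-rate windows for a Zoom-mode design.

    Grid-searches predict() over a log-space box spanning
    [rate/expansion_factor, rate*expansion_factor] per gene around the
    current best variant, and returns, per gene, the (r_min, r_max) window
    containing the top-``top_fraction`` predictions.  A flat landscape
    returns the expanded box itself with a warning.
    """
    import warnings

    if expansion_factor < 1:
        raise ValueError("expansion factor must be >= 1")
    axes = []
    for r in best_rates:
        lo = max(r / expansion_factor, rate_floor)
        hi = min(r * expansion_factor, rate_ceiling)
        axes.append(np.logspace(math.log10(lo), math.log10(hi), grid_points))
    grid = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    prods = np.array([
        seamap.predict(PathwayVariant(tuple(row))) for row in grid
    ])
    if prods.max() - prods.min() <= 1e-12 * max(prods.max(), 1.0):
        warnings.warn("flat productivity landscape; returning the expanded box")
        windows = {g: (float(a[0]), float(a[-1]))
                   for g, a in zip(CRT_GENES, axes)}
        return windows
    cutoff = np.quantile(prods, 1.0 - top_fraction)
    top = grid[prods >= cutoff]
    windows = {}
    for gi, g in enumerate(CRT_GENES):
        lo, hi = float(top[:, gi].min()), float(top[:, gi].max())
        if lo >= hi:  # top decile collapsed onto one grid line
            step = axes[gi][1] / axes[gi][0]
            lo, hi = lo / step, hi * step
        windows[g] = (lo, hi)
    return windows
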