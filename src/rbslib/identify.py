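"""Kinetic parameter reduction and identification from variant productivities.

The full model carries 48 rate constants.  Two standard constraints reduce
the degrees of freedom to 33:

* one detailed-balance relation per overall catalyzed conversion pins the
  reverse constant of the conversion's bound-state catalytic step, given a
  configured overall equilibrium constant for the conversion (10 dependent
  constants), and
* the five substrate-binding forward constants (one per enzyme) are fixed at
  configured values standing in for independent biochemical knowledge
  (5 pinned constants).

``reduce``/``inverse_reduce`` move between the two representations; the
dependency relations hold exactly on every reconstructed full set, and the
round trip is the identity on the 33 free coordinates.

``identify`` fits the 33 free parameters (log10 space) to a table of pathway
variants — per-gene translation rates plus measured productivity — by
minimizing the mean relative error between predicted and measured
productivities over the non-reference rows, with a memetic genetic
algorithm: global GA search plus a trust-region least-squares polish of each
run's best individual, repeated over independent randomly initialized runs.
Cross-run dispersion of the best-fit parameters is reported as a uniqueness
diagnostic.

``generate_synthetic_dataset`` produces study-scale variant tables from a
known parameter set (the in-silico stand-in for a wet-lab characterization
campaign), so identification is testable end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import (
    CRT_GENES,
    REFERENCE_PRODUCTIVITY,
    REFERENCE_TRANSLATION_RATES,
    PathwayVariant,
    ReactionNetwork,
    ReferenceState,
    SimulationError,
    build_canonical_network,
    enzyme_ratio,
    simulate,
)

__all__ = [
    "ReductionMap",
    "ParameterSet",
    "VariantDataset",
    "reduce_parameters",
    "inverse_reduce",
    "identify",
    "FitReport",
    "generate_synthetic_dataset",
    "loguniform_design",
    "example_true_parameters",
    "SEARCH_RATE_RANGES",
    "N_FREE_PARAMETERS",
]

N_FREE_PARAMETERS = 33

#: Translation-rate ranges (au) spanned by the three Search-mode libraries
#: used to characterize the pathway: crtE, crtB, crtI.
SEARCH_RATE_RANGES = {
    "crtE": (445.0, 72000.0),
    "crtB": (3.0, 20000.0),
    "crtI": (97.0, 203000.0),
}


# -- reduction ---------------------------------------------------------------

@dataclass(frozen=True)
class ReductionMap:
    """Versioned dependency map: which constants are dependent or pinned.

    ``dependent`` maps a rate-constant id to the conversion whose
    detailed-balance relation determines it; ``pinned`` maps a constant id to
    its fixed value; ``conversion_keq`` gives each conversion's overall
    equilibrium constant.  Changing the map must keep 48 - 10 - 5 = 33 free.
    """

    dependent: dict[str, str]
    pinned: dict[str, float]
    conversion_keq: dict[str, float]
    version: str = "v1"

    @classmethod
    def canonical(cls, network: ReactionNetwork,
                  keq: float = 50.0,
                  pinned_value: float = 40.0) -> "ReductionMap":
        """Default map: the catalytic step closest to each conversion's
        product end is dependent; the first binding kf of each enzyme is
        pinned."""
        dependent: dict[str, str] = {}
        for conv in network.conversions:
            cats = [r for r in network.conversion_reactions(conv) if r.kind == "cat"]
            # conversions without a cat step (none in the canonical network)
            # would fall back to their release step
            step = cats[-1] if cats else network.conversion_reactions(conv)[-1]
            dependent[step.kr_id] = conv
        pinned: dict[str, float] = {}
        for enz in network.enzymes:
            first_bind = next(r for r in network.reactions
                              if r.enzyme == enz and r.kind == "bind")
            pinned[first_bind.kf_id] = pinned_value
        return cls(
            dependent=dependent,
            pinned=pinned,
            conversion_keq={c: keq for c in network.conversions},
        )

    def free_ids(self, network: ReactionNetwork) -> tuple[str, ...]:
        return tuple(k for k in network.rate_constant_ids
                     if k not in self.dependent and k not in self.pinned)


def _conversion_path(network: ReactionNetwork, conversion: str) -> list[tuple[str, int]]:
    """Elementary reactions (with orientation) whose equilibrium constants
    multiply to the conversion's overall K_eq: the conversion's own
    elementary steps, taken in their forward direction."""
    return [(r.id, +1) for r in network.conversion_reactions(conversion)]


def _solve_dependent(network: ReactionNetwork, rmap: ReductionMap,
                     params: dict[str, float]) -> dict[str, float]:
    """Compute each dependent kr from the others so that every conversion's
    overall equilibrium constant equals its configured value."""
    by_id = {r.id: r for r in network.reactions}
    out = dict(params)
    for dep_id, conv in rmap.dependent.items():
        keq = rmap.conversion_keq[conv]
        # K_eq = prod over path of (kf/kr)^orient ; solve for dep kr
        log_acc = 0.0
        dep_rxn = None
        for rid, orient in _conversion_path(network, conv):
            r = by_id[rid]
            if r.kr_id == dep_id:
                dep_rxn = (r, orient)
                log_acc += orient * math.log(out[r.kf_id])
                continue
            log_acc += orient * (math.log(out[r.kf_id]) - math.log(out[r.kr_id]))
        assert dep_rxn is not None, f"dependent {dep_id} not on path of {conv}"
        r, orient = dep_rxn
        # log K = log_acc - orient*log kr_dep  =>  log kr_dep = (log_acc - log K)/orient
        out[dep_id] = math.exp((log_acc - math.log(keq)) / orient)
    return out


def reduce_parameters(
    full: dict[str, float],
    network: ReactionNetwork,
    rmap: ReductionMap | None = None,
    pin_tolerance: float = 1e-6,
) -> np.ndarray:
    """Project a full 48-constant set to its 33 free coordinates.

    Pinned constants deviating beyond ``pin_tolerance`` (relative) raise a
    warning and are projected onto their configured values.
    """
    import warnings

    if rmap is None:
        rmap = ReductionMap.canonical(network)
    if any(v <= 0 for v in full.values()):
        raise ValueError("all rate constants must be positive")
    for pid, val in rmap.pinned.items():
        if abs(full[pid] - val) / val > pin_tolerance:
            warnings.warn(
                f"pinned constant {pid}={full[pid]:.6g} deviates from its "
                f"configured value {val:.6g}; projecting", stacklevel=2,
            )
    return np.array([full[k] for k in rmap.free_ids(network)])


def inverse_reduce(
    reduced: np.ndarray,
    network: ReactionNetwork,
    rmap: ReductionMap | None = None,
) -> dict[str, float]:
    """Reconstruct the full 48-constant set from 33 free values; the
    dependency relations hold exactly on the output."""
    if rmap is None:
        rmap = ReductionMap.canonical(network)
    reduced = np.asarray(reduced, dtype=float)
    free = rmap.free_ids(network)
    if reduced.shape != (len(free),):
        raise ValueError(f"expected {len(free)} free values, got {reduced.shape}")
    if np.any(reduced <= 0):
        raise ValueError("free parameters must be positive")
    params = dict(zip(free, reduced))
    params.update(rmap.pinned)
    return _solve_dependent(network, rmap, params)


@dataclass
class ParameterSet:
    """Full 48-constant set together with its reduction bookkeeping."""

    full: dict[str, float]
    network: ReactionNetwork = field(repr=False)
    rmap: ReductionMap = field(repr=False)

    @classmethod
    def from_reduced(cls, reduced: np.ndarray, network: ReactionNetwork,
                     rmap: ReductionMap | None = None) -> "ParameterSet":
        rmap = rmap or ReductionMap.canonical(network)
        return cls(full=inverse_reduce(reduced, network, rmap),
                   network=network, rmap=rmap)

    @property
    def reduced(self) -> np.ndarray:
        return reduce_parameters(self.full, self.network, self.rmap)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.network.rate_constant_ids:
            role = ("dependent" if k in self.rmap.dependent
                    else "pinned" if k in self.rmap.pinned else "free")
            rows.append({"constant": k, "value": self.full[k], "role": role})
        return pd.DataFrame(rows)


# -- datasets ----------------------------------------------------------------

DATASET_COLUMNS = ["label", "rate_crtE_au", "rate_crtB_au", "rate_crtI_au",
                   "productivity_ug_gDCW_h", "is_reference"]


@dataclass
class VariantDataset:
    """Pathway-variant table: per-gene translation rates and measured
    productivity, with exactly one reference row."""

    table: pd.DataFrame
    provenance: str = "file"

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        nref = int(self.table["is_reference"].sum())
        if nref != 1:
            raise ValueError(f"dataset must flag exactly one reference row, got {nref}")
        rates = self.table[["rate_crtE_au", "rate_crtB_au", "rate_crtI_au"]]
        if (rates <= 0).any().any() or (self.table["productivity_ug_gDCW_h"] <= 0).any():
            raise ValueError("rates and productivities must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def reference_row(self) -> pd.Series:
        return self.table[self.table["is_reference"]].iloc[0]

    @property
    def reference(self) -> ReferenceState:
        ref = self.reference_row
        return ReferenceState(
            translation_rates=(ref["rate_crtE_au"], ref["rate_crtB_au"],
                               ref["rate_crtI_au"]),
            productivity=float(ref["productivity_ug_gDCW_h"]),
        )

    @property
    def non_reference(self) -> pd.DataFrame:
        return self.table[~self.table["is_reference"]]

    @classmethod
    def from_tsv(cls, path: str) -> "VariantDataset":
        return cls(pd.read_csv(path, sep="\t"), provenance="file")

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def loguniform_design(n: int, rng: np.random.Generator,
                      ranges: dict[str, tuple[float, float]] | None = None
                      ) -> list[tuple[float, float, float]]:
    """Scatter n rate triples log-uniformly across the Search-mode ranges."""
    ranges = ranges or SEARCH_RATE_RANGES
    cols = []
    for g in CRT_GENES:
        lo, hi = ranges[g]
        cols.append(10 ** rng.uniform(math.log10(lo), math.log10(hi), size=n))
    return list(zip(*cols))


def generate_synthetic_dataset(
    true_params: dict[str, float],
    design: list[tuple[float, float, float]] | None = None,
    noise_cv: float = 0.10,
    rng: np.random.Generator | None = None,
    network: ReactionNetwork | None = None,
    n_variants: int = 73,
    precursor_supply: float = 1.0,
) -> VariantDataset:
    """Simulate a pathway-variant characterization campaign.

    ``design`` defaults to ``n_variants`` log-uniform rate triples across the
    Search-mode ranges.  The row closest (log distance) to the canonical
    reference rates is flagged as the reference; enzyme ratios are computed
    against that row, every productivity is rescaled so the reference reads
    exactly 196 ug/gDCW/h, and multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` is applied to the non-reference
    rows.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if network is None:
        network = build_canonical_network()
    if design is None:
        design = loguniform_design(n_variants, rng)
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")

    target = np.log10(REFERENCE_TRANSLATION_RATES)
    dist = [np.linalg.norm(np.log10(t) - target) for t in design]
    ref_i = int(np.argmin(dist))
    ref_rates = tuple(float(x) for x in design[ref_i])
    reference = ReferenceState(translation_rates=ref_rates,
                               productivity=REFERENCE_PRODUCTIVITY)

    r_p_ref = simulate(network, true_params, ratios=(1.0, 1.0, 1.0),
                       precursor_supply=precursor_supply).r_p
    if r_p_ref <= 0:
        raise ValueError("true parameter set gives zero reference flux")

    sigma = math.sqrt(math.log1p(noise_cv**2))
    rows = []
    for i, rates in enumerate(design):
        ratios = enzyme_ratio(PathwayVariant(tuple(rates)), reference)
        r_p = simulate(network, true_params, ratios=ratios,
                       precursor_supply=precursor_supply).r_p
        prod = REFERENCE_PRODUCTIVITY * r_p / r_p_ref
        if i != ref_i and noise_cv > 0:
            prod *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
        rows.append({
            "label": "reference" if i == ref_i else f"variant_{i:03d}",
            "rate_crtE_au": rates[0], "rate_crtB_au": rates[1],
            "rate_crtI_au": rates[2],
            "productivity_ug_gDCW_h": REFERENCE_PRODUCTIVITY if i == ref_i else prod,
            "is_reference": i == ref_i,
        })
    return VariantDataset(pd.DataFrame(rows), provenance="synthetic")


def example_true_parameters(seed: int, network: ReactionNetwork | None = None,
                            rmap: ReductionMap | None = None,
                            spread: float = 0.6) -> dict[str, float]:
    """A documented, seeded synthetic "ground-truth" parameter set: the
    default parameter profile jittered log-uniformly by ``+-spread`` decades
    on the free coordinates."""
    from .kinetics import default_parameters

    network = network or build_canonical_network()
    rmap = rmap or ReductionMap.canonical(network)
    rng = np.random.default_rng(seed)
    base = reduce_parameters(default_parameters(network) | dict(rmap.pinned),
                             network, rmap)
    jitter = 10 ** rng.uniform(-spread, spread, size=base.size)
    return inverse_reduce(base * jitter, network, rmap)


# -- identification ----------------------------------------------------------

@dataclass
class FitReport:
    """Outcome of one identification campaign."""

    best_params: ParameterSet
    best_error: float                 # mean relative error, best run
    run_errors: list[float]
    run_seeds: list[int]
    run_best_reduced: np.ndarray      # (runs, 33) best free params per run
    n_variants_fit: int

    @property
    def parameter_dispersion(self) -> np.ndarray:
        """Std of log10 best-fit free parameters across runs (uniqueness
        diagnostic: small values indicate a well-determined coordinate)."""
        return np.log10(self.run_best_reduced).std(axis=0)

    def to_json(self) -> str:
        return json.dumps({
            "best_error": self.best_error,
            "run_errors": self.run_errors,
            "run_seeds": self.run_seeds,
            "n_variants_fit": self.n_variants_fit,
            "parameter_dispersion_log10": self.parameter_dispersion.tolist(),
            "best_parameters": self.best_params.full,
        }, indent=2)


def _fit_objective_factory(dataset: VariantDataset, network: ReactionNetwork,
                           rmap: ReductionMap, rtol: float, atol: float,
                           penalty: float = 10.0):
    reference = dataset.reference
    nonref = dataset.non_reference
    rate_cols = nonref[["rate_crtE_au", "rate_crtB_au", "rate_crtI_au"]].to_numpy()
    measured = nonref["productivity_ug_gDCW_h"].to_numpy()
    ref_rates = np.array(reference.translation_rates)

    def residuals(log10_free: np.ndarray) -> np.ndarray:
        try:
            full = inverse_reduce(10.0 ** log10_free, network, rmap)
            r_p_ref = simulate(network, full, ratios=(1, 1, 1),
                               rtol=rtol, atol=atol).r_p
            if r_p_ref <= 1e-12:
                return np.full(len(measured), penalty)
            res = np.empty(len(measured))
            for i in range(len(measured)):
                ratios = tuple(rate_cols[i] / ref_rates)
                r_p = simulate(network, full, ratios=ratios,
                               rtol=rtol, atol=atol).r_p
                pred = reference.productivity * r_p / r_p_ref
                res[i] = (pred - measured[i]) / measured[i]
            return res
        except (SimulationError, OverflowError, FloatingPointError):
            return np.full(len(measured), penalty)

    def mean_rel_error(log10_free: np.ndarray) -> float:
        return float(np.abs(residuals(log10_free)).mean())

    return residuals, mean_rel_error


def identify(
    dataset: VariantDataset,
    network: ReactionNetwork | None = None,
    runs: int = 10,
    rng: np.random.Generator | int | None = None,
    rmap: ReductionMap | None = None,
    ga_population: int = 24,
    ga_generations: int = 10,
    polish_max_nfev: int = 6,
    log10_bounds: tuple[float, float] = (-4.0, 4.0),
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-9,
    init_sigma: float = 0.8,
) -> FitReport:
    """Identify the 33 free kinetic parameters from variant productivities.

    Each of ``runs`` independent runs draws a random initial GA population in
    log10 space (centered on the default parameter profile), evolves it
    (tournament selection, blend crossover, Gaussian mutation, elitism), and
    polishes the best individual with a bounded trust-region least-squares
    step (``polish_max_nfev`` counts trust-region iterations; each also pays
    one finite-difference Jacobian of 33 residual evaluations).  Simulation
    failures are penalized, not fatal.  The best run wins;
    per-run errors and the cross-run dispersion of the best-fit parameters
    are reported.
    """
    if len(dataset.non_reference) < 2:
        raise ValueError("need at least 2 non-reference variants to fit")
    network = network or build_canonical_network()
    rmap = rmap or ReductionMap.canonical(network)
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)

    residuals, mean_rel_error = _fit_objective_factory(
        dataset, network, rmap, sim_rtol, sim_atol)

    from .kinetics import default_parameters
    center = np.log10(reduce_parameters(
        default_parameters(network) | dict(rmap.pinned), network, rmap))
    lo, hi = log10_bounds
    dim = center.size

    run_errors: list[float] = []
    run_seeds: list[int] = []
    run_best: list[np.ndarray] = []

    for run in range(runs):
        seed = int(rng.integers(2**31 - 1))
        run_seeds.append(seed)
        r = np.random.default_rng(seed)

        pop = np.clip(center + r.normal(0.0, init_sigma, size=(ga_population, dim)),
                      lo, hi)
        err = np.array([mean_rel_error(x) for x in pop])
        for _ in range(ga_generations):
            order = np.argsort(err)
            elite = pop[order[: max(2, ga_population // 6)]]
            children = [pop[order[0]].copy()]
            while len(children) < ga_population:
                # tournament parents
                i, j = r.integers(ga_population, size=2)
                a = pop[i] if err[i] < err[j] else pop[j]
                i, j = r.integers(ga_population, size=2)
                b = pop[i] if err[i] < err[j] else pop[j]
                w = r.uniform(-0.25, 1.25, size=dim)  # blend crossover
                child = w * a + (1 - w) * b
                mask = r.random(dim) < 0.25
                child[mask] += r.normal(0.0, 0.3, size=mask.sum())
                children.append(np.clip(child, lo, hi))
            # keep elites in the pool
            for k, e in enumerate(elite[: len(children) - 1], start=1):
                if r.random() < 0.5:
                    children[k] = e.copy()
            pop = np.asarray(children)
            err = np.array([mean_rel_error(x) for x in pop])

        best = pop[int(err.argmin())]
        try:
            sol = least_squares(
                residuals, best, bounds=(lo, hi), method="trf",
                max_nfev=polish_max_nfev, diff_step=1e-3,
            )
            polished = sol.x
        except Exception:
            polished = best
        e_best = mean_rel_error(polished)
        e_ga = float(err.min())
        if e_ga < e_best:
            polished, e_best = best, e_ga
        run_errors.append(e_best)
        run_best.append(10.0 ** polished)

    best_run = int(np.argmin(run_errors))
    best_params = ParameterSet.from_reduced(run_best[best_run], network, rmap)
    return FitReport(
        best_params=best_params,
        best_error=float(run_errors[best_run]),
        run_errors=[float(e) for e in run_errors],
        run_seeds=run_seeds,
        run_best_reduced=np.asarray(run_best),
        n_variants_fit=len(dataset.non_reference),
    )
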