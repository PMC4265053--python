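"""Thermodynamic model of bacterial translation initiation.

The 30S ribosomal subunit's binding free energy to an mRNA is scored with a
five-term Gibbs free energy model,

    dG_total = dG_mRNA:rRNA + dG_start + dG_spacing + dG_standby - dG_mRNA,

where the final state (ribosome bound, last nine nucleotides of the 16S rRNA
hybridized to the mRNA, non-clashing mRNA structures refolded) is compared to
the initial state (free mRNA at its minimum free energy, dG_mRNA <= 0).
dG_start is the tRNA-fMet/start-codon pairing energy (most negative for AUG
and GUG); dG_spacing >= 0 penalizes a non-optimal distance between the
16S rRNA binding site and the start codon (the ribosome prefers five
nucleotides); dG_standby is a 5' standby-site penalty (0 by default).

Translation initiation rate follows a Boltzmann-like exponential law,

    r = rate_scale * exp(-beta * dG_total),

with an apparent Boltzmann constant beta = 0.45 mol/kcal and a proportionality
constant of 2,500, which puts common physiological rates between ~1 and
100,000 au on a proportional (not absolute) scale.

RNA folding and duplex energies come from a pluggable :class:`FoldingEngine`:
a production adapter over ViennaRNA and a deterministic toy engine for
algorithmic tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Protocol

import numpy as np

from .degenerate import DegenerateSequence, _normalize, count_variants

__all__ = [
    "MRNAContext",
    "RibosomeModel",
    "EnergyBreakdown",
    "FoldingEngine",
    "ToyEngine",
    "ViennaEngine",
    "anti_sd_for",
    "register_organism",
    "ORGANISM_ANTI_SD",
    "spacing_penalty",
    "delta_g_total",
    "translation_rate",
    "rate_to_delta_g",
    "predict_library_rates",
    "LibraryRates",
    "UnknownOrganismError",
    "RBS_LENGTH",
]

#: Conventional RBS length: the 35 nucleotides before the start codon.
RBS_LENGTH = 35

#: How many CDS nucleotides participate in folding calculations.
_CDS_FOLD_WINDOW = 35


# -- organisms ---------------------------------------------------------------

#: 3' tail (9 nt, written 5'->3') of the 16S rRNA per organism.  Gram-negative
#: hosts share ACCUCCUUA; the gram-positives here use ACCUCCUUU.
ORGANISM_ANTI_SD: dict[str, str] = {
    "E. coli": "ACCUCCUUA",
    "S. typhimurium": "ACCUCCUUA",
    "P. fluorescens": "ACCUCCUUA",
    "C. glutamicum": "ACCUCCUUU",
    "B. subtilis": "ACCUCCUUU",
}


class UnknownOrganismError(KeyError):
    def __init__(self, organism: str, registry: dict[str, str]):
        self.organism = organism
        super().__init__(
            f"unknown organism {organism!r}; registered organisms: "
            + ", ".join(sorted(registry))
        )


def anti_sd_for(organism: str, registry: dict[str, str] | None = None) -> str:
    """The 9-nt 3' 16S rRNA tail used for hybridization in ``organism``."""
    reg = ORGANISM_ANTI_SD if registry is None else registry
    try:
        return reg[organism]
    except KeyError:
        raise UnknownOrganismError(organism, reg) from None


def register_organism(organism: str, anti_sd: str) -> None:
    """Extend the organism registry (e.g. from a user config file)."""
    ORGANISM_ANTI_SD[organism] = _normalize(anti_sd)


# -- domain types ------------------------------------------------------------

@dataclass(frozen=True)
class MRNAContext:
    """One mRNA: a promoter-derived 5' leader, the RBS, and the CDS.

    On construction the leader/RBS boundary is renormalized so that ``rbs``
    holds the (at most) 35 nucleotides immediately before the start codon and
    ``pre_sequence`` absorbs the rest of the 5' leader.
    """

    pre_sequence: str
    rbs: str
    cds: str
    organism: str = "E. coli"

    def __post_init__(self) -> None:
        pre = _normalize(self.pre_sequence) if self.pre_sequence else ""
        rbs = _normalize(self.rbs)
        cds = _normalize(self.cds)
        if len(rbs) == 0:
            raise ValueError("RBS must be non-empty")
        if len(cds) < 3:
            raise ValueError("CDS must contain at least a start codon")
        leader = pre + rbs
        rbs = leader[-RBS_LENGTH:]
        pre = leader[: -len(rbs)]
        object.__setattr__(self, "pre_sequence", pre)
        object.__setattr__(self, "rbs", rbs)
        object.__setattr__(self, "cds", cds)

    @property
    def leader(self) -> str:
        return self.pre_sequence + self.rbs

    @property
    def start_codon(self) -> str:
        return self.cds[:3]

    def mrna(self, cds_window: int = _CDS_FOLD_WINDOW) -> str:
        """The mRNA subsequence used for energy calculations."""
        return self.leader + self.cds[:cds_window]

    def with_rbs(self, rbs: str) -> "MRNAContext":
        return replace(self, rbs=rbs)


@dataclass(frozen=True)
class SpacingPenaltyParams:
    """Coefficients of the two penalty branches (kcal/mol).

    Compressed spacings (below the optimum) are penalized quadratically;
    stretched spacings saturate sigmoidally at ``stretched_max``.
    """

    compressed_quadratic: float = 0.5   # kcal/mol per nt^2 below optimum
    stretched_max: float = 6.0          # kcal/mol plateau above optimum
    stretched_halfwidth: float = 4.0    # nt at which half the plateau is reached


@dataclass(frozen=True)
class RibosomeModel:
    """Organism-specific ribosome parameters of the free-energy model."""

    anti_sd: str = "ACCUCCUUA"
    beta: float = 0.45            # mol/kcal, apparent Boltzmann constant
    rate_scale: float = 2500.0    # au, proportionality constant of the rate law
    optimal_spacing: int = 5      # nt between 16S pairing site and start codon
    spacing_penalty_params: SpacingPenaltyParams = field(default_factory=SpacingPenaltyParams)
    start_codon_energies: dict[str, float] = field(
        default_factory=lambda: {"AUG": -1.19, "GUG": -1.19, "UUG": -0.54, "CUG": -0.34}
    )
    footprint: int = 13           # CDS nt occluded by the bound ribosome
    dG_standby: float = 0.0       # standby-site penalty hook (>=0)
    max_spacing: int = 20         # widest aligned spacing scanned

    def __post_init__(self) -> None:
        object.__setattr__(self, "anti_sd", _normalize(self.anti_sd))
        if self.beta <= 0 or self.rate_scale <= 0:
            raise ValueError("beta and rate_scale must be positive")

    @classmethod
    def for_organism(cls, organism: str, **overrides) -> "RibosomeModel":
        return cls(anti_sd=anti_sd_for(organism), **overrides)


@dataclass(frozen=True)
class EnergyBreakdown:
    """The five dG terms (kcal/mol), their total, and the chosen 16S site."""

    dG_mRNA_rRNA: float
    dG_start: float
    dG_spacing: float
    dG_standby: float
    dG_mRNA: float
    dG_total: float
    binding_site: int        # 0-based mRNA index of the 16S pairing window start
    aligned_spacing: int     # nt strictly between pairing window and start codon

    def recompute_total(self) -> float:
        return (self.dG_mRNA_rRNA + self.dG_start + self.dG_spacing
                + self.dG_standby - self.dG_mRNA)


# -- folding engines ---------------------------------------------------------

class FoldingEngine(Protocol):
    """Minimum-free-energy folding and mRNA:rRNA hybridization provider.

    Implementations must be deterministic for fixed inputs and return finite
    energies in kcal/mol.
    """

    def mfe_fold(self, sequence: str) -> tuple[float, str]:
        """(folding free energy, dot-bracket structure) of ``sequence``."""
        ...

    def hybridize(self, site: str, anti_sd: str) -> tuple[float, str, int]:
        """Duplex of ``site`` paired with ``anti_sd``.

        Returns (free energy, structure, pair_end) where ``pair_end`` is the
        0-based site index just after the 3'-most paired site base (used to
        measure the aligned spacing to the start codon).
        """
        ...


_TOY_PAIR_ENERGY = {("G", "C"): -3.0, ("C", "G"): -3.0,
                    ("A", "U"): -2.0, ("U", "A"): -2.0,
                    ("G", "U"): -1.0, ("U", "G"): -1.0}


class ToyEngine:
    """Deterministic toy folding engine for tests and worked examples.

    Folding energies come from an explicit ``mfe_map`` (sequence -> energy,
    default ``fold_energy`` for sequences not listed).  Hybridization scores an
    ungapped antiparallel alignment of the site against the anti-SD with fixed
    per-pair energies (GC -3, AU -2, GU -1 kcal/mol) unless an explicit
    ``duplex_map`` entry exists.  It honours every postcondition of the
    production engine while being trivially predictable.
    """

    def __init__(self,
                 mfe_map: dict[str, float] | None = None,
                 duplex_map: dict[str, float] | None = None,
                 fold_energy: float = 0.0,
                 pair_energies: dict[tuple[str, str], float] | None = None):
        self.mfe_map = dict(mfe_map or {})
        self.duplex_map = dict(duplex_map or {})
        self.fold_energy = fold_energy
        self.pair_energies = dict(
            _TOY_PAIR_ENERGY if pair_energies is None else pair_energies)

    def mfe_fold(self, sequence: str) -> tuple[float, str]:
        e = self.mfe_map.get(sequence, self.fold_energy if len(sequence) >= 4 else 0.0)
        return e, "." * len(sequence)

    def hybridize(self, site: str, anti_sd: str) -> tuple[float, str, int]:
        if site in self.duplex_map:
            return self.duplex_map[site], "", len(site)
        # antiparallel, ungapped: site 5'->3' against anti_sd 3'->5'
        e = sum(self.pair_energies.get((s, a), 0.0)
                for s, a in zip(site, reversed(anti_sd)))
        return e, "", len(site)

    def identity(self) -> str:
        return "toy"


class ViennaEngine:
    """Production adapter over the ViennaRNA nearest-neighbor model
    (Turner parameters)."""

    def __init__(self):
        import RNA  # deferred: optional dependency
        self._RNA = RNA
        self._mfe_cache: dict[str, tuple[float, str]] = {}
        self._dup_cache: dict[tuple[str, str], tuple[float, str]] = {}

    def mfe_fold(self, sequence: str) -> tuple[float, str]:
        if len(sequence) < 4:
            return 0.0, "." * len(sequence)
        hit = self._mfe_cache.get(sequence)
        if hit is None:
            structure, energy = self._RNA.fold(sequence)
            # open chain is always available: clamp tiny positive artefacts
            hit = (min(float(energy), 0.0), structure)
            self._mfe_cache[sequence] = hit
        return hit

    def hybridize(self, site: str, anti_sd: str) -> tuple[float, str, int]:
        key = (site, anti_sd)
        hit = self._dup_cache.get(key)
        if hit is None:
            dup = self._RNA.duplexfold(site, anti_sd)
            part = dup.structure.split("&")[0]
            if "(" in part:
                # dup.i is the 1-based end of the duplex region in the site;
                # trailing unpaired bases of the region do not count
                pair_end = dup.i - (len(part) - part.rfind("(") - 1)
            else:
                pair_end = len(site)
            hit = (float(dup.energy), dup.structure, pair_end)
            self._dup_cache[key] = hit
        return hit

    def identity(self) -> str:
        return f"viennarna-{getattr(self._RNA, '__version__', 'unknown')}"


# -- operations --------------------------------------------------------------

def spacing_penalty(s: int, model: RibosomeModel) -> float:
    """Energetic penalty (kcal/mol) for an aligned spacing of ``s`` nt.

    Zero at the optimal spacing; quadratic on the compressed branch;
    sigmoidally saturating on the stretched branch.  Non-decreasing away from
    the optimum on both branches.
    """
    if s < 0:
        raise ValueError("spacing must be a non-negative integer")
    d = s - model.optimal_spacing
    p = model.spacing_penalty_params
    if d == 0:
        return 0.0
    if d < 0:
        return p.compressed_quadratic * d * d
    return p.stretched_max * d * d / (d * d + p.stretched_halfwidth**2)


def translation_rate(dG_total: float, model: RibosomeModel) -> float:
    """Translation initiation rate r = rate_scale * exp(-beta * dG_total), au."""
    if not math.isfinite(dG_total):
        raise ValueError("dG_total must be finite")
    return model.rate_scale * math.exp(-model.beta * dG_total)


def rate_to_delta_g(rate: float, model: RibosomeModel) -> float:
    """Inverse of the rate law (au -> kcal/mol)."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return -math.log(rate / model.rate_scale) / model.beta


def delta_g_total(context: MRNAContext, model: RibosomeModel,
                  engine: FoldingEngine) -> EnergyBreakdown:
    """Five-term ribosome binding free energy for one mRNA.

    Candidate 16S rRNA pairing windows (9 nt, ending 0..``max_spacing`` nt
    before the start codon) are scanned.  For each candidate the final-state
    energy combines the mRNA:rRNA duplex with refolding of the mRNA regions
    that neither impede the hybridization nor overlap the ribosome footprint,
    plus the start-codon, spacing, and standby terms.  The minimum-total
    candidate is selected (ties broken toward the spacing closest to the
    optimum, then the most-upstream site), and the initial-state folding
    energy dG_mRNA is subtracted.
    """
    start_codon = context.start_codon
    if start_codon not in model.start_codon_energies:
        raise ValueError(
            f"CDS begins with {start_codon}, not a recognized start codon "
            f"({', '.join(sorted(model.start_codon_energies))})"
        )
    dG_start = model.start_codon_energies[start_codon]

    mrna = context.mrna()
    start_pos = len(context.leader)
    asd_len = len(model.anti_sd)
    if start_pos < asd_len:
        raise ValueError("5' leader too short to accommodate a 16S rRNA pairing site")

    dG_mRNA, _ = engine.mfe_fold(mrna)

    # mRNA downstream of the ribosome footprint refolds identically for every
    # candidate site; compute once.
    downstream = mrna[start_pos + model.footprint:]
    dG_down, _ = engine.mfe_fold(downstream)

    best = None  # keyed on (total, |s - opt|, binding_site)
    for window_s in range(0, model.max_spacing + 1):
        p = start_pos - asd_len - window_s
        if p < 0:
            break
        site = mrna[p:p + asd_len]
        dG_hyb, _, pair_end = engine.hybridize(site, model.anti_sd)
        # spacing is measured from the 3'-most actually paired base
        s = start_pos - (p + pair_end)
        if s < 0 or s > model.max_spacing:
            continue
        dG_up, _ = engine.mfe_fold(mrna[:p])
        dG_complex = dG_hyb + dG_up + dG_down
        dG_sp = spacing_penalty(s, model)
        total = dG_complex + dG_start + dG_sp + model.dG_standby
        key = (total, abs(s - model.optimal_spacing), p)
        if best is None or key < best[0]:
            best = (key, dG_complex, dG_sp, p, s)
    if best is None:
        raise ValueError("no feasible 16S rRNA pairing site within the spacing range")

    (_, dG_complex, dG_sp, p, s) = best
    dG_total_val = dG_complex + dG_start + dG_sp + model.dG_standby - dG_mRNA
    return EnergyBreakdown(
        dG_mRNA_rRNA=dG_complex,
        dG_start=dG_start,
        dG_spacing=dG_sp,
        dG_standby=model.dG_standby,
        dG_mRNA=dG_mRNA,
        dG_total=dG_total_val,
        binding_site=p,
        aligned_spacing=s,
    )


def predict_rate(context: MRNAContext, model: RibosomeModel,
                 engine: FoldingEngine) -> float:
    """Convenience: dG_total -> translation initiation rate (au)."""
    return translation_rate(delta_g_total(context, model, engine).dG_total, model)


@dataclass
class LibraryRates:
    """Per-variant predicted rates for a degenerate RBS; ``exhaustive`` is
    False when the library was too large to expand and was subsampled."""

    rates: dict[str, float]
    exhaustive: bool

    def __iter__(self):
        return iter(self.rates.items())


def predict_library_rates(
    context: MRNAContext,
    dseq: DegenerateSequence | str,
    model: RibosomeModel,
    engine: FoldingEngine,
    limit: int = 10**4,
    rng: np.random.Generator | None = None,
    cache: dict[str, float] | None = None,
) -> LibraryRates:
    """Predicted translation initiation rate for each variant of an RBS library.

    Libraries larger than ``limit`` are evaluated on a seeded subsample of
    ``limit`` draws and flagged (``exhaustive=False``).  ``cache`` maps a
    concrete RBS variant to its rate and may be shared across calls with the
    same context/model/engine.
    """
    d = dseq if isinstance(dseq, DegenerateSequence) else DegenerateSequence(dseq)
    n = count_variants(d)
    if n <= limit:
        variants = d.expand(limit)
        exhaustive = True
    else:
        if rng is None:
            raise ValueError(f"library has {n} variants (> {limit}); pass rng to subsample")
        variants = sorted({d.sample_variant(rng) for _ in range(limit)})
        exhaustive = False
    if cache is None:
        cache = {}
    rates: dict[str, float] = {}
    for v in variants:
        r = cache.get(v)
        if r is None:
            r = predict_rate(context.with_rbs(v), model, engine)
            cache[v] = r
        rates[v] = r
    return LibraryRates(rates=rates, exhaustive=exhaustive)
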