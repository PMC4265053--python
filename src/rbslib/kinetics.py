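"""De-dimensionalized mass-action kinetics of the crtEBI carotenoid pathway.

The canonical network decomposes the enzymatic conversion of the isoprenoid
precursors IPP and DMAPP to neurosporene into 24 reversible elementary
reactions (48 rate constants): reversible binding of substrate to enzyme,
reversible conversion between enzyme-bound states, and reversible release of
product, grouped into 10 overall catalyzed conversions by Idi, IspA, CrtE,
CrtB and CrtI.  Following the ensemble-modeling convention, all
concentrations are expressed as dimensionless ratios relative to a reference
pathway variant, so rate constants are apparent (dimensionless) quantities
and a pathway variant enters the model only through its total-enzyme
concentration ratios,

    e_gene = transcription_multiplier * r_gene / r_gene_reference,      (ratio)

its simulated end-point neurosporene production flux r_p (free neurosporene
accumulated over the 7-h batch horizon divided by 7 h), and the calibrated
flux-to-productivity map

    productivity = 196 ug/gDCW/h * r_p / r_p_reference.

Precursor pools (IPP, DMAPP) are boundary species held at a fixed
dimensionless level (``precursor_supply``), which makes upstream precursor
engineering (e.g. a dxs translation-rate sweep) a single-knob simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.integrate import odeint

try:  # JIT-compiled mass-action kernel; plain numpy otherwise
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "PathwayVariant",
    "ReferenceState",
    "SimulationResult",
    "build_canonical_network",
    "load_network",
    "parse_network_definition",
    "enzyme_ratio",
    "simulate",
    "productivity",
    "default_parameters",
    "rescale_parameters",
    "REFERENCE_TRANSLATION_RATES",
    "REFERENCE_PRODUCTIVITY",
    "CRT_GENES",
]

#: Predicted translation initiation rates (au) of the reference pathway
#: variant for crtE, crtB, crtI, and its measured neurosporene productivity.
REFERENCE_TRANSLATION_RATES = (72268.0, 20496.0, 203462.0)
REFERENCE_PRODUCTIVITY = 196.0  # ug/gDCW/h

CRT_GENES = ("crtE", "crtB", "crtI")
_CRT_ENZYMES = ("CrtE", "CrtB", "CrtI")

_NETWORK_RESOURCE = "crtebi_network_v1.tsv"


@dataclass(frozen=True)
class Reaction:
    """One reversible elementary reaction with mass-action kinetics."""

    id: str
    enzyme: str
    conversion: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    kind: str  # bind | cat | release

    @property
    def kf_id(self) -> str:
        return f"kf_{self.id}"

    @property
    def kr_id(self) -> str:
        return f"kr_{self.id}"


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, reversible elementary reactions and their grouping."""

    reactions: tuple[Reaction, ...]
    boundary_species: frozenset[str] = frozenset({"IPP", "DMAPP"})
    product_species: str = "Neurosporene"

    @property
    def enzymes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.enzyme, None)
        return tuple(seen)

    @property
    def conversions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.conversion, None)
        return tuple(seen)

    @property
    def species(self) -> tuple[str, ...]:
        """Deterministic species order: metabolites, free enzymes, complexes."""
        mets: dict[str, None] = {}
        complexes: dict[str, None] = {}
        enz = set(self.enzymes)
        for r in self.reactions:
            for s in r.reactants + r.products:
                if ":" in s:
                    complexes.setdefault(s, None)
                elif s not in enz:
                    mets.setdefault(s, None)
        return tuple(mets) + self.enzymes + tuple(complexes)

    @property
    def rate_constant_ids(self) -> tuple[str, ...]:
        out = []
        for r in self.reactions:
            out.extend((r.kf_id, r.kr_id))
        return tuple(out)

    def enzyme_members(self, enzyme: str) -> tuple[str, ...]:
        """Species carrying one unit of ``enzyme`` (free form + complexes)."""
        return (enzyme,) + tuple(
            s for s in self.species if s.startswith(enzyme + ":")
        )

    def conversion_reactions(self, conversion: str) -> tuple[Reaction, ...]:
        return tuple(r for r in self.reactions if r.conversion == conversion)

    def validate(self) -> None:
        species = set(self.species)
        for r in self.reactions:
            assert set(r.reactants + r.products) <= species
        for c in {s for s in self.species if ":" in s}:
            assert any(c in r.products for r in self.reactions), \
                f"complex {c} never formed"
        for e in self.enzymes:
            # each elementary reaction conserves the enzyme's "atoms"
            for r in self.reactions:
                members = set(self.enzyme_members(e))
                lhs = sum(s in members for s in r.reactants)
                rhs = sum(s in members for s in r.products)
                assert lhs == rhs, f"{r.id} does not conserve {e}"

    def definition_text(self) -> str:
        lines = ["# id\tenzyme\tconversion\treactants\tproducts\tkind"]
        for r in self.reactions:
            lines.append("\t".join([
                r.id, r.enzyme, r.conversion,
                " + ".join(r.reactants), " + ".join(r.products), r.kind,
            ]))
        return "\n".join(lines) + "\n"


def parse_network_definition(text: str) -> ReactionNetwork:
    """Parse the human-readable reaction-list format (see the shipped file)."""
    reactions = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rid, enzyme, conversion, lhs, rhs, kind = line.split("\t")
        reactions.append(Reaction(
            id=rid, enzyme=enzyme, conversion=conversion,
            reactants=tuple(s.strip() for s in lhs.split("+")),
            products=tuple(s.strip() for s in rhs.split("+")),
            kind=kind,
        ))
    net = ReactionNetwork(reactions=tuple(reactions))
    net.validate()
    return net


def load_network(path: str) -> ReactionNetwork:
    with open(path) as fh:
        return parse_network_definition(fh.read())


def build_canonical_network() -> ReactionNetwork:
    """The canonical crtEBI network from the versioned definition shipped
    with the package (24 reversible reactions, 48 constants, 10 conversions)."""
    text = resources.files("rbslib.data").joinpath(_NETWORK_RESOURCE).read_text()
    return parse_network_definition(text)


# -- pathway variants --------------------------------------------------------

@dataclass(frozen=True)
class PathwayVariant:
    """A crtEBI pathway variant described by its expression-level knobs."""

    translation_rates: tuple[float, float, float]  # crtE, crtB, crtI (au)
    transcription_multiplier: float = 1.0
    precursor_supply: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.translation_rates):
            raise ValueError("translation rates must be positive")
        if self.transcription_multiplier <= 0 or self.precursor_supply <= 0:
            raise ValueError("multipliers must be positive")


@dataclass
class ReferenceState:
    """The reference pathway variant anchoring the dimensionless model."""

    translation_rates: tuple[float, float, float] = REFERENCE_TRANSLATION_RATES
    productivity: float = REFERENCE_PRODUCTIVITY  # ug/gDCW/h
    r_p_ref: float | None = None                  # simulated reference flux

    @property
    def variant(self) -> PathwayVariant:
        return PathwayVariant(self.translation_rates, label="reference")


def enzyme_ratio(variant: PathwayVariant,
                 reference: ReferenceState) -> tuple[float, float, float]:
    """Total-enzyme concentration ratios (eE, eB, eI): each is the
    transcription multiplier times the variant/reference translation-rate
    ratio (the reference variant at multiplier 1 maps to (1, 1, 1))."""
    return tuple(
        variant.transcription_multiplier * r / r0
        for r, r0 in zip(variant.translation_rates, reference.translation_rates)
    )


# -- simulation --------------------------------------------------------------

#: Default batch horizon matching the experimental post-induction period.
DEFAULT_HORIZON_H = 7.0


@dataclass
class SimulationResult:
    times: np.ndarray
    concentrations: np.ndarray   # shape (len(times), n_species)
    species: tuple[str, ...]
    r_p: float                   # product flux: free product at horizon / horizon
    horizon: float

    def trajectory(self, species: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(species)]

    def enzyme_total(self, network: ReactionNetwork, enzyme: str) -> np.ndarray:
        idx = [self.species.index(s) for s in network.enzyme_members(enzyme)]
        return self.concentrations[:, idx].sum(axis=1)


class _CompiledNetwork:
    """Index arrays for a fast mass-action right-hand side."""

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.species = network.species
        sidx = {s: i for i, s in enumerate(self.species)}
        n_s, n_r = len(self.species), len(network.reactions)
        # pad with a phantom species fixed at 1.0 for unimolecular sides
        self.pad = n_s
        def side_idx(side):
            a = np.full(n_r, self.pad, dtype=np.intp)
            b = np.full(n_r, self.pad, dtype=np.intp)
            for j, r in enumerate(network.reactions):
                sp = side(r)
                a[j] = sidx[sp[0]]
                if len(sp) > 1:
                    b[j] = sidx[sp[1]]
                if len(sp) > 2:  # pragma: no cover - network is at most bimolecular
                    raise ValueError("elementary reactions are at most bimolecular")
            return a, b
        self.r1, self.r2 = side_idx(lambda r: r.reactants)
        self.p1, self.p2 = side_idx(lambda r: r.products)
        S = np.zeros((n_s, n_r))
        for j, r in enumerate(network.reactions):
            for sp in r.reactants:
                S[sidx[sp], j] -= 1.0
            for sp in r.products:
                S[sidx[sp], j] += 1.0
        for bsp in network.boundary_species:
            if bsp in sidx:
                S[sidx[bsp], :] = 0.0  # boundary pools are held fixed
        self.S = S

    def rhs(self, y: np.ndarray, t: float, kf: np.ndarray, kr: np.ndarray) -> np.ndarray:
        if _RHS_KERNEL is not None:
            return _RHS_KERNEL(y, kf, kr, self.r1, self.r2, self.p1, self.p2, self.S)
        z = np.append(y, 1.0)
        v = kf * z[self.r1] * z[self.r2] - kr * z[self.p1] * z[self.p2]
        return self.S @ v


def _make_rhs_kernel():
    if _njit is None:
        return None

    @_njit(cache=False, fastmath=False)
    def kernel(y, kf, kr, r1, r2, p1, p2, S):  # pragma: no cover - compiled
        n_s = y.shape[0]
        n_r = kf.shape[0]
        dy = np.zeros(n_s)
        for j in range(n_r):
            a = y[r1[j]] if r1[j] < n_s else 1.0
            b = y[r2[j]] if r2[j] < n_s else 1.0
            c = y[p1[j]] if p1[j] < n_s else 1.0
            d = y[p2[j]] if p2[j] < n_s else 1.0
            v = kf[j] * a * b - kr[j] * c * d
            for i in range(n_s):
                s = S[i, j]
                if s != 0.0:
                    dy[i] += s * v
        return dy

    return kernel


_RHS_KERNEL = _make_rhs_kernel()


_compiled_cache: dict[int, _CompiledNetwork] = {}


def _compiled(network: ReactionNetwork) -> _CompiledNetwork:
    key = id(network)
    c = _compiled_cache.get(key)
    if c is None or c.network is not network:
        c = _CompiledNetwork(network)
        _compiled_cache[key] = c
    return c


class SimulationError(RuntimeError):
    def __init__(self, message: str, params=None, state=None):
        super().__init__(message)
        self.params = params
        self.state = state


def simulate(
    network: ReactionNetwork,
    params: dict[str, float],
    ratios: Sequence[float] = (1.0, 1.0, 1.0),
    idi_ratio: float = 1.0,
    ispa_ratio: float = 1.0,
    precursor_supply: float = 1.0,
    horizon: float = DEFAULT_HORIZON_H,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_report: int = 25,
) -> SimulationResult:
    """Integrate the dimensionless mass-action ODEs over the batch horizon.

    ``ratios`` are the (CrtE, CrtB, CrtI) total-enzyme ratios; Idi and IspA
    default to 1 (their expression is not varied).  Initial conditions: free
    enzymes at their total ratios, boundary precursors at
    ``precursor_supply``, every other species at zero.  Returns trajectories
    and the end-point product flux r_p.
    """
    if min(params.values()) < 0:
        raise ValueError("rate constants must be non-negative")
    if min(ratios) < 0 or idi_ratio < 0 or ispa_ratio < 0:
        raise ValueError("enzyme ratios must be non-negative")
    comp = _compiled(network)
    kf = np.array([params[r.kf_id] for r in network.reactions])
    kr = np.array([params[r.kr_id] for r in network.reactions])

    sidx = {s: i for i, s in enumerate(comp.species)}
    y0 = np.zeros(len(comp.species))
    for bsp in network.boundary_species:
        y0[sidx[bsp]] = precursor_supply
    totals = dict(zip(_CRT_ENZYMES, ratios))
    totals.setdefault("Idi", idi_ratio)
    totals.setdefault("IspA", ispa_ratio)
    for enz in network.enzymes:
        y0[sidx[enz]] = totals.get(enz, 1.0)

    times = np.linspace(0.0, horizon, n_report)
    y, info = odeint(
        comp.rhs, y0, times, args=(kf, kr),
        rtol=rtol, atol=atol, mxstep=50000, full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"stiff integration failed: {info['message']}",
            params=params, state=y[-1],
        )
    if y.min() < -1e-6:
        raise SimulationError(
            f"negative concentration beyond tolerance (min {y.min():.3e})",
            params=params, state=y[-1],
        )
    np.clip(y, 0.0, None, out=y)
    r_p = float(y[-1, sidx[network.product_species]]) / horizon
    return SimulationResult(
        times=times, concentrations=y, species=comp.species,
        r_p=r_p, horizon=horizon,
    )


def productivity(r_p: float, reference: ReferenceState) -> float:
    """Map a simulated flux to a productivity (ug/gDCW/h) by comparison with
    the reference pathway: productivity = 196 * r_p / r_p_ref."""
    if reference.r_p_ref is None:
        raise ValueError("reference flux not initialized; simulate the "
                         "reference variant first and set r_p_ref")
    if reference.r_p_ref <= 0:
        raise ValueError("reference flux must be positive")
    return reference.productivity * r_p / reference.r_p_ref


# -- parameter helpers -------------------------------------------------------

def default_parameters(network: ReactionNetwork) -> dict[str, float]:
    """A plain, valid (positive) parameter set: fast reversible binding and
    release, slower forward-favored catalysis.  Dimensionless, per hour."""
    params: dict[str, float] = {}
    for r in network.reactions:
        if r.kind == "bind":
            params[r.kf_id], params[r.kr_id] = 40.0, 10.0
        elif r.kind == "cat":
            params[r.kf_id], params[r.kr_id] = 20.0, 1.0
        else:  # release
            params[r.kf_id], params[r.kr_id] = 40.0, 4.0
    return params


def rescale_parameters(network: ReactionNetwork, params: dict[str, float],
                       lam: float) -> dict[str, float]:
    """Compensating parameter transform for a uniform rescaling of all
    reference concentrations by ``lam``: kf' = kf * lam^(order-1) per side.

    With these parameters the dimensionless trajectories scale as y/lam, so
    the flux ratio r_p / r_p_ref — and hence every productivity prediction —
    is unchanged.
    """
    if lam <= 0:
        raise ValueError("rescaling factor must be positive")
    out = dict(params)
    for r in network.reactions:
        out[r.kf_id] = params[r.kf_id] * lam ** (len(r.reactants) - 1)
        out[r.kr_id] = params[r.kr_id] * lam ** (len(r.products) - 1)
    return out
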