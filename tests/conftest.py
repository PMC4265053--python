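"""Shared fixtures: engines, networks, parameter sets, toy design problems."""

import math

import numpy as np
import pytest

from rbslib import biophysics as bp
from rbslib import identify as idf
from rbslib import kinetics as kn


@pytest.fixture(scope="session")
def model():
    return bp.RibosomeModel()


@pytest.fixture
def toy_engine():
    return bp.ToyEngine()


@pytest.fixture(scope="session")
def vienna_engine():
    return bp.ViennaEngine()


@pytest.fixture(scope="session")
def strong_sd_context():
    """SD consensus placed ~4 nt upstream of an AUG start."""
    return bp.MRNAContext(
        pre_sequence="",
        rbs="AAACUUUCAGCAUAAAGCUAAUUAAGGAGGUAAAA",
        cds="AUGGCUUCCUCCGAAGACGUUAUCAAAGAGUUCAU",
        organism="E. coli",
    )


@pytest.fixture(scope="session")
def network():
    return kn.build_canonical_network()


@pytest.fixture(scope="session")
def true_params(network):
    """Seeded synthetic ground-truth kinetic parameter set."""
    return idf.example_true_parameters(seed=42, network=network)


@pytest.fixture(scope="session")
def seamap(network, true_params):
    from rbslib.applications import SEAMAP

    return SEAMAP(network=network, params=true_params,
                  sim_rtol=1e-6, sim_atol=1e-9)


class AdditiveToyProblem:
    """Tiny library-design problem with position-additive energies.

    Each base at each RBS position contributes a fixed, seeded energy, so
    every variant's translation rate is known in closed form and the full
    degenerate design space (16^length candidates) is enumerable.
    """

    def __init__(self, length: int = 3, seed: int = 2024,
                 r_min: float = 2500.0, r_max: float = 40000.0, W: float = 0.2):
        rng = np.random.default_rng(seed)
        self.length = length
        self.pos_energy = {
            (i, b): float(rng.uniform(-2.0, 0.0))
            for i in range(length) for b in "ACGU"
        }
        self.r_min, self.r_max, self.W = r_min, r_max, W
        self._cache: dict[str, float] = {}

    def rate(self, variant: str) -> float:
        r = self._cache.get(variant)
        if r is None:
            dg = sum(self.pos_energy[(i, b)] for i, b in enumerate(variant))
            r = self._cache.setdefault(variant, 2500.0 * math.exp(-0.45 * dg))
        return r

    def rate_fn(self, dseq):
        return {v: self.rate(v) for v in dseq.expand(10**4)}, True


@pytest.fixture(scope="session")
def toy_problem():
    return AdditiveToyProblem()


@pytest.fixture(scope="session")
def toy_problem_brute_force(toy_problem):
    """Exhaustive optimum of the toy problem over all 16^3 candidates."""
    import itertools

    from rbslib import design as dz
    from rbslib.degenerate import DEGENERATE_ALPHABET, DegenerateSequence

    grid = dz.BinGrid(toy_problem.r_min, toy_problem.r_max, toy_problem.W)
    best_F, best_letters = -np.inf, None
    for combo in itertools.product(DEGENERATE_ALPHABET, repeat=toy_problem.length):
        d = DegenerateSequence("".join(combo))
        rates, _ = toy_problem.rate_fn(d)
        F = dz.objective(dz.coverage(list(rates.values()), grid), d.count_variants())
        if F > best_F:
            best_F, best_letters = F, d.letters
    return best_F, best_letters
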