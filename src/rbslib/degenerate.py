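"""Algebra over IUPAC-degenerate nucleotide sequences.

A degenerate sequence is a string over the 16-letter IUPAC nucleotide code in
which each letter stands for a set of 1-4 concrete bases.  A single degenerate
oligonucleotide therefore compactly encodes a whole mixture (library) of
concrete sequences: the library size is the product of the per-position
cardinalities.  This module provides validation, counting, exhaustive
expansion, uniform sampling, and the edit operators that the library-design
genetic algorithm composes (degeneracy increase/decrease, base substitution,
recombination, and fresh random sequences).

Sequences are held internally in the RNA alphabet (``T`` is normalized to
``U`` on input); readers accept both DNA and RNA spellings.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "DEGENERATE_ALPHABET",
    "BASES",
    "DegenerateSequence",
    "InvalidLetterError",
    "NoOpEditError",
    "count_variants",
    "expand",
    "sample_variant",
    "edit",
    "EDIT_OPERATORS",
    "code_for_bases",
    "supersets_of",
    "strict_subsets_of",
    "random_concrete_sequence",
    "design_space_size",
    "DEFAULT_EXPAND_LIMIT",
]

#: IUPAC code -> the set of concrete bases it stands for (RNA alphabet).
DEGENERATE_ALPHABET: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "W": "AU", "S": "CG", "M": "AC", "K": "GU", "R": "AG", "Y": "CU",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

BASES = "ACGU"

_CODE_OF: dict[frozenset[str], str] = {
    frozenset(bases): code for code, bases in DEGENERATE_ALPHABET.items()
}

#: Expansion refuses above this many variants; callers switch to sampling.
DEFAULT_EXPAND_LIMIT = 10**6


class InvalidLetterError(ValueError):
    """A sequence letter outside the 16-letter IUPAC alphabet."""

    def __init__(self, position: int, letter: str):
        self.position = position
        self.letter = letter
        super().__init__(
            f"invalid IUPAC letter {letter!r} at position {position}; "
            f"allowed letters are {''.join(sorted(DEGENERATE_ALPHABET))} (and T for U)"
        )


class NoOpEditError(RuntimeError):
    """Requested edit has no eligible position ("no-op possible"); redraw."""


def _normalize(letters: str) -> str:
    s = letters.upper().replace("T", "U")
    for i, ch in enumerate(s):
        if ch not in DEGENERATE_ALPHABET:
            raise InvalidLetterError(i, letters[i])
    return s


@dataclass(frozen=True)
class DegenerateSequence:
    """An IUPAC-16 string encoding a set of concrete RNA sequences."""

    letters: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "letters", _normalize(self.letters))
        if len(self.letters) == 0:
            raise ValueError("degenerate sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.letters)

    def __str__(self) -> str:
        return self.letters

    def bases_at(self, position: int) -> str:
        """Concrete bases allowed at ``position`` (sorted A<C<G<U)."""
        return DEGENERATE_ALPHABET[self.letters[position]]

    @property
    def cardinalities(self) -> tuple[int, ...]:
        return tuple(len(DEGENERATE_ALPHABET[c]) for c in self.letters)

    @property
    def is_degenerate(self) -> bool:
        return any(k > 1 for k in self.cardinalities)

    def count_variants(self) -> int:
        n = 1
        for k in self.cardinalities:
            n *= k
        return n

    def expand(self, limit: int = DEFAULT_EXPAND_LIMIT) -> list[str]:
        """All concrete variants, deduplicated, in lexicographic order.

        Raises ``ValueError`` carrying the variant count when it exceeds
        ``limit``, so callers can switch to sampling.
        """
        n = self.count_variants()
        if n > limit:
            raise ValueError(
                f"expansion of {self.letters} has {n} variants, over the "
                f"limit of {limit}; use sample_variant instead"
            )
        # per-position base sets are sorted, so the cross product is already
        # lexicographic and free of duplicates
        return ["".join(p) for p in itertools.product(*(self.bases_at(i) for i in range(len(self))))]

    def iter_variants(self) -> Iterator[str]:
        for p in itertools.product(*(self.bases_at(i) for i in range(len(self)))):
            yield "".join(p)

    def sample_variant(self, rng: np.random.Generator) -> str:
        """One concrete variant drawn uniformly over the expansion."""
        return "".join(
            self.bases_at(i)[rng.integers(len(self.bases_at(i)))]
            for i in range(len(self))
        )

    def contains(self, concrete: str) -> bool:
        s = _normalize(concrete)
        return len(s) == len(self) and all(
            base in self.bases_at(i) for i, base in enumerate(s)
        )


# -- module-level operation façade -------------------------------------------

def count_variants(dseq: DegenerateSequence | str) -> int:
    """Number of concrete sequences encoded by ``dseq`` (product of
    per-position code cardinalities)."""
    return _as_dseq(dseq).count_variants()


def expand(dseq: DegenerateSequence | str, limit: int = DEFAULT_EXPAND_LIMIT) -> list[str]:
    return _as_dseq(dseq).expand(limit)


def sample_variant(dseq: DegenerateSequence | str, rng: np.random.Generator) -> str:
    return _as_dseq(dseq).sample_variant(rng)


def _as_dseq(dseq: DegenerateSequence | str) -> DegenerateSequence:
    return dseq if isinstance(dseq, DegenerateSequence) else DegenerateSequence(dseq)


def code_for_bases(bases: str) -> str:
    """The IUPAC letter for a non-empty set of concrete bases."""
    key = frozenset(_normalize(bases))
    try:
        return _CODE_OF[key]
    except KeyError:  # pragma: no cover - unreachable for valid base sets
        raise ValueError(f"no IUPAC code for base set {bases!r}") from None


def supersets_of(code: str) -> list[str]:
    """IUPAC codes whose base set strictly contains that of ``code``."""
    base = set(DEGENERATE_ALPHABET[_normalize(code)])
    return sorted(
        c for c, b in DEGENERATE_ALPHABET.items()
        if base < set(b)
    )


def strict_subsets_of(code: str) -> list[str]:
    """IUPAC codes whose base set is strictly contained in that of ``code``."""
    base = set(DEGENERATE_ALPHABET[_normalize(code)])
    return sorted(
        c for c, b in DEGENERATE_ALPHABET.items()
        if set(b) < base
    )


def random_concrete_sequence(length: int, rng: np.random.Generator) -> DegenerateSequence:
    """A random non-degenerate sequence of the given length."""
    return DegenerateSequence("".join(BASES[i] for i in rng.integers(4, size=length)))


def design_space_size(length: int) -> int:
    """Number of distinct degenerate sequences of ``length`` (16^length)."""
    return 16**length


# -- edit operators -----------------------------------------------------------

def _replace(dseq: DegenerateSequence, pos: int, code: str) -> DegenerateSequence:
    s = dseq.letters
    return DegenerateSequence(s[:pos] + code + s[pos + 1:])


def _increase_degeneracy(dseq: DegenerateSequence, rng: np.random.Generator) -> DegenerateSequence:
    eligible = [i for i, c in enumerate(dseq.letters) if c != "N"]
    if not eligible:
        raise NoOpEditError("no position can gain degeneracy (all N)")
    pos = eligible[rng.integers(len(eligible))]
    choices = supersets_of(dseq.letters[pos])
    return _replace(dseq, pos, choices[rng.integers(len(choices))])


def _decrease_degeneracy(dseq: DegenerateSequence, rng: np.random.Generator) -> DegenerateSequence:
    eligible = [i for i, k in enumerate(dseq.cardinalities) if k > 1]
    if not eligible:
        raise NoOpEditError("no degenerate position to reduce")
    pos = eligible[rng.integers(len(eligible))]
    choices = strict_subsets_of(dseq.letters[pos])
    return _replace(dseq, pos, choices[rng.integers(len(choices))])


def _substitute(dseq: DegenerateSequence, rng: np.random.Generator) -> DegenerateSequence:
    eligible = [i for i, k in enumerate(dseq.cardinalities) if k == 1]
    if not eligible:
        raise NoOpEditError("no non-degenerate position to substitute")
    pos = eligible[rng.integers(len(eligible))]
    others = [b for b in BASES if b != dseq.letters[pos]]
    return _replace(dseq, pos, others[rng.integers(3)])


def _recombine(a: DegenerateSequence, b: DegenerateSequence,
               rng: np.random.Generator) -> DegenerateSequence:
    if len(a) != len(b):
        raise ValueError(f"recombination partners differ in length ({len(a)} vs {len(b)})")
    junction = int(rng.integers(1, len(a)))  # at least one letter from each parent
    return DegenerateSequence(a.letters[:junction] + b.letters[junction:])


def recombine_at(a: DegenerateSequence, b: DegenerateSequence, junction: int) -> DegenerateSequence:
    """Deterministic splice: prefix of ``a`` up to ``junction`` + suffix of ``b``."""
    if len(a) != len(b):
        raise ValueError(f"recombination partners differ in length ({len(a)} vs {len(b)})")
    return DegenerateSequence(a.letters[:junction] + b.letters[junction:])


EDIT_OPERATORS = (
    "increase_degeneracy",
    "decrease_degeneracy",
    "substitute",
    "recombine",
    "fresh_random",
)


def edit(
    dseq: DegenerateSequence | str,
    operator: str,
    rng: np.random.Generator,
    partner: DegenerateSequence | str | None = None,
) -> DegenerateSequence:
    """Apply one GA edit operator; output length always equals input length.

    ``recombine`` requires an equal-length ``partner``.  Operators with no
    eligible position raise :class:`NoOpEditError` so the caller can redraw.
    """
    d = _as_dseq(dseq)
    if operator == "increase_degeneracy":
        return _increase_degeneracy(d, rng)
    if operator == "decrease_degeneracy":
        return _decrease_degeneracy(d, rng)
    if operator == "substitute":
        return _substitute(d, rng)
    if operator == "recombine":
        if partner is None:
            raise ValueError("recombine requires a partner sequence")
        return _recombine(d, _as_dseq(partner), rng)
    if operator == "fresh_random":
        return random_concrete_sequence(len(d), rng)
    raise ValueError(f"unknown edit operator {operator!r}; one of {EDIT_OPERATORS}")
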