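"""Base alphabets, sequences and Watson-Crick complementarity.

The default alphabet is the four-letter DNA alphabet (A, C, G, T) with the
usual Watson-Crick complement map.  Generalized alphabets with any even number
of bases and a total complementary pairing are supported for counterfactual
pool calculations (2-letter alphabets, >4-letter alphabets); for those the
stacking energetics are carried as a single per-alphabet average rather than a
per-quartet table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class InvalidInputError(ValueError):
    """Raised when an argument violates a documented precondition."""


@dataclass(frozen=True)
class AlphabetSpec:
    """A base set with an involutive complement map.

    Parameters
    ----------
    bases
        Ordered base symbols.
    complement
        Map base -> complementary base.  Must be an involution covering every
        base exactly once; self-complementary bases are not allowed, so the
        number of bases is even.
    strong
        Subset of bases counted as "strong" (C/G-class) for composition
        bookkeeping.  Empty for alphabets where composition plays no role.
    """

    bases: tuple[str, ...]
    complement: dict[str, str] = field(hash=False)
    strong: frozenset[str] = frozenset()
    #: optional per-alphabet averaged stack (dH kcal/mol, dS cal/(mol K));
    #: when set it replaces the composition-dependent quartet average.
    avg_stack: Optional[tuple[float, float]] = None
    #: optional per-end averaged initiation (dH, dS) accompanying ``avg_stack``.
    avg_init_per_end: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if len(self.bases) < 2 or len(self.bases) % 2 != 0:
            raise InvalidInputError(
                f"alphabet must have an even number (>= 2) of bases, got {len(self.bases)}"
            )
        if set(self.complement) != set(self.bases):
            raise InvalidInputError("complement map must cover exactly the alphabet bases")
        for b in self.bases:
            c = self.complement[b]
            if c not in self.complement or self.complement[c] != b or c == b:
                raise InvalidInputError(
                    "complement must be an involution without self-complementary bases"
                )

    @property
    def n_b(self) -> int:
        return len(self.bases)

    def check(self, seq: str) -> None:
        bad = set(seq) - set(self.bases)
        if bad:
            raise InvalidInputError(f"unknown symbols {sorted(bad)} for alphabet {self.bases}")

    def f_cg(self, seq: str) -> float:
        """Fraction of strong bases in ``seq``."""
        self.check(seq)
        if not seq:
            raise InvalidInputError("empty sequence")
        return sum(b in self.strong for b in seq) / len(seq)


DNA4 = AlphabetSpec(
    bases=("A", "C", "G", "T"),
    complement={"A": "T", "T": "A", "C": "G", "G": "C"},
    strong=frozenset({"C", "G"}),
)


def two_base_alphabet() -> AlphabetSpec:
    """A minimal complementary alphabet with a single base pair (X-Y)."""
    return AlphabetSpec(bases=("X", "Y"), complement={"X": "Y", "Y": "X"})


def n_base_alphabet(n_b: int) -> AlphabetSpec:
    """A generalized WC-type alphabet with ``n_b`` single-letter bases paired
    consecutively (first with second, third with fourth, ...)."""
    if n_b < 2 or n_b % 2:
        raise InvalidInputError("n_b must be even and >= 2")
    symbols = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if n_b > len(symbols):
        raise InvalidInputError(f"n_b must be <= {len(symbols)}")
    bases = tuple(symbols[:n_b])
    comp = {}
    for i in range(0, n_b, 2):
        comp[bases[i]] = bases[i + 1]
        comp[bases[i + 1]] = bases[i]
    return AlphabetSpec(bases=bases, complement=comp)


def reverse_complement(seq: str, alphabet: AlphabetSpec = DNA4) -> str:
    """Reverse-complement of ``seq``; applying it twice is the identity."""
    alphabet.check(seq)
    return "".join(alphabet.complement[b] for b in reversed(seq))


def is_complementary_pair(seq_a: str, seq_b: str, alphabet: AlphabetSpec = DNA4) -> bool:
    return len(seq_a) == len(seq_b) and reverse_complement(seq_a, alphabet) == seq_b


def random_sequence(rng, length: int, alphabet: AlphabetSpec = DNA4,
                    n_strong: Optional[int] = None) -> str:
    """Uniform random sequence; with ``n_strong`` given, exactly that many strong bases.

    ``rng`` is a :class:`numpy.random.Generator`.
    """
    if length < 1:
        raise InvalidInputError("length must be >= 1")
    if n_strong is None:
        idx = rng.integers(0, alphabet.n_b, size=length)
        return "".join(alphabet.bases[i] for i in idx)
    if not 0 <= n_strong <= length:
        raise InvalidInputError("n_strong out of range")
    strong = sorted(alphabet.strong)
    weak = sorted(set(alphabet.bases) - alphabet.strong)
    if not strong:
        raise InvalidInputError("alphabet has no strong bases")
    picks = [strong[i] for i in rng.integers(0, len(strong), size=n_strong)]
    picks += [weak[i] for i in rng.integers(0, len(weak), size=length - n_strong)]
    pos = rng.permutation(length)
    out = [""] * length
    for p, b in zip(pos, picks):
        out[p] = b
    return "".join(out)


def longest_complementary_run(seq_a: str, seq_b: str, alphabet: AlphabetSpec = DNA4) -> int:
    """Longest run of consecutive WC-paired positions between two strands,
    maximized over all mutual alignments (antiparallel, all 2L-1 shifts)."""
    alphabet.check(seq_a)
    alphabet.check(seq_b)
    rb = seq_b[::-1]  # antiparallel partner read 3'->5'
    la, lb = len(seq_a), len(rb)
    best = 0
    for shift in range(-(lb - 1), la):
        run = 0
        for i in range(max(0, shift), min(la, lb + shift)):
            if alphabet.complement[seq_a[i]] == rb[i - shift]:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best
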