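"""Mutation/variant algebra over a protein sequence.

A variant is a set of single-site substitutions applied to a wild-type
sequence, written in the field's usual slash-joined notation, e.g.
``"L6P/D17V"``.  Positions are 1-based and refer to the supplied wild-type
sequence exactly as given (no signal-peptide offset logic).  ``"WT"`` denotes
the empty variant.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Iterator, Sequence

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)
_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


class VariantError(ValueError):
    """Malformed variant string or mutation inconsistent with the sequence."""


@dataclass(frozen=True, slots=True)
class Mutation:
    """A single-site substitution: ``wt_aa`` at 1-based ``position`` -> ``mut_aa``."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        for aa, label in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in _AA_SET:
                raise VariantError(f"{label} {aa!r} is not a standard amino acid")
        if self.wt_aa == self.mut_aa:
            raise VariantError(f"silent mutation {self.wt_aa}{self.position}{self.mut_aa}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


class Variant:
    """An immutable set of mutations at pairwise-distinct positions.

    The canonical string form is position-sorted and slash-joined
    (``"L6P/D17V"``); the empty variant prints as ``"WT"``.
    """

    __slots__ = ("mutations",)

    mutations: tuple[Mutation, ...]

    def __init__(self, mutations: Iterable[Mutation] = ()):
        muts = tuple(sorted(mutations, key=lambda m: m.position))
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            dupes = sorted({p for p in positions if positions.count(p) > 1})
            raise VariantError(f"duplicate positions in variant: {dupes}")
        object.__setattr__(self, "mutations", muts)

    @classmethod
    def _from_sorted(cls, mutations: tuple[Mutation, ...]) -> "Variant":
        """Fast path for enumeration: caller guarantees sorted, distinct positions."""
        v = object.__new__(cls)
        object.__setattr__(v, "mutations", mutations)
        return v

    def __setattr__(self, name, value):  # pragma: no cover - immutability guard
        raise AttributeError("Variant is immutable")

    @property
    def order(self) -> int:
        return len(self.mutations)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(m.position for m in self.mutations)

    def __str__(self) -> str:
        return "/".join(str(m) for m in self.mutations) if self.mutations else "WT"

    def __repr__(self) -> str:
        return f"Variant({self!s})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Variant) and self.mutations == other.mutations

    def __hash__(self) -> int:
        return hash(self.mutations)

    def __contains__(self, m: Mutation) -> bool:
        return m in self.mutations

    def __iter__(self) -> Iterator[Mutation]:
        return iter(self.mutations)

    def union(self, other: "Variant | Iterable[Mutation]") -> "Variant":
        """Combine two variants; positions must be disjoint."""
        extra = other.mutations if isinstance(other, Variant) else tuple(other)
        return Variant(self.mutations + extra)

    def difference(self, other: "Variant | Iterable[Mutation]") -> "Variant":
        drop = set(other.mutations if isinstance(other, Variant) else other)
        return Variant(m for m in self.mutations if m not in drop)

    def contains_all(self, other: "Variant | Iterable[Mutation]") -> bool:
        mine = set(self.mutations)
        theirs = other.mutations if isinstance(other, Variant) else other
        return all(m in mine for m in theirs)


WILD_TYPE = Variant()


def parse_variant(text: str, wild_type: str | None = None) -> Variant:
    """Parse ``"L6P/D17V"``-style notation (or ``"WT"``) into a :class:`Variant`.

    When ``wild_type`` is given, each token's expected residue is checked
    against the sequence.  ``format(parse(x))`` round-trips to the canonical
    (position-sorted) form of ``x``.
    """
    text = text.strip()
    if not text:
        raise VariantError("empty variant string")
    if text.upper() == "WT":
        return WILD_TYPE
    mutations = []
    for token in text.split("/"):
        m = _TOKEN_RE.match(token.strip())
        if m is None:
            raise VariantError(f"malformed mutation token {token!r}")
        wt_aa, pos, mut_aa = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        mutations.append(Mutation(pos, wt_aa, mut_aa))
    v = Variant(mutations)
    if wild_type is not None:
        validate_variant(v, wild_type)
    return v


def validate_variant(v: Variant, wild_type: str) -> None:
    """Check every mutation's wt_aa against the wild-type sequence."""
    for m in v.mutations:
        if m.position > len(wild_type):
            raise VariantError(
                f"position {m.position} beyond sequence length {len(wild_type)}"
            )
        found = wild_type[m.position - 1]
        if found != m.wt_aa:
            raise VariantError(
                f"mutation {m}: wild type has {found!r} at position {m.position}, "
                f"expected {m.wt_aa!r}"
            )


def apply_variant(v: Variant, wild_type: str) -> str:
    """Apply substitutions to the wild-type sequence; length is preserved."""
    if not v.mutations:
        return wild_type
    seq = list(wild_type)
    for m in v.mutations:
        if m.position > len(seq):
            raise VariantError(
                f"position {m.position} beyond sequence length {len(seq)}"
            )
        seq[m.position - 1] = m.mut_aa
    return "".join(seq)


@dataclass(frozen=True)
class CandidateSet:
    """The wild-type sequence plus the n candidate single mutations to combine."""

    wild_type: str
    candidates: tuple[Mutation, ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise VariantError("candidate set must contain at least one mutation")
        object.__setattr__(
            self,
            "candidates",
            tuple(sorted(self.candidates, key=lambda m: m.position)),
        )
        positions = [m.position for m in self.candidates]
        if len(set(positions)) != len(positions):
            raise VariantError("candidate mutations must be at distinct positions")
        for m in self.candidates:
            validate_variant(Variant([m]), self.wild_type)

    @property
    def n(self) -> int:
        return len(self.candidates)

    def space_size(self, orders: Sequence[int] | None = None) -> int:
        """Number of variants the combinatorial space contains (2^n for all orders)."""
        if orders is None:
            return 2**self.n
        return sum(comb(self.n, k) for k in orders if 0 <= k <= self.n)


def enumerate_combinations(
    cs: CandidateSet,
    orders: Sequence[int] | None = None,
    cap: int = 24,
) -> Iterator[Variant]:
    """Lazily yield every subset of the candidate mutations exactly once.

    Deterministic order: by mutation count, then lexicographically by the
    position tuple (candidates are position-sorted).  Includes the wild type
    (order 0) unless ``orders`` excludes it.  ``cap`` bounds n so that 2^n
    enumeration stays tractable.
    """
    if cs.n > cap:
        raise VariantError(f"candidate count {cs.n} exceeds enumeration cap {cap}")
    ks = range(cs.n + 1) if orders is None else sorted(set(orders))
    from_sorted = Variant._from_sorted
    for k in ks:
        if k < 0 or k > cs.n:
            continue
        if k == 0:
            yield WILD_TYPE
            continue
        for combo in itertools.combinations(cs.candidates, k):
            yield from_sorted(combo)


def read_fasta(path) -> str:
    """Read the wild-type sequence from a FASTA file (first record; warn on more)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise VariantError(f"no FASTA records in {path}")
    if len(records) > 1:
        warnings.warn(
            f"{path} contains {len(records)} records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    return str(records[0].seq).upper()
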