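"""Circular binary genomes and the seven mutation operators.

A genome is a circular, double-stranded sequence over {0,1}; the stored bits
are the leading strand, the lagging strand is its reverse complement.  Seven
mutation types act on it: substitutions, small insertions/deletions (InDels,
size uniform on [1,6]), and four chromosomal rearrangements (duplications,
large deletions, translocations, inversions) whose segment size is uniform on
[1,L].

Coordinate convention (documented and tested): coordinates are 0-based, and a
span ``(p1, p2)`` denotes the circular run of ``((p2 - p1) mod L) + 1``
positions starting at ``p1`` — i.e. positions ``p1 .. p2`` inclusive, wrapping
through the origin when ``p2 < p1``.  Insertions happen *before* the given
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Genome",
    "MutationType",
    "MutationRates",
    "MutationEvent",
    "GenomeExtinctionError",
    "sample_mutation_counts",
    "apply_substitution",
    "apply_small_indel",
    "apply_duplication",
    "apply_large_deletion",
    "apply_translocation",
    "apply_inversion",
    "apply_event",
    "apply_events",
    "draw_event",
    "replicate",
    "replicate_bits",
]


class GenomeExtinctionError(ValueError):
    """A deletion would remove every base of the genome."""


class MutationType(IntEnum):
    SUBSTITUTION = 0
    SMALL_INSERTION = 1
    SMALL_DELETION = 2
    DUPLICATION = 3
    LARGE_DELETION = 4
    TRANSLOCATION = 5
    INVERSION = 6


#: Rearrangements are applied before local events within one replication.
REARRANGEMENTS = (
    MutationType.DUPLICATION,
    MutationType.LARGE_DELETION,
    MutationType.TRANSLOCATION,
    MutationType.INVERSION,
)
LOCAL_EVENTS = (
    MutationType.SUBSTITUTION,
    MutationType.SMALL_INSERTION,
    MutationType.SMALL_DELETION,
)

INDEL_MAX = 6


def _as_bits(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        bits = seq.astype(np.uint8, copy=False)
    elif isinstance(seq, str):
        bits = np.frombuffer(seq.encode(), dtype=np.uint8) - ord("0")
    else:
        bits = np.asarray(list(seq), dtype=np.uint8)
    if bits.ndim != 1 or bits.size < 1:
        raise ValueError("genome must be a non-empty 1-D bit sequence")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("genome symbols must be 0 or 1")
    return bits


@dataclass(frozen=True)
class Genome:
    """Circular double-stranded binary genome (bits = leading strand)."""

    bits: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bits", _as_bits(self.bits))

    @classmethod
    def from_string(cls, s: str) -> "Genome":
        return cls(bits=s)

    @classmethod
    def random(cls, length: int, rng: np.random.Generator) -> "Genome":
        if length < 1:
            raise ValueError("genome length must be >= 1")
        return cls(bits=rng.integers(0, 2, size=length, dtype=np.uint8))

    def __len__(self) -> int:
        return int(self.bits.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.bits.shape == other.bits.shape and bool(
            (self.bits == other.bits).all()
        )

    def __hash__(self):
        return hash(self.bits.tobytes())

    def to_string(self) -> str:
        return "".join("01"[b] for b in self.bits)

    def reverse_complement(self) -> "Genome":
        return Genome(bits=(1 - self.bits[::-1]).astype(np.uint8))

    def rotated(self, shift: int) -> "Genome":
        """Genome re-linearized at another origin of the circle."""
        return Genome(bits=np.roll(self.bits, shift))


@dataclass(frozen=True)
class MutationRates:
    """Per-type per-base-pair mutation rates (events / bp / generation)."""

    substitution: float = 0.0
    small_insertion: float = 0.0
    small_deletion: float = 0.0
    duplication: float = 0.0
    large_deletion: float = 0.0
    translocation: float = 0.0
    inversion: float = 0.0

    _FIELDS = (
        "substitution",
        "small_insertion",
        "small_deletion",
        "duplication",
        "large_deletion",
        "translocation",
        "inversion",
    )

    def __post_init__(self):
        for name in self._FIELDS:
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {name}={r} outside [0, 1]")

    @classmethod
    def uniform(cls, mu: float) -> "MutationRates":
        """All 7 rates equal to ``mu`` (the no-bias configuration)."""
        return cls(**{name: mu for name in cls._FIELDS})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self._FIELDS], dtype=float)

    def rate_of(self, mtype: MutationType) -> float:
        return getattr(self, self._FIELDS[mtype])

    def with_rate(self, mtype: MutationType, rate: float) -> "MutationRates":
        return _dc_replace(self, **{self._FIELDS[mtype]: rate})

    def scaled(self, factor: float) -> "MutationRates":
        return MutationRates(
            **{n: getattr(self, n) * factor for n in self._FIELDS}
        )

    def total(self) -> float:
        return float(self.as_array().sum())

    def p_no_event(self, length: int) -> float:
        """Probability that a replication of an ``length``-bp genome draws no
        event at all: prod over types of (1 - rate)^L."""
        return float(np.prod((1.0 - self.as_array()) ** length))


@dataclass
class MutationEvent:
    """One applied (or discarded) mutation, sufficient for exact replay."""

    mtype: MutationType
    p1: int = -1
    p2: int = -1
    p3: int = -1
    size: int = 0
    payload: np.ndarray | None = None
    inverted: bool = False
    discarded: bool = False


def span_length(L: int, p1: int, p2: int) -> int:
    """Length of the circular span p1..p2 inclusive: ((p2 - p1) mod L) + 1."""
    return ((p2 - p1) % L) + 1


def _span_indices(L: int, p1: int, s: int) -> np.ndarray:
    return (p1 + np.arange(s)) % L


def _check_pos(L: int, *positions: int) -> None:
    for p in positions:
        if not 0 <= p < L:
            raise IndexError(f"position {p} outside genome of length {L}")


def sample_mutation_counts(
    length: int, rates: MutationRates, rng: np.random.Generator
) -> np.ndarray:
    """Draw the per-type event counts for one replication: Binomial(L, rate),
    independently across the 7 types."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    return rng.binomial(length, rates.as_array())


# ---------------------------------------------------------------------------
# operators on raw bit arrays (hot path) and Genome wrappers
# ---------------------------------------------------------------------------


def _substitution(bits: np.ndarray, pos: int) -> np.ndarray:
    out = bits.copy()
    out[pos] ^= 1
    return out


def _insertion(bits: np.ndarray, pos: int, payload: np.ndarray) -> np.ndarray:
    return np.insert(bits, pos, payload)


def _deletion(bits: np.ndarray, p1: int, s: int) -> np.ndarray:
    L = bits.size
    if s >= L:
        raise GenomeExtinctionError(
            f"deletion of {s} bp would empty a {L}-bp genome"
        )
    keep = np.ones(L, dtype=bool)
    keep[_span_indices(L, p1, s)] = False
    return bits[keep]


def _duplication(bits: np.ndarray, p1: int, p2: int, p3: int) -> np.ndarray:
    L = bits.size
    s = span_length(L, p1, p2)
    seg = bits[_span_indices(L, p1, s)]
    return np.insert(bits, p3, seg)


def _inversion(bits: np.ndarray, p1: int, p2: int) -> np.ndarray:
    L = bits.size
    s = span_length(L, p1, p2)
    idx = _span_indices(L, p1, s)
    out = bits.copy()
    out[idx] = 1 - out[idx][::-1]
    return out


def _translocation(
    bits: np.ndarray, p1: int, p2: int, p3: int, inverted: bool
) -> np.ndarray:
    L = bits.size
    s = span_length(L, p1, p2)
    if s > L - 1:
        raise ValueError("cannot translocate the whole genome")
    seg = bits[_span_indices(L, p1, s)]
    rest = _deletion(bits, p1, s)
    if not 0 <= p3 <= rest.size:
        raise IndexError(
            f"reinsertion point {p3} outside re-closed circle of {rest.size} bp"
        )
    if inverted:
        seg = (1 - seg[::-1]).astype(np.uint8)
    return np.insert(rest, p3, seg)


def apply_substitution(g: Genome, pos: int) -> Genome:
    """Flip the bit at ``pos``; length unchanged."""
    _check_pos(len(g), pos)
    return Genome(bits=_substitution(g.bits, pos))


def apply_small_indel(
    g: Genome,
    pos: int,
    kind: str,
    size: int,
    payload: Sequence[int] | np.ndarray | str | None = None,
) -> Genome:
    """Insert or delete ``size`` in [1,6] bases at ``pos``.

    A deletion of size >= L is a :class:`GenomeExtinctionError`.
    """
    L = len(g)
    _check_pos(L, pos)
    if not 1 <= size <= INDEL_MAX:
        raise ValueError(f"InDel size {size} outside [1, {INDEL_MAX}]")
    if kind == "insertion":
        pl = _as_bits(payload)
        if pl.size != size:
            raise ValueError("payload length must equal the insertion size")
        return Genome(bits=_insertion(g.bits, pos, pl))
    if kind == "deletion":
        return Genome(bits=_deletion(g.bits, pos, size))
    raise ValueError(f"unknown InDel kind {kind!r}")


def apply_duplication(g: Genome, p1: int, p2: int, p3: int) -> Genome:
    """Copy the span p1..p2 and insert the copy before ``p3``; the template
    segment is untouched; length grows by the span size."""
    L = len(g)
    _check_pos(L, p1, p2, p3)
    return Genome(bits=_duplication(g.bits, p1, p2, p3))


def apply_large_deletion(g: Genome, p1: int, p2: int) -> Genome:
    """Remove the circular span p1..p2 (GenomeExtinctionError if it covers
    the whole genome)."""
    L = len(g)
    _check_pos(L, p1, p2)
    return Genome(bits=_deletion(g.bits, p1, span_length(L, p1, p2)))


def apply_translocation(
    g: Genome, p1: int, p2: int, p3: int, inverted: bool = False
) -> Genome:
    """Excise the span p1..p2, re-close the circle, and reinsert the segment
    (reverse-complemented if ``inverted``) before position ``p3`` of the
    re-closed sequence.  Length is unchanged."""
    L = len(g)
    _check_pos(L, p1, p2)
    return Genome(bits=_translocation(g.bits, p1, p2, p3, inverted))


def apply_inversion(g: Genome, p1: int, p2: int) -> Genome:
    """Replace the span p1..p2 by its reverse complement in place."""
    L = len(g)
    _check_pos(L, p1, p2)
    return Genome(bits=_inversion(g.bits, p1, p2))


# ---------------------------------------------------------------------------
# stochastic replication
# ---------------------------------------------------------------------------


def draw_event(
    bits: np.ndarray, mtype: MutationType, rng: np.random.Generator
) -> MutationEvent:
    """Draw the parameters of one event of ``mtype`` uniformly on the current
    genome.  Events that would empty the genome are marked ``discarded``."""
    L = bits.size
    if mtype == MutationType.SUBSTITUTION:
        return MutationEvent(mtype, p1=int(rng.integers(L)), size=1)
    if mtype == MutationType.SMALL_INSERTION:
        size = int(rng.integers(1, INDEL_MAX + 1))
        payload = rng.integers(0, 2, size=size, dtype=np.uint8)
        return MutationEvent(
            mtype, p1=int(rng.integers(L)), size=size, payload=payload
        )
    if mtype == MutationType.SMALL_DELETION:
        pos = int(rng.integers(L))
        size = int(rng.integers(1, INDEL_MAX + 1))
        return MutationEvent(mtype, p1=pos, size=size, discarded=size >= L)
    if mtype == MutationType.DUPLICATION:
        p1, p2, p3 = (int(x) for x in rng.integers(L, size=3))
        return MutationEvent(mtype, p1=p1, p2=p2, p3=p3, size=span_length(L, p1, p2))
    if mtype == MutationType.LARGE_DELETION:
        p1, p2 = (int(x) for x in rng.integers(L, size=2))
        s = span_length(L, p1, p2)
        return MutationEvent(mtype, p1=p1, p2=p2, size=s, discarded=s >= L)
    if mtype == MutationType.TRANSLOCATION:
        p1, p2 = (int(x) for x in rng.integers(L, size=2))
        s = span_length(L, p1, p2)
        if s > L - 1:
            return MutationEvent(mtype, p1=p1, p2=p2, size=s, discarded=True)
        p3 = int(rng.integers(L - s + 1))
        inverted = bool(rng.integers(2))
        return MutationEvent(mtype, p1=p1, p2=p2, p3=p3, size=s, inverted=inverted)
    if mtype == MutationType.INVERSION:
        p1, p2 = (int(x) for x in rng.integers(L, size=2))
        return MutationEvent(mtype, p1=p1, p2=p2, size=span_length(L, p1, p2))
    raise ValueError(f"unknown mutation type {mtype}")


def apply_event(bits: np.ndarray, ev: MutationEvent) -> np.ndarray:
    """Apply one logged event to a bit array (discarded events are no-ops)."""
    if ev.discarded:
        return bits
    t = ev.mtype
    if t == MutationType.SUBSTITUTION:
        return _substitution(bits, ev.p1)
    if t == MutationType.SMALL_INSERTION:
        return _insertion(bits, ev.p1, ev.payload)
    if t == MutationType.SMALL_DELETION:
        return _deletion(bits, ev.p1, ev.size)
    if t == MutationType.DUPLICATION:
        return _duplication(bits, ev.p1, ev.p2, ev.p3)
    if t == MutationType.LARGE_DELETION:
        return _deletion(bits, ev.p1, ev.size)
    if t == MutationType.TRANSLOCATION:
        return _translocation(bits, ev.p1, ev.p2, ev.p3, ev.inverted)
    if t == MutationType.INVERSION:
        return _inversion(bits, ev.p1, ev.p2)
    raise ValueError(f"unknown mutation type {t}")


def apply_events(bits: np.ndarray, events: Iterable[MutationEvent]) -> np.ndarray:
    """Replay a logged event sequence (deterministic, bit-exact)."""
    for ev in events:
        bits = apply_event(bits, ev)
    return bits


def _event_order(
    counts: np.ndarray, rng: np.random.Generator
) -> list[MutationType]:
    """Canonical within-replication order: the sampled rearrangements in
    shuffled order, then the sampled local events in shuffled order."""
    order: list[MutationType] = []
    for group in (REARRANGEMENTS, LOCAL_EVENTS):
        block = [t for t in group for _ in range(int(counts[t]))]
        if len(block) > 1:
            block = [block[i] for i in rng.permutation(len(block))]
        order.extend(block)
    return order


def mutate_bits(
    bits: np.ndarray, counts: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[MutationEvent]]:
    """Apply ``counts[t]`` events of each type to ``bits``; each event's
    parameters are drawn uniformly on the genome length current at the moment
    of application.  Returns the child bits and the replayable event log."""
    events: list[MutationEvent] = []
    for mtype in _event_order(counts, rng):
        ev = draw_event(bits, mtype, rng)
        bits = apply_event(bits, ev)
        events.append(ev)
    return bits, events


def replicate_bits(
    bits: np.ndarray, rates: MutationRates, rng: np.random.Generator
) -> tuple[np.ndarray, list[MutationEvent]]:
    counts = sample_mutation_counts(bits.size, rates, rng)
    if counts.sum() == 0:
        return bits, []
    return mutate_bits(bits, counts, rng)


def replicate(
    g: Genome, rates: MutationRates, rng: np.random.Generator
) -> tuple[Genome, list[MutationEvent]]:
    """One replication: sample per-type counts, apply rearrangements then
    local events, and return the child with its replayable event log."""
    bits, events = replicate_bits(g.bits, rates, rng)
    return Genome(bits=bits), events
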