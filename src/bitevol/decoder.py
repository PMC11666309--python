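"""Genotype-to-phenotype-to-fitness map.

Decoding is a pure, deterministic function of the genome:

1. *Transcription* — 22-bp windows on both strands within ``PROMOTER_MAX_MISMATCH``
   Hamming mismatches of the consensus act as promoters; each transcribes up to
   the first downstream stem-loop terminator on its strand.
2. *Translation* — within a transcript, every RBS + 4-bp spacer + START motif
   opens a reading frame, read 3 bits at a time until a STOP codon.
3. *Protein functions* — the codons of a gene encode, through a Gray code, a
   triangle kernel on [0,1]: position ``m``, half-width ``w`` (≤ W_MAX) and
   height ``h`` in [-1,1], expressed at the promoter's level ``e``.
4. *Phenotype and fitness* — the proteins' kernels are summed on a uniform
   grid, clipped to [0,1], and compared with the environmental target; the
   metabolic error ``g`` is the trapezoidal integral of the absolute gap and
   fitness is ``exp(-k·g)``.

Proteins are summed in a canonical, rotation-invariant order (sorted by
``(m, w, h, e)``) so that equal genomes — and rotations or reverse
complements of a genome — yield bit-identical metabolic errors, which makes
the exact-neutrality comparison used by the robustness analyses meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from . import _kernels
from .chemistry import (
    DEFAULT_GRID,
    EnvironmentTarget,
    FitnessParams,
    GENE_HEAD_LEN,
    PROMOTER_LEN,
    PROMOTER_MAX_MISMATCH,
    TERMINATOR_LEN,
    build_target,
    consensus_array,
    W_MAX,
)
from .genome import Genome

__all__ = [
    "Promoter",
    "Rna",
    "Protein",
    "DecodedGenome",
    "GridMismatchError",
    "decode",
    "evaluate_bits",
    "find_promoters",
    "find_terminator",
    "transcribe",
    "translate",
    "compute_phenotype",
    "metabolic_error",
    "fitness",
    "annotate_coding",
    "cds_intervals",
]

LEADING, LAGGING = 0, 1
_STRAND_NAMES = ("leading", "lagging")


class GridMismatchError(ValueError):
    """Phenotype and target were sampled on different grids."""


@dataclass(frozen=True)
class Promoter:
    """A consensus-like window.  ``position`` is strand-local: on the lagging
    strand, position ``s`` corresponds to stored position ``L - 1 - s``."""

    position: int
    strand: int
    mismatches: int
    expression: float

    @property
    def strand_name(self) -> str:
        return _STRAND_NAMES[self.strand]


@dataclass(frozen=True)
class Rna:
    promoter: Promoter
    start: int          # strand-local first transcribed position
    length: int         # through the end of the terminator
    terminator: int     # strand-local position of the stem-loop start
    strand: int

    @property
    def expression(self) -> float:
        return self.promoter.expression


@dataclass(frozen=True)
class Protein:
    m: float
    w: float
    h: float
    e: float
    strand: int
    cds_start: int      # strand-local position of the START codon
    cds_length: int     # START through STOP inclusive, bp

    @property
    def mwhe(self) -> tuple[float, float, float, float]:
        return (self.m, self.w, self.h, self.e)


@dataclass(frozen=True)
class DecodedGenome:
    """Full decoding result of one genome against one environment."""

    length: int
    promoters: tuple[Promoter, ...]
    rnas: tuple[Rna, ...]
    proteins: tuple[Protein, ...]
    phenotype: np.ndarray
    metabolic_error: float
    fitness: float
    coding_mask: np.ndarray
    coding_size: int

    @property
    def noncoding_size(self) -> int:
        return self.length - self.coding_size

    @property
    def coding_fraction(self) -> float:
        return self.coding_size / self.length


def _decode_raw(bits: np.ndarray):
    return _kernels.decode_strands(
        bits, consensus_array(), PROMOTER_MAX_MISMATCH, W_MAX
    )


def _canonical_order(prot_f: np.ndarray) -> np.ndarray:
    if prot_f.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    return np.lexsort((prot_f[:, 3], prot_f[:, 2], prot_f[:, 1], prot_f[:, 0]))


def evaluate_bits(
    bits: np.ndarray, target_values: np.ndarray, k: float
) -> tuple[float, float, int]:
    """Fast path: (metabolic error, fitness, coding size) of a bit array."""
    _, _, prot_f, prot_i = _decode_raw(bits)
    order = _canonical_order(prot_f)
    _, g = _kernels.phenotype_and_error(prot_f, order, target_values)
    coding = int(_kernels.coding_mask(prot_i, bits.size).sum())
    return float(g), float(np.exp(-k * g)), coding


def decode(
    g: Genome,
    target: EnvironmentTarget | None = None,
    params: FitnessParams | None = None,
    coding: Literal["cds", "essential"] = "cds",
) -> DecodedGenome:
    """Decode a genome into promoters, RNAs, proteins, phenotype and fitness."""
    target = target if target is not None else build_target()
    params = params if params is not None else FitnessParams()
    bits = g.bits
    L = bits.size
    prom_a, rna_a, prot_f, prot_i = _decode_raw(bits)

    prom_order = np.lexsort((prom_a[:, 0], prom_a[:, 1])) if prom_a.size else []
    promoters = tuple(
        Promoter(
            position=int(prom_a[i, 1]),
            strand=int(prom_a[i, 0]),
            mismatches=int(prom_a[i, 2]),
            expression=1.0 - prom_a[i, 2] / (PROMOTER_MAX_MISMATCH + 1.0),
        )
        for i in prom_order
    )
    by_row = {int(prom_a[i, 1]) * 2 + int(prom_a[i, 0]): p for i, p in
              zip(prom_order, promoters)}

    def _prom_of(row: int) -> Promoter:
        return by_row[int(prom_a[row, 1]) * 2 + int(prom_a[row, 0])]

    rnas = tuple(
        Rna(
            promoter=_prom_of(int(rna_a[i, 3])),
            start=int(rna_a[i, 1]),
            length=int(rna_a[i, 2]),
            terminator=int(rna_a[i, 4]),
            strand=int(rna_a[i, 0]),
        )
        for i in range(rna_a.shape[0])
    )
    proteins = tuple(
        Protein(
            m=float(prot_f[i, 0]),
            w=float(prot_f[i, 1]),
            h=float(prot_f[i, 2]),
            e=float(prot_f[i, 3]),
            strand=int(prot_i[i, 0]),
            cds_start=int(prot_i[i, 1]),
            cds_length=int(prot_i[i, 2]),
        )
        for i in range(prot_i.shape[0])
    )

    order = _canonical_order(prot_f)
    phen, g_err = _kernels.phenotype_and_error(prot_f, order, target.values)
    mask = _kernels.coding_mask(prot_i, L).astype(bool)
    if coding == "essential":
        mask = mask | _essential_mask(L, rna_a, prot_i)
    elif coding != "cds":
        raise ValueError(f"unknown coding definition {coding!r}")
    return DecodedGenome(
        length=L,
        promoters=promoters,
        rnas=rnas,
        proteins=proteins,
        phenotype=phen,
        metabolic_error=float(g_err),
        fitness=float(np.exp(-params.k * g_err)),
        coding_mask=mask,
        coding_size=int(mask.sum()),
    )


def _strand_positions(L: int, strand: int, start: int, length: int) -> np.ndarray:
    s = (start + np.arange(length)) % L
    return s if strand == 0 else L - 1 - s


def _essential_mask(L: int, rna_a: np.ndarray, prot_i: np.ndarray) -> np.ndarray:
    """Positions of promoters, RBS+spacer and terminators of *expressed* genes."""
    mask = np.zeros(L, dtype=bool)
    for i in range(prot_i.shape[0]):
        strand = int(prot_i[i, 0])
        rna_row = int(prot_i[i, 3])
        rna_start = int(rna_a[rna_row, 1])
        term = int(rna_a[rna_row, 4])
        prom_start = (rna_start - PROMOTER_LEN) % L
        mask[_strand_positions(L, strand, prom_start, PROMOTER_LEN)] = True
        mask[_strand_positions(L, strand, term, TERMINATOR_LEN)] = True
        head_start = (int(prot_i[i, 1]) - (GENE_HEAD_LEN - 3)) % L
        mask[_strand_positions(L, strand, head_start, GENE_HEAD_LEN - 3)] = True
    return mask


# ---------------------------------------------------------------------------
# per-stage views (thin wrappers over the same kernel pass)
# ---------------------------------------------------------------------------


def find_promoters(g: Genome) -> tuple[Promoter, ...]:
    """All promoter windows on both strands, ordered by (position, strand)."""
    return decode_structure(g).promoters


def transcribe(g: Genome) -> tuple[Rna, ...]:
    """One RNA per promoter that reaches a terminator on its strand."""
    return decode_structure(g).rnas


def translate(r: Rna, g: Genome) -> tuple[Protein, ...]:
    """Proteins translated from one RNA."""
    _, rna_a, prot_f, prot_i = _decode_raw(g.bits)
    row = -1
    for i in range(rna_a.shape[0]):
        if (
            int(rna_a[i, 0]) == r.strand
            and int(rna_a[i, 1]) == r.start
            and int(rna_a[i, 2]) == r.length
        ):
            row = i
            break
    if row < 0:
        raise ValueError("RNA does not belong to this genome")
    return tuple(
        Protein(
            m=float(prot_f[i, 0]),
            w=float(prot_f[i, 1]),
            h=float(prot_f[i, 2]),
            e=float(prot_f[i, 3]),
            strand=int(prot_i[i, 0]),
            cds_start=int(prot_i[i, 1]),
            cds_length=int(prot_i[i, 2]),
        )
        for i in range(prot_i.shape[0])
        if int(prot_i[i, 3]) == row and int(prot_i[i, 0]) == r.strand
    )


_STRUCTURE_TARGET = build_target(grid=2)  # decoding structure needs no target


def decode_structure(g: Genome) -> DecodedGenome:
    """Decode promoters/RNAs/proteins only (tiny throwaway phenotype grid)."""
    return decode(g, target=_STRUCTURE_TARGET)


def find_terminator(g: Genome, start: int, strand: int) -> int | None:
    """First strand-local position >= ``start`` (circular scan, <= L steps)
    where the stem-loop predicate holds; ``None`` if the strand has none."""
    bits = g.bits if strand == 0 else (1 - g.bits[::-1]).astype(np.uint8)
    L = bits.size
    ext = np.concatenate([bits, bits[: TERMINATOR_LEN]])
    for k in range(L):
        i = (start + k) % L
        if all(ext[i + j] == 1 - ext[i + 10 - j] for j in range(4)):
            return i
    return None


# ---------------------------------------------------------------------------
# phenotype / fitness
# ---------------------------------------------------------------------------


def compute_phenotype(
    proteins: Sequence[Protein] | Sequence[tuple[float, float, float, float]],
    grid: int = DEFAULT_GRID,
) -> np.ndarray:
    """Sum the proteins' triangle kernels on the uniform grid, clipped to [0,1]."""
    rows = [
        p.mwhe if isinstance(p, Protein) else tuple(p) for p in proteins
    ]
    prot_f = np.array(rows, dtype=float).reshape(-1, 4)
    order = _canonical_order(prot_f)
    zero = np.zeros(grid)
    phen, _ = _kernels.phenotype_and_error(prot_f, order, zero)
    return phen


def metabolic_error(phenotype: np.ndarray, target: EnvironmentTarget | np.ndarray) -> float:
    """Trapezoidal integral of |phenotype - target| over [0,1]."""
    tvals = target.values if isinstance(target, EnvironmentTarget) else np.asarray(target)
    if phenotype.shape != tvals.shape:
        raise GridMismatchError(
            f"phenotype grid {phenotype.shape} != target grid {tvals.shape}"
        )
    x = np.linspace(0.0, 1.0, tvals.shape[0])
    return float(np.trapezoid(np.abs(phenotype - tvals), x))


def fitness(g_err: float, params: FitnessParams | None = None) -> float:
    """exp(-k·g): 1 at a perfect phenotype match, strictly decreasing in g."""
    if g_err < 0:
        raise ValueError("metabolic error must be >= 0")
    params = params if params is not None else FitnessParams()
    return float(np.exp(-params.k * g_err))


def annotate_coding(
    g: Genome, coding: Literal["cds", "essential"] = "cds"
) -> tuple[np.ndarray, int, int, float]:
    """(per-position coding mask, coding bp, noncoding bp, coding fraction).

    A position is coding iff it lies in at least one translated CDS (START
    through STOP inclusive) of an expressed protein; ``coding='essential'``
    additionally counts promoter, RBS+spacer and terminator positions.
    """
    dec = decode(g, target=_STRUCTURE_TARGET, coding=coding)
    return (
        dec.coding_mask,
        dec.coding_size,
        dec.noncoding_size,
        dec.coding_fraction,
    )


def cds_intervals(g: Genome) -> list[tuple[int, int, str]]:
    """BED-like 0-based half-open CDS intervals with strand symbol.

    Wrapping CDSs are split at the origin into two intervals.
    """
    L = len(g)
    out: list[tuple[int, int, str]] = []
    for p in decode_structure(g).proteins:
        pos = np.sort(_strand_positions(L, p.strand, p.cds_start, p.cds_length))
        sym = "+" if p.strand == 0 else "-"
        run_start = int(pos[0])
        prev = int(pos[0])
        for v in pos[1:]:
            v = int(v)
            if v != prev + 1:
                out.append((run_start, prev + 1, sym))
                run_start = v
            prev = v
        out.append((run_start, prev + 1, sym))
    return sorted(out)
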