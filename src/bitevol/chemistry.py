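"""Constants of the artificial chemistry.

The genotype-to-phenotype map rests on a small set of fixed sequence motifs
and numeric conventions (promoter consensus, terminator stem-loop geometry,
ribosome-binding motif, codon table, phenotype grid).  They are pinned here in
one place so that planted-genome fixtures and the decoder always agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: 22-bp promoter consensus scanned on both strands.
PROMOTER_CONSENSUS = "0101011001110010010110"
#: Maximum Hamming mismatch for a window to still act as a promoter.
PROMOTER_MAX_MISMATCH = 4
#: Length of the promoter window, bp.
PROMOTER_LEN = len(PROMOTER_CONSENSUS)

#: Terminator: positions i..i+3 must equal the reverse complement of
#: i+7..i+10 (4-bp stem, 3-bp loop, 11 bp total).
TERMINATOR_STEM = 4
TERMINATOR_LOOP = 3
TERMINATOR_LEN = 2 * TERMINATOR_STEM + TERMINATOR_LOOP  # 11

#: Shine-Dalgarno-like ribosome binding motif, followed by a free 4-bp spacer
#: and the START codon.
RBS_MOTIF = "011011"
RBS_SPACER = 4
CODON_LEN = 3
GENE_HEAD_LEN = len(RBS_MOTIF) + RBS_SPACER + CODON_LEN  # 13

#: Codon values (3 bits read MSB first).
START_CODON = 0b000
STOP_CODON = 0b001
CODON_W0, CODON_W1 = 0b010, 0b011
CODON_M0, CODON_M1 = 0b100, 0b101
CODON_H0, CODON_H1 = 0b110, 0b111

#: Maximum half-width of a protein's triangle kernel on the [0,1] axis.
W_MAX = 0.033

#: Number of uniform samples of the phenotype/target on [0,1].
DEFAULT_GRID = 1024

#: Default selection strength (fitness = exp(-k * metabolic error)).
DEFAULT_K = 1000.0

#: Default environmental target: sum of 3 Gaussians (center, height, sd),
#: clipped to [0,1].
DEFAULT_TARGET_GAUSSIANS = (
    (0.25, 0.6, 0.05),
    (0.53, 0.8, 0.04),
    (0.80, 0.5, 0.03),
)

_CONSENSUS_ARRAY = np.frombuffer(PROMOTER_CONSENSUS.encode(), dtype=np.uint8) - ord("0")
_CONSENSUS_ARRAY.setflags(write=False)


def consensus_array() -> np.ndarray:
    """Promoter consensus as a read-only uint8 array of 0/1."""
    return _CONSENSUS_ARRAY


def promoter_expression(mismatches: int, d_max: int = PROMOTER_MAX_MISMATCH) -> float:
    """Expression level of a promoter with ``mismatches`` errors: 1 - d/(d_max+1)."""
    if not 0 <= mismatches <= d_max:
        raise ValueError(f"mismatch count {mismatches} outside [0, {d_max}]")
    return 1.0 - mismatches / (d_max + 1.0)


@dataclass(frozen=True)
class EnvironmentTarget:
    """Target phenotype sampled on the same uniform grid as phenotypes."""

    values: np.ndarray
    gaussians: tuple = DEFAULT_TARGET_GAUSSIANS

    @property
    def grid_size(self) -> int:
        return self.values.shape[0]


def build_target(
    grid: int = DEFAULT_GRID,
    gaussians: tuple = DEFAULT_TARGET_GAUSSIANS,
) -> EnvironmentTarget:
    """Sample the environmental target function on ``grid`` uniform points of [0,1]."""
    x = np.linspace(0.0, 1.0, grid)
    y = np.zeros(grid)
    for center, height, sd in gaussians:
        y += height * np.exp(-0.5 * ((x - center) / sd) ** 2)
    np.clip(y, 0.0, 1.0, out=y)
    y.setflags(write=False)
    return EnvironmentTarget(values=y, gaussians=tuple(gaussians))


@dataclass(frozen=True)
class FitnessParams:
    """Selection strength of the exponential fitness function."""

    k: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("selection strength k must be > 0")
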