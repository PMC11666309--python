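"""Spatial Wright-Fisher population dynamics.

Individuals live on a toroidal W×H grid.  Every generation, each cell draws a
parent among its 9 toroidal neighbours (self included) with probability
proportional to raw fitness, and is refilled with a mutated replicate of that
parent.  Only mutated offspring are re-decoded; an unmutated child inherits
its parent's genome object and metrics, which keeps large low-mutation-rate
populations cheap.

Randomness is counter-based: each generation ``t`` of a run seeded with ``s``
consumes a fresh Philox stream keyed by ``(s, t)``, so a run can be restarted
from any checkpoint bit-exactly, and every replication is replayable from its
logged events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .chemistry import EnvironmentTarget, FitnessParams, build_target
from .decoder import evaluate_bits
from .genome import (
    Genome,
    MutationEvent,
    MutationRates,
    apply_events,
    mutate_bits,
)

__all__ = [
    "PopulationGrid",
    "LineageRecord",
    "LineagePath",
    "Simulation",
    "select_parent",
    "step_generation",
    "reconstruct_line_of_descent",
    "coalescence_truncation",
    "analysis_horizon",
    "NotCoalescedWarning",
]

#: 3x3 neighbourhood offsets, row-major; the centre (self) is included.
NEIGHBOR_OFFSETS = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
)


class NotCoalescedWarning(UserWarning):
    """The final population had not coalesced by the analysis horizon."""


class LineageIntegrityError(KeyError):
    """A generation needed for lineage reconstruction is missing."""


@dataclass
class PopulationGrid:
    """Toroidal grid of individuals with cached per-cell metrics."""

    width: int
    height: int
    genomes: list[np.ndarray]
    metabolic_error: np.ndarray
    fitness: np.ndarray
    coding: np.ndarray
    generation: int = 0

    @property
    def size(self) -> int:
        return self.width * self.height

    @property
    def lengths(self) -> np.ndarray:
        return np.array([g.size for g in self.genomes], dtype=np.int64)

    @classmethod
    def clonal(
        cls,
        width: int,
        height: int,
        founder: Genome | np.ndarray,
        target: EnvironmentTarget,
        params: FitnessParams,
    ) -> "PopulationGrid":
        bits = founder.bits if isinstance(founder, Genome) else np.asarray(founder)
        g_err, fit, coding = evaluate_bits(bits, target.values, params.k)
        n = width * height
        return cls(
            width=width,
            height=height,
            genomes=[bits] * n,
            metabolic_error=np.full(n, g_err),
            fitness=np.full(n, fit),
            coding=np.full(n, coding, dtype=np.int64),
            generation=0,
        )

    def cell_index(self, cell: tuple[int, int]) -> int:
        y, x = cell
        return (y % self.height) * self.width + (x % self.width)


_NEIGHBOR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _neighbor_indices(width: int, height: int) -> np.ndarray:
    """(9, N) flat parent indices for each cell, in NEIGHBOR_OFFSETS order."""
    key = (width, height)
    if key not in _NEIGHBOR_CACHE:
        ys, xs = np.divmod(np.arange(height * width), width)
        out = np.empty((9, height * width), dtype=np.int64)
        for k, (dy, dx) in enumerate(NEIGHBOR_OFFSETS):
            out[k] = ((ys + dy) % height) * width + (xs + dx) % width
        _NEIGHBOR_CACHE[key] = out
    return _NEIGHBOR_CACHE[key]


def select_parent(
    grid: PopulationGrid,
    cell: tuple[int, int],
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw the parent cell of ``cell``: one of its 9 toroidal neighbours
    (self included), with probability proportional to fitness.

    On grids narrower than 3 cells a neighbour reachable through more than
    one offset appears multiple times in the weight vector, i.e. it counts
    once per path.  Returns (y, x) or an array of flat indices if ``size``
    is given.
    """
    idx = _neighbor_indices(grid.width, grid.height)[:, grid.cell_index(cell)]
    w = grid.fitness[idx].astype(float)
    tot = w.sum()
    if tot <= 0.0:  # guarded: fitness = exp(-k g) > 0 by construction
        w = np.ones(9)
        tot = 9.0
    p = w / tot
    draws = rng.choice(idx, size=size if size is not None else 1, p=p)
    if size is not None:
        return draws
    flat = int(draws[0])
    return divmod(flat, grid.width)


@dataclass
class LineageRecord:
    """Per-generation parent pointers + replication event logs.

    ``parents[t]`` maps each cell of generation ``start_generation + t + 1``
    to the flat index of its parent cell in the previous generation;
    ``events[t]`` holds the event log of every *mutated* replication.
    Together with the initial genomes this replays any line of descent
    bit-exactly.
    """

    width: int
    height: int
    initial_genomes: list[np.ndarray]
    start_generation: int = 0
    parents: list[np.ndarray] = field(default_factory=list)
    events: list[dict[int, list[MutationEvent]]] = field(default_factory=list)

    @property
    def last_generation(self) -> int:
        return self.start_generation + len(self.parents)

    def append(self, parents: np.ndarray, events: dict[int, list[MutationEvent]]):
        self.parents.append(parents)
        self.events.append(events)

    def save(self, directory) -> None:
        """Persist as parents.npz + events.tsv + founders.fa in ``directory``."""
        from pathlib import Path

        from . import io as bio

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            directory / "parents.npz",
            parents=np.stack(self.parents) if self.parents else np.empty((0, 0), np.int32),
            shape=np.array([self.width, self.height]),
            start_generation=np.array([self.start_generation]),
        )
        rows = []
        for t, per_gen in enumerate(self.events):
            gen = self.start_generation + t + 1
            for cell in sorted(per_gen):
                for ev in per_gen[cell]:
                    # cell is folded into the generation column as gen:cell
                    rows.append((f"{gen}:{cell}", ev))
        bio.write_event_log(directory / "events.tsv", rows)
        bio.write_genomes(
            directory / "founders.fa",
            [
                (f"cell_{i}", self.start_generation, float("nan"), bits)
                for i, bits in enumerate(self.initial_genomes)
            ],
        )

    @classmethod
    def load(cls, directory) -> "LineageRecord":
        from pathlib import Path

        from . import io as bio

        directory = Path(directory)
        with np.load(directory / "parents.npz") as npz:
            stacked = npz["parents"]
            width, height = (int(x) for x in npz["shape"])
            start = int(npz["start_generation"][0])
        founders = [g.bits for _, _, _, g in bio.read_genomes(directory / "founders.fa")]
        rec = cls(
            width=width,
            height=height,
            initial_genomes=founders,
            start_generation=start,
        )
        rec.parents = [stacked[i] for i in range(stacked.shape[0])]
        rec.events = [dict() for _ in rec.parents]
        for tag, ev in bio.read_event_log(directory / "events.tsv"):
            gen, cell = (int(x) for x in str(tag).split(":"))
            rec.events[gen - start - 1].setdefault(cell, []).append(ev)
        return rec


def step_generation(
    grid: PopulationGrid,
    rates: MutationRates,
    params: FitnessParams,
    target: EnvironmentTarget,
    rng: np.random.Generator,
) -> tuple[PopulationGrid, np.ndarray, dict[int, list[MutationEvent]]]:
    """Advance one generation; returns (next grid, parent table, event logs)."""
    H, W = grid.height, grid.width
    n = grid.size
    nidx = _neighbor_indices(W, H)
    weights = grid.fitness[nidx]  # (9, N)
    cum = np.cumsum(weights, axis=0)
    tot = cum[-1]
    bad = tot <= 0.0
    if bad.any():  # guarded degenerate case: uniform choice
        weights = np.where(bad[None, :], 1.0, weights)
        cum = np.cumsum(weights, axis=0)
        tot = cum[-1]
    u = rng.random(n) * tot
    k = (u[None, :] >= cum).sum(axis=0)
    parents = nidx[k, np.arange(n)]

    rate_arr = rates.as_array()
    lengths = np.array([grid.genomes[p].size for p in parents], dtype=np.int64)
    counts = rng.binomial(lengths[:, None], rate_arr[None, :])  # (N, 7)
    mutated = np.nonzero(counts.sum(axis=1) > 0)[0]

    genomes = [grid.genomes[p] for p in parents]
    g_err = grid.metabolic_error[parents].copy()
    fit = grid.fitness[parents].copy()
    coding = grid.coding[parents].copy()
    ev_log: dict[int, list[MutationEvent]] = {}
    for i in mutated:
        child, events = mutate_bits(genomes[i], counts[i], rng)
        if events:
            ev_log[int(i)] = events
        if child is not genomes[i]:
            genomes[i] = child
        g_err[i], fit[i], coding[i] = evaluate_bits(child, target.values, params.k)

    new = PopulationGrid(
        width=W,
        height=H,
        genomes=genomes,
        metabolic_error=g_err,
        fitness=fit,
        coding=coding,
        generation=grid.generation + 1,
    )
    return new, parents.astype(np.int32), ev_log


@dataclass
class Snapshot:
    """Restartable state: (generation, genomes).  The random stream needs no
    saving because it is re-derived from (seed, generation)."""

    generation: int
    genomes: list[np.ndarray]


class Simulation:
    """A seeded run of the spatial Wright-Fisher model.

    Parameters
    ----------
    founder : Genome or bit array used to fill the initial clonal grid.
    width, height : grid shape (W·H = N individuals).
    rates : per-type mutation rates.
    params : selection strength.
    target : environmental target (defaults to the standard 3-Gaussian mix).
    seed : base seed; generation ``t`` uses a Philox stream keyed ``(seed, t)``.
    record_lineage : keep parent tables + event logs for ancestor replay.
    """

    def __init__(
        self,
        founder: Genome | np.ndarray,
        width: int,
        height: int,
        rates: MutationRates,
        params: FitnessParams | None = None,
        target: EnvironmentTarget | None = None,
        seed: int = 0,
        record_lineage: bool = True,
    ):
        self.params = params if params is not None else FitnessParams()
        self.target = target if target is not None else build_target()
        self.rates = rates
        self.seed = int(seed)
        self.grid = PopulationGrid.clonal(
            width, height, founder, self.target, self.params
        )
        self.record: LineageRecord | None = (
            LineageRecord(
                width=width,
                height=height,
                initial_genomes=list(self.grid.genomes),
            )
            if record_lineage
            else None
        )

    def generation_rng(self, generation: int) -> np.random.Generator:
        key = np.array([self.seed, generation], dtype=np.uint64)
        return np.random.Generator(np.random.Philox(key=key))

    def step(self) -> None:
        rng = self.generation_rng(self.grid.generation)
        self.grid, parents, events = step_generation(
            self.grid, self.rates, self.params, self.target, rng
        )
        if self.record is not None:
            self.record.append(parents, events)

    def run(self, generations: int, callback=None) -> PopulationGrid:
        for _ in range(generations):
            self.step()
            if callback is not None:
                callback(self.grid)
        return self.grid

    def snapshot(self) -> Snapshot:
        return Snapshot(
            generation=self.grid.generation, genomes=list(self.grid.genomes)
        )

    def restore(self, snap: Snapshot) -> None:
        g = PopulationGrid.clonal(
            self.grid.width,
            self.grid.height,
            snap.genomes[0],
            self.target,
            self.params,
        )
        genomes = list(snap.genomes)
        err = np.empty(len(genomes))
        fit = np.empty(len(genomes))
        cod = np.empty(len(genomes), dtype=np.int64)
        cache: dict[bytes, tuple[float, float, int]] = {}
        for i, bits in enumerate(genomes):
            kkey = bits.tobytes()
            if kkey not in cache:
                cache[kkey] = evaluate_bits(bits, self.target.values, self.params.k)
            err[i], fit[i], cod[i] = cache[kkey]
        g.genomes = genomes
        g.metabolic_error = err
        g.fitness = fit
        g.coding = cod
        g.generation = snap.generation
        self.grid = g
        if self.record is not None and self.record.last_generation > snap.generation:
            keep = snap.generation - self.record.start_generation
            del self.record.parents[keep:]
            del self.record.events[keep:]

    def population_metrics(self) -> dict[str, float]:
        lengths = self.grid.lengths
        coding = self.grid.coding
        return {
            "generation": self.grid.generation,
            "mean_fitness": float(self.grid.fitness.mean()),
            "best_fitness": float(self.grid.fitness.max()),
            "mean_metabolic_error": float(self.grid.metabolic_error.mean()),
            "mean_length": float(lengths.mean()),
            "mean_coding": float(coding.mean()),
            "mean_noncoding": float((lengths - coding).mean()),
            "mean_coding_fraction": float((coding / lengths).mean()),
        }


@dataclass
class LineagePath:
    """Line of descent of one final cell: per-generation ancestor cells and
    their replayed genomes."""

    record: LineageRecord
    cells: np.ndarray          # flat ancestor cell per generation (start..end)
    start_generation: int

    @property
    def end_generation(self) -> int:
        return self.start_generation + self.cells.size - 1

    def genomes(self) -> Iterator[np.ndarray]:
        """Replay the ancestor genomes from the recorded event logs."""
        rec = self.record
        t0 = self.start_generation - rec.start_generation
        bits = rec.initial_genomes[int(self.cells[0])] if t0 == 0 else None
        if bits is None:
            raise LineageIntegrityError(
                "replay must start at the record's first generation"
            )
        yield bits
        for i in range(1, self.cells.size):
            events = rec.events[t0 + i - 1].get(int(self.cells[i]), [])
            if events:
                bits = apply_events(bits, events)
            yield bits

    def metrics(
        self,
        target: EnvironmentTarget,
        params: FitnessParams | None = None,
    ) -> pd.DataFrame:
        """Per-generation table: fitness, L, coding, noncoding, fraction."""
        params = params if params is not None else FitnessParams()
        rows = []
        prev_key: bytes | None = None
        prev_row = None
        for gen, bits in zip(
            range(self.start_generation, self.end_generation + 1), self.genomes()
        ):
            key = bits.tobytes()
            if key == prev_key:
                row = dict(prev_row)
            else:
                g_err, fit, coding = evaluate_bits(bits, target.values, params.k)
                L = int(bits.size)
                row = {
                    "fitness": fit,
                    "metabolic_error": g_err,
                    "length": L,
                    "coding": coding,
                    "noncoding": L - coding,
                    "coding_fraction": coding / L,
                }
                prev_key, prev_row = key, row
            row["generation"] = gen
            rows.append(row)
        df = pd.DataFrame(rows)
        return df[
            [
                "generation",
                "fitness",
                "metabolic_error",
                "length",
                "coding",
                "noncoding",
                "coding_fraction",
            ]
        ]


def reconstruct_line_of_descent(
    record: LineageRecord,
    final_cell: int | tuple[int, int],
    start_generation: int | None = None,
    end_generation: int | None = None,
) -> LineagePath:
    """Walk parent pointers back from ``final_cell`` at ``end_generation``.

    Returns the ordered ancestor series from ``start_generation`` (default:
    the record's first generation) to ``end_generation`` (default: last).
    """
    start = record.start_generation if start_generation is None else start_generation
    end = record.last_generation if end_generation is None else end_generation
    if not record.start_generation <= start <= end <= record.last_generation:
        raise LineageIntegrityError(
            f"records cover [{record.start_generation}, {record.last_generation}], "
            f"requested [{start}, {end}]"
        )
    if isinstance(final_cell, tuple):
        y, x = final_cell
        flat = (y % record.height) * record.width + (x % record.width)
    else:
        flat = int(final_cell)
    n_steps = end - record.start_generation
    cells = np.empty(end - start + 1, dtype=np.int64)
    cur = flat
    pos = cells.size - 1
    cells[pos] = cur
    for t in range(n_steps - 1, -1, -1):
        cur = int(record.parents[t][cur])
        gen = record.start_generation + t
        if gen >= start:
            pos -= 1
            cells[pos] = cur
    return LineagePath(record=record, cells=cells, start_generation=start)


def analysis_horizon(total_generations: int, margin: int) -> int:
    """Generation up to which lineage analyses run: G_total - ΔG."""
    if total_generations <= margin:
        raise ValueError("margin must be smaller than the run length")
    return total_generations - margin


def coalescence_truncation(
    record: LineageRecord,
    total_generations: int,
    margin: int,
    rng: np.random.Generator | None = None,
) -> int:
    """Return the analysis horizon G_total - ΔG and warn if two random final
    cells do *not* share their ancestor at the horizon (population not yet
    coalesced, so the truncated lineage may not represent everyone)."""
    horizon = analysis_horizon(total_generations, margin)
    n = record.width * record.height
    if rng is None:
        a, b = 0, n - 1
    else:
        a, b = (int(x) for x in rng.choice(n, size=2, replace=False))
    anc_a = reconstruct_line_of_descent(
        record, a, end_generation=total_generations
    ).cells
    anc_b = reconstruct_line_of_descent(
        record, b, end_generation=total_generations
    ).cells
    off = horizon - record.start_generation
    if anc_a[off] != anc_b[off]:
        warnings.warn(
            f"population has not coalesced by generation {horizon}",
            NotCoalescedWarning,
            stacklevel=2,
        )
    return horizon
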