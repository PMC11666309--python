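"""Experiment orchestration: wild types, perturbations, condition matrices.

The experimental design has two stages.  First, *wild types* (WTs) are
evolved from random founders under basal conditions (population N₀, per-type
rate μ₀, no mutational bias) until their genome structure is stationary; the
WT genome is the final population's common ancestor.  Second, clonal
populations founded by a WT are confronted with new conditions — population
size and/or mutation rate multiplied or divided by 4 or 16, or 2:1 mutational
biases at conserved total rate — and the line of descent of the final
population is analyzed.

Desk-scale defaults (N₀=256, L₀=2,000 bp, μ₀=1e-5, 50,000 WT generations,
20,000 perturbation generations, ΔG=1,000, 5 replicates) make the protocol
runnable on one workstation core; :meth:`ExperimentConfig.paper_scale`
switches to the full cluster-sized design (N₀=1,024, μ₀=1e-6, 10M WT
generations, 2.1M perturbation generations, ΔG=100,000, 10 replicates,
10,000 robustness offspring).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .chemistry import (
    DEFAULT_GRID,
    DEFAULT_K,
    DEFAULT_TARGET_GAUSSIANS,
    EnvironmentTarget,
    FitnessParams,
    build_target,
)
from .decoder import decode, evaluate_bits
from .genome import Genome, MutationRates, MutationType
from .population import (
    LineagePath,
    LineageRecord,
    Simulation,
    coalescence_truncation,
    reconstruct_line_of_descent,
)
from .robustness import estimate_robustness

__all__ = [
    "ExperimentConfig",
    "ConditionSpec",
    "WildType",
    "RunOutput",
    "ConfigurationError",
    "evolve_wild_type",
    "run_perturbation",
    "run_replicates",
    "condition_matrix",
    "bias_matrix",
    "derive_seed",
    "grid_shape",
]

#: Mutational bias configurations: (favoured type, disfavoured type); the
#: favoured rate is set to twice the disfavoured one at conserved pair sum.
BIASES = {
    "deletion": (MutationType.LARGE_DELETION, MutationType.DUPLICATION),
    "insertion": (MutationType.DUPLICATION, MutationType.LARGE_DELETION),
    "small_deletion": (MutationType.SMALL_DELETION, MutationType.SMALL_INSERTION),
    "small_insertion": (MutationType.SMALL_INSERTION, MutationType.SMALL_DELETION),
}


class ConfigurationError(ValueError):
    pass


def derive_seed(base: int, *tags: int) -> int:
    """Deterministic child seed (< 2^31) from a base seed and integer tags."""
    ss = np.random.SeedSequence([int(base), *[int(t) for t in tags]])
    return int(ss.generate_state(1)[0] % 2**31)


def grid_shape(n: int) -> tuple[int, int]:
    """Square-most factorization (height, width) with H <= W and H*W = n."""
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    for a in range(int(np.sqrt(n)), 0, -1):
        if n % a == 0:
            return a, n // a
    raise AssertionError("unreachable")


def snap_to_square(n: float) -> int:
    """Nearest perfect square (the paper's squared-grid population sizes:
    1024/2 -> 529 = 23², 1024*2 -> 2025 = 45²)."""
    r = max(1, round(float(n) ** 0.5))
    return r * r


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything that determines a run; hashable to a manifest digest."""

    n: int = 256                      # population size (W*H)
    mu: float = 1e-5                  # basal per-type per-bp rate
    rate_multipliers: tuple[float, ...] = (1.0,) * 7
    bias: str | None = None           # one of BIASES or None
    k: float = DEFAULT_K
    generations: int = 20_000         # perturbation run length G_total
    coalescence_margin: int = 1_000   # ΔG
    wt_generations: int = 50_000      # WT evolution length
    founder_length: int = 2_000       # L0 of the random founder
    grid_points: int = DEFAULT_GRID   # phenotype/target grid D
    target_gaussians: tuple = DEFAULT_TARGET_GAUSSIANS
    seed: int = 0
    replicates: int = 5
    wt_count: int = 1
    sample_every: int = 100           # population metric cadence
    robustness_every: int = 1_000     # lineage robustness cadence
    robustness_offspring: int = 1_000
    coding_mode: str = "cds"
    wt_source: str = "fresh"          # "fresh" or a FASTA path

    def __post_init__(self):
        if self.bias is not None and self.bias not in BIASES:
            raise ConfigurationError(f"unknown bias {self.bias!r}")
        if len(self.rate_multipliers) != 7:
            raise ConfigurationError("need one rate multiplier per mutation type")
        if any(m <= 0 for m in self.rate_multipliers):
            raise ConfigurationError("rate multipliers must be > 0")

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        """The full cluster-sized design of the original experiments."""
        base = dict(
            n=1024,
            mu=1e-6,
            generations=2_100_000,
            coalescence_margin=100_000,
            wt_generations=10_000_000,
            founder_length=5_000,
            replicates=10,
            wt_count=5,
            sample_every=1_000,
            robustness_every=1_000,
            robustness_offspring=10_000,
        )
        base.update(overrides)
        return cls(**base)

    def rates(self) -> MutationRates:
        """Per-type rates: μ times the per-type multiplier, then the 2:1 bias
        rescaling of the affected pair at conserved pair (and total) sum."""
        arr = self.mu * np.asarray(self.rate_multipliers, dtype=float)
        if self.bias is not None:
            fav, dis = BIASES[self.bias]
            pair = arr[fav] + arr[dis]
            arr[fav] = 2.0 * pair / 3.0
            arr[dis] = pair / 3.0
        return MutationRates(*arr)

    def grid(self) -> tuple[int, int]:
        return grid_shape(self.n)

    def target(self) -> EnvironmentTarget:
        return build_target(self.grid_points, self.target_gaussians)

    def params(self) -> FitnessParams:
        return FitnessParams(k=self.k)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        d = self.to_dict()
        d["rate_multipliers"] = list(d["rate_multipliers"])
        d["target_gaussians"] = [list(g) for g in d["target_gaussians"]]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        if "rate_multipliers" in d:
            d["rate_multipliers"] = tuple(d["rate_multipliers"])
        if "target_gaussians" in d:
            d["target_gaussians"] = tuple(tuple(g) for g in d["target_gaussians"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_yaml(Path(path).read_text())

    def digest(self) -> str:
        return bio.config_digest(self.to_dict())


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the condition matrix."""

    config: ExperimentConfig
    n_multiplier: Fraction
    mu_multiplier: Fraction
    product_class: str

    @property
    def label(self) -> str:
        return f"N×{self.n_multiplier} μ×{self.mu_multiplier}"


#: The 13 tested (N multiplier, μ multiplier) combinations; the (1, 1) row is
#: the control.  Product classes follow the nominal multipliers (the ~1/2 and
#: ~2 population rows land on the nearest square grid).
CONDITION_MULTIPLIERS: tuple[tuple[Fraction, Fraction], ...] = (
    (Fraction(1, 16), Fraction(1)),
    (Fraction(1, 4), Fraction(1)),
    (Fraction(1), Fraction(1)),
    (Fraction(1, 2), Fraction(2)),
    (Fraction(1, 4), Fraction(4)),
    (Fraction(1, 16), Fraction(16)),
    (Fraction(2), Fraction(2)),
    (Fraction(4), Fraction(1)),
    (Fraction(1), Fraction(4)),
    (Fraction(4), Fraction(4)),
    (Fraction(16), Fraction(1)),
    (Fraction(1), Fraction(16)),
    (Fraction(16), Fraction(16)),
)


def condition_matrix(base: ExperimentConfig) -> list[ConditionSpec]:
    """The 13 (N, μ) conditions scaled from ``base``; population sizes snap
    to the nearest perfect square so the grid stays square."""
    out = []
    for n_mult, mu_mult in CONDITION_MULTIPLIERS:
        n = snap_to_square(base.n * float(n_mult))
        cfg = replace(base, n=n, mu=base.mu * float(mu_mult))
        out.append(
            ConditionSpec(
                config=cfg,
                n_multiplier=n_mult,
                mu_multiplier=mu_mult,
                product_class=str(n_mult * mu_mult),
            )
        )
    return out


def bias_matrix(base: ExperimentConfig) -> list[ExperimentConfig]:
    """The four 2:1 mutational-bias configurations at conserved total rate."""
    return [replace(base, bias=b) for b in BIASES]


# ---------------------------------------------------------------------------
# wild-type evolution
# ---------------------------------------------------------------------------


@dataclass
class WildType:
    genome: Genome
    founder: Genome
    config: ExperimentConfig
    lineage_metrics: pd.DataFrame
    stationarity_slope: float
    horizon: int


def _empty_phenotype_error(target: EnvironmentTarget) -> float:
    """Metabolic error of an empty phenotype, via the same summation kernel
    used for real genomes (bit-comparable with evaluate_bits output)."""
    from . import _kernels

    _, g = _kernels.phenotype_and_error(
        np.empty((0, 4)), np.empty(0, dtype=np.int64), target.values
    )
    return float(g)


#: Minimum metabolic-error improvement over the empty phenotype a random
#: founder must show: filters out genomes whose only proteins are clipped
#: away or negligible, which would feel no selection gradient at all.
FOUNDER_MIN_GAIN = 1e-3


def sample_founder(
    length: int,
    target: EnvironmentTarget,
    params: FitnessParams,
    rng: np.random.Generator,
    max_tries: int = 200_000,
) -> Genome:
    """Random founder that decodes to at least one protein and visibly beats
    the empty phenotype (the platform's usual seeded-founder practice)."""
    empty = _empty_phenotype_error(target)
    for _ in range(max_tries):
        g = Genome.random(length, rng)
        g_err, _, coding = evaluate_bits(g.bits, target.values, params.k)
        if coding > 0 and g_err <= empty - FOUNDER_MIN_GAIN:
            return g
    raise ConfigurationError(
        f"no viable founder of {length} bp found in {max_tries} draws"
    )


def evolve_wild_type(
    cfg: ExperimentConfig, wt_index: int = 0
) -> WildType:
    """Evolve one WT at basal conditions and extract the final population's
    common ancestor at the truncation horizon.

    Also reports a genome-structure stationarity indicator: the linear slope
    of genome length (bp/generation) over the last 20% of the analyzed
    lineage.
    """
    from scipy import stats

    target = cfg.target()
    params = cfg.params()
    founder_rng = np.random.default_rng(derive_seed(cfg.seed, 1, wt_index))
    founder = sample_founder(cfg.founder_length, target, params, founder_rng)
    H, W = cfg.grid()
    sim = Simulation(
        founder,
        width=W,
        height=H,
        rates=cfg.rates(),
        params=params,
        target=target,
        seed=derive_seed(cfg.seed, 2, wt_index),
    )
    sim.run(cfg.wt_generations)
    if cfg.wt_generations == 0:
        df = LineagePath(
            record=sim.record, cells=np.zeros(1, dtype=np.int64), start_generation=0
        ).metrics(target, params)
        return WildType(
            genome=founder,
            founder=founder,
            config=cfg,
            lineage_metrics=df,
            stationarity_slope=0.0,
            horizon=0,
        )
    pick_rng = np.random.default_rng(derive_seed(cfg.seed, 3, wt_index))
    horizon = coalescence_truncation(
        sim.record, cfg.wt_generations, min(cfg.coalescence_margin, cfg.wt_generations - 1),
        rng=pick_rng,
    )
    path = reconstruct_line_of_descent(
        sim.record, int(pick_rng.integers(sim.grid.size))
    )
    metrics = path.metrics(target, params).iloc[: horizon + 1]
    wt_bits = None
    for gen, bits in zip(range(path.cells.size), path.genomes()):
        if gen == horizon:
            wt_bits = bits
            break
    tail = metrics.iloc[int(len(metrics) * 0.8):]
    slope = float(
        stats.linregress(tail["generation"], tail["length"]).slope
    ) if len(tail) > 2 else 0.0
    return WildType(
        genome=Genome(bits=wt_bits),
        founder=founder,
        config=cfg,
        lineage_metrics=metrics,
        stationarity_slope=slope,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# perturbation runs
# ---------------------------------------------------------------------------


@dataclass
class RunOutput:
    """All outputs of one replicate run, traceable to (config, seed, replicate)."""

    population: pd.DataFrame
    lineage: pd.DataFrame
    robustness: pd.DataFrame
    final: dict
    manifest: dict

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.population.to_csv(outdir / "population.csv", index=False)
        self.lineage.to_csv(outdir / "lineage.csv", index=False)
        self.robustness.to_csv(outdir / "robustness.csv", index=False)
        bio.write_manifest(outdir / "final.json", self.final)
        bio.write_manifest(outdir / "manifest.json", self.manifest)


def run_perturbation(
    wt: Genome,
    cfg: ExperimentConfig,
    replicate: int = 0,
) -> RunOutput:
    """Run one clonal population founded by ``wt`` under ``cfg`` and analyze
    its line of descent up to the truncation horizon."""
    target = cfg.target()
    params = cfg.params()
    g_err, fit, coding = evaluate_bits(wt.bits, target.values, params.k)
    if coding == 0:
        raise ConfigurationError("wild type decodes to zero proteins under this target")
    H, W = cfg.grid()
    sim = Simulation(
        wt,
        width=W,
        height=H,
        rates=cfg.rates(),
        params=params,
        target=target,
        seed=derive_seed(cfg.seed, 10, replicate),
    )
    pop_rows = [sim.population_metrics()]
    def _sample(grid):
        if grid.generation % cfg.sample_every == 0 or grid.generation == cfg.generations:
            pop_rows.append(sim.population_metrics())
    sim.run(cfg.generations, callback=_sample)

    pick_rng = np.random.default_rng(derive_seed(cfg.seed, 11, replicate))
    margin = min(cfg.coalescence_margin, max(cfg.generations - 1, 0))
    if cfg.generations > 0:
        horizon = coalescence_truncation(
            sim.record, cfg.generations, margin, rng=pick_rng
        )
        path = reconstruct_line_of_descent(
            sim.record, int(pick_rng.integers(sim.grid.size))
        )
    else:
        horizon = 0
        path = LineagePath(
            record=sim.record, cells=np.zeros(1, dtype=np.int64), start_generation=0
        )
    lineage = path.metrics(target, params).iloc[: horizon + 1]

    rob_rows = []
    rob_rng = np.random.default_rng(derive_seed(cfg.seed, 12, replicate))
    rates = cfg.rates()
    for gen, bits in zip(range(path.cells.size), path.genomes()):
        if gen > horizon:
            break
        if gen % cfg.robustness_every == 0 or gen == horizon:
            est = estimate_robustness(
                bits,
                rates,
                n_offspring=cfg.robustness_offspring,
                rng=rob_rng,
                target=target,
                params=params,
            )
            rob_rows.append(
                {
                    "generation": gen,
                    "nu": est.nu,
                    "ci_lo": est.ci_low,
                    "ci_hi": est.ci_high,
                    "n_offspring": est.n_offspring,
                }
            )
    robustness = pd.DataFrame(rob_rows)

    final = lineage.iloc[-1].to_dict()
    final.update(
        {
            "replicate": replicate,
            "horizon": horizon,
            "n": cfg.n,
            "mu": cfg.mu,
            "bias": cfg.bias or "none",
        }
    )
    manifest = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "replicate": replicate,
        "run_seed": derive_seed(cfg.seed, 10, replicate),
        "wt_length": int(wt.bits.size),
        "coding_definition": cfg.coding_mode,
    }
    return RunOutput(
        population=pd.DataFrame(pop_rows),
        lineage=lineage,
        robustness=robustness,
        final=final,
        manifest=manifest,
    )


def run_replicates(
    wt: Genome,
    cfg: ExperimentConfig,
    n_multiplier: Fraction | float = Fraction(1),
    mu_multiplier: Fraction | float = Fraction(1),
    product_class: str | None = None,
) -> pd.DataFrame:
    """Run ``cfg.replicates`` independent replicates; return one final-ancestor
    row per replicate, tagged with the condition multipliers."""
    rows = []
    for rep in range(cfg.replicates):
        out = run_perturbation(wt, cfg, replicate=rep)
        row = dict(out.final)
        row["n_multiplier"] = float(n_multiplier)
        row["mu_multiplier"] = float(mu_multiplier)
        row["product_class"] = (
            product_class
            if product_class is not None
            else str(Fraction(n_multiplier) * Fraction(mu_multiplier))
        )
        rows.append(row)
    return pd.DataFrame(rows)
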