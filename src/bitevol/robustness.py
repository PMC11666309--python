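"""Replicative robustness: measurement, scaling predictions and summaries.

The replicative robustness ν of an individual is the probability that one of
its offspring has *exactly* the parent's fitness, i.e. underwent no mutation
or only neutral ones.  "Exactly" is implemented as bit-identical metabolic
error under the canonical, order-fixed decoding — no epsilon — which is
meaningful because decoding is a pure deterministic function.

Under the independent-events (Poisson) model, deleterious events arrive at
rate λ = -ln ν per replication; multiplying every mutation rate by ``c``
scales λ by ``c``, hence the prediction ν(c·μ) = ν(μ)^c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chemistry import EnvironmentTarget, FitnessParams, build_target
from .decoder import evaluate_bits
from .genome import (
    Genome,
    LOCAL_EVENTS,
    MutationRates,
    MutationType,
    REARRANGEMENTS,
    apply_event,
    draw_event,
    mutate_bits,
)

__all__ = [
    "RobustnessEstimate",
    "estimate_robustness",
    "predict_rate_scaled_robustness",
    "compose_single_event_neutrality",
    "per_type_robustness",
    "summarize_lineage",
    "build_isocline_table",
]


@dataclass(frozen=True)
class RobustnessEstimate:
    """Neutral-offspring fraction with its binomial 95% CI."""

    nu: float
    n_offspring: int
    ci_low: float
    ci_high: float
    per_type: dict[MutationType, float] | None = None

    def scaled(self, factor: float) -> float:
        return predict_rate_scaled_robustness(self.nu, factor)


def _wilson_ci(successes: int, n: int) -> tuple[float, float]:
    lo, hi = stats.binomtest(successes, n).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    return float(lo), float(hi)


def estimate_robustness(
    individual: Genome | np.ndarray,
    rates: MutationRates,
    n_offspring: int = 10_000,
    rng: np.random.Generator | None = None,
    target: EnvironmentTarget | None = None,
    params: FitnessParams | None = None,
) -> RobustnessEstimate:
    """Monte-Carlo ν: generate ``n_offspring`` mutated replicates and count
    those whose metabolic error equals the parent's bit-exactly.

    Offspring that drew no event at all are neutral without re-decoding
    (decoding is pure), which makes the estimator cheap at low rates.
    """
    if n_offspring < 1:
        raise ValueError("need at least one offspring")
    rng = rng if rng is not None else np.random.default_rng()
    target = target if target is not None else build_target()
    params = params if params is not None else FitnessParams()
    bits = individual.bits if isinstance(individual, Genome) else individual
    parent_err, _, _ = evaluate_bits(bits, target.values, params.k)

    counts = rng.binomial(bits.size, rates.as_array()[None, :], size=(n_offspring, 7))
    neutral = 0
    for i in range(n_offspring):
        if counts[i].sum() == 0:
            neutral += 1
            continue
        child, events = mutate_bits(bits, counts[i], rng)
        err, _, _ = evaluate_bits(child, target.values, params.k)
        if err == parent_err:
            neutral += 1
    lo, hi = _wilson_ci(neutral, n_offspring)
    return RobustnessEstimate(
        nu=neutral / n_offspring, n_offspring=n_offspring, ci_low=lo, ci_high=hi
    )


def predict_rate_scaled_robustness(nu_base: float, factor: float) -> float:
    """ν after multiplying all mutation rates by ``factor``: ν_base^factor.

    Deleterious events are modelled as a Poisson stream with rate
    -ln(ν_base); scaling every per-type rate by ``factor`` scales that rate,
    giving ν = exp(factor · ln ν_base).
    """
    if not 0.0 < nu_base <= 1.0:
        raise ValueError("base neutral fraction must be in (0, 1]")
    if factor <= 0:
        raise ValueError("rate factor must be > 0")
    return float(nu_base**factor)


def compose_single_event_neutrality(
    nu_single: float, length: int, rate: float
) -> float:
    """Expected ν when events of one type arrive Binomial(L, rate) and each
    event is independently neutral with probability ``nu_single``:
    Σ_k C(L,k) μ^k (1-μ)^(L-k) ν₁^k = (1 - μ(1 - ν₁))^L."""
    return float((1.0 - rate * (1.0 - nu_single)) ** length)


def per_type_robustness(
    individual: Genome | np.ndarray,
    rates: MutationRates,
    n_per_type: int = 1_000,
    rng: np.random.Generator | None = None,
    target: EnvironmentTarget | None = None,
    params: FitnessParams | None = None,
) -> dict[str, float]:
    """Neutral fraction of offspring carrying exactly one *forced* event of
    each type (types with rate 0 are skipped), plus the local-mutation vs
    chromosomal-rearrangement group means.

    Forced single events (rather than post-hoc classification of natural
    offspring) keep the per-type decomposition unconfounded; this semantics
    is recorded in the returned metadata key.
    """
    rng = rng if rng is not None else np.random.default_rng()
    target = target if target is not None else build_target()
    params = params if params is not None else FitnessParams()
    bits = individual.bits if isinstance(individual, Genome) else individual
    parent_err, _, _ = evaluate_bits(bits, target.values, params.k)

    out: dict[str, float] = {"semantics": "forced_single_event"}
    groups: dict[str, list[float]] = {"local": [], "rearrangement": []}
    for mtype in MutationType:
        if rates.rate_of(mtype) == 0.0:
            continue
        neutral = 0
        for _ in range(n_per_type):
            ev = draw_event(bits, mtype, rng)
            child = apply_event(bits, ev)
            err, _, _ = evaluate_bits(child, target.values, params.k)
            if err == parent_err:
                neutral += 1
        frac = neutral / n_per_type
        out[f"nu_{mtype.name.lower()}"] = frac
        groups["local" if mtype in LOCAL_EVENTS else "rearrangement"].append(frac)
    for name, vals in groups.items():
        if vals:
            out[f"nu_{name}_mean"] = float(np.mean(vals))
    return out


def summarize_lineage(
    metrics: pd.DataFrame, window: int = 100
) -> pd.DataFrame:
    """Windowed means/SD of a line-of-descent metric table.

    ``metrics`` must carry per-generation columns ``fitness, length, coding,
    noncoding, coding_fraction``; rolling statistics (centred, min_periods=1)
    are appended as ``<col>_mean`` / ``<col>_sd``.
    """
    if metrics.empty:
        raise ValueError("lineage series is empty")
    cols = ["fitness", "length", "coding", "noncoding", "coding_fraction"]
    out = metrics.copy()
    roll = metrics[cols].rolling(window=window, center=True, min_periods=1)
    for c in cols:
        out[f"{c}_mean"] = roll.mean()[c]
        out[f"{c}_sd"] = roll.std(ddof=0)[c]
    return out


def build_isocline_table(final_rows: pd.DataFrame) -> pd.DataFrame:
    """Group per-replicate final-ancestor rows into the (N, μ) condition
    table with per-product-class means.

    ``final_rows`` needs columns ``n_multiplier, mu_multiplier,
    product_class, length, coding, noncoding, coding_fraction`` (one row per
    replicate).  Returns one row per condition: replicate count, means and
    coding-fraction dispersion (SD over replicates), plus the class-level
    mean coding fraction broadcast as ``class_coding_fraction``.
    """
    if final_rows.empty:
        raise ValueError("no run outputs to tabulate")
    grouped = (
        final_rows.groupby(["n_multiplier", "mu_multiplier", "product_class"])
        .agg(
            replicates=("coding_fraction", "size"),
            mean_length=("length", "mean"),
            mean_coding=("coding", "mean"),
            mean_noncoding=("noncoding", "mean"),
            mean_coding_fraction=("coding_fraction", "mean"),
            sd_coding_fraction=("coding_fraction", lambda s: s.std(ddof=0)),
        )
        .reset_index()
    )
    cls = (
        final_rows.groupby("product_class")["coding_fraction"]
        .mean()
        .rename("class_coding_fraction")
    )
    return grouped.merge(cls, on="product_class")
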