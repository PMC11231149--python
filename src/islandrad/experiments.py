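"""Replicate batches, parameter sweeps and summary statistics.

A batch runs independent replicates of one parameter setting with seeds
derived deterministically from a base seed.  Summaries report the
percentage of uncensored replicates classified as simultaneous speciation
(with an exact Clopper-Pearson 95% confidence interval) and the min /
median / max speciation interval, the quantities used to compare parameter
settings.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import run_simulation
from .params import (
    GeometryError,
    SimulationParams,
    build_geometry,
    validate_params,
)
from .speciation import SpeciationResult

PRESETS = {
    "default": dict(
        x=0.0, y=0.0, mu=1e-4, N_A=100, N_B=100, N_C=100, q=1, DS=0.7, M=0.5
    ),
    "realistic": dict(
        x=-1.0, y=0.0, mu=1e-5, N_A=5000, N_B=5000, N_C=5000, q=1, DS=0.05, M=0.5
    ),
}


def preset(name: str, q: int | None = None, **overrides) -> SimulationParams:
    """Named parameter bundles.

    ``default`` is the fast exploration set (small populations, strong
    selection); ``realistic`` uses larger populations, a lower mutation
    rate and weak selection; ``table1_q`` is the default set with the
    number of dispersal loci overridden.
    """
    if name == "table1_q":
        if q is None:
            raise ValueError("preset 'table1_q' requires q")
        base = dict(PRESETS["default"], q=q)
    elif name in PRESETS:
        base = dict(PRESETS[name])
        if q is not None:
            base["q"] = q
    else:
        raise ValueError(
            f"unknown preset {name!r}; choose from "
            f"{sorted(PRESETS) + ['table1_q']}"
        )
    base.update(overrides)
    return validate_params(SimulationParams(**base))


def replicate_seeds(base_seed: int, n_replicates: int) -> list[int]:
    """Distinct per-replicate seeds derived from (base_seed, index)."""
    seeds: list[int] = []
    seen = set()
    for i in range(n_replicates):
        ss = np.random.SeedSequence(base_seed, spawn_key=(i,))
        s = int(ss.generate_state(1, np.uint64)[0] % (2**31))
        while s in seen:  # vanishingly unlikely; keep seeds distinct
            s = (s + 1) % (2**31)
        seen.add(s)
        seeds.append(s)
    return seeds


@dataclass
class ReplicateBatch:
    """Results of independent replicates of one parameter setting."""

    params: SimulationParams
    n_replicates: int
    base_seed: int
    seeds: list[int]
    results: list[SpeciationResult]

    @property
    def uncensored(self) -> list[SpeciationResult]:
        return [r for r in self.results if not r.censored]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seed, r in zip(self.seeds, self.results):
            rows.append(
                dict(
                    seed=seed,
                    onset_first=r.onset_first,
                    onset_second=r.onset_second,
                    interval=r.interval,
                    simultaneous=r.simultaneous,
                    censored=r.censored,
                    first_isolated=r.first_isolated,
                    n_generations=r.n_generations,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class BatchSummary:
    """Aggregate of a replicate batch over its uncensored runs."""

    n: int
    freq_simultaneous: float  # percent
    ci_low: float  # percent, exact binomial
    ci_high: float  # percent
    interval_min: int
    interval_median: float
    interval_max: int
    n_censored: int

    def to_dict(self) -> dict:
        return dict(
            n=self.n,
            freq_simultaneous=self.freq_simultaneous,
            ci_low=self.ci_low,
            ci_high=self.ci_high,
            interval_min=self.interval_min,
            interval_median=self.interval_median,
            interval_max=self.interval_max,
            n_censored=self.n_censored,
        )


def run_replicates(
    params: SimulationParams,
    n_replicates: int,
    base_seed: int,
    progress: bool = False,
) -> ReplicateBatch:
    """Run ``n_replicates`` independent simulations with derived seeds."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    params = validate_params(params)
    seeds = replicate_seeds(base_seed, n_replicates)
    results = []
    iterator = enumerate(seeds)
    for i, seed in iterator:
        rep_params = SimulationParams(**{**params.to_dict(), "seed": seed})
        _, result = run_simulation(rep_params, keep_records=False)
        results.append(result)
        if progress:
            print(
                f"replicate {i}: seed={seed} interval={result.interval} "
                f"censored={result.censored}"
            )
    return ReplicateBatch(
        params=params,
        n_replicates=n_replicates,
        base_seed=base_seed,
        seeds=seeds,
        results=results,
    )


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion, as fractions."""
    if n == 0:
        raise ValueError("n must be positive")
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def summarize(batch: ReplicateBatch) -> BatchSummary:
    """Summary statistics over a batch's uncensored replicates.

    Raises ``ValueError`` when every replicate is censored (no intervals
    exist to summarize).
    """
    good = batch.uncensored
    if not good:
        raise ValueError("all replicates censored; no summary possible")
    intervals = np.array([r.interval for r in good])
    k = sum(r.simultaneous for r in good)
    n = len(good)
    lo, hi = clopper_pearson(k, n)
    return BatchSummary(
        n=n,
        freq_simultaneous=100.0 * k / n,
        ci_low=100.0 * lo,
        ci_high=100.0 * hi,
        interval_min=int(intervals.min()),
        interval_median=float(np.median(intervals)),
        interval_max=int(intervals.max()),
        n_censored=len(batch.results) - n,
    )


def _sweep_row(x, y, summary: BatchSummary | None, n_censored_all: int = 0) -> dict:
    geom = build_geometry(x, y)
    row = dict(
        x=x,
        y=y,
        isolation_index=geom.isolation_index,
        isolated_island=geom.isolated_island,
    )
    if summary is not None:
        row.update(summary.to_dict())
    else:
        row.update(
            n=0,
            freq_simultaneous=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            interval_min=np.nan,
            interval_median=np.nan,
            interval_max=np.nan,
            n_censored=n_censored_all,
        )
    return row


def geometry_sweep(
    x_values,
    y_values,
    n_replicates: int,
    params: SimulationParams,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Batch summaries over a grid of island-A placements.

    Each grid point is annotated with its isolation index and which island
    is the geographically isolated one.  Points coinciding with island B
    or C are skipped with a warning.  Deterministic for a fixed base seed.
    """
    rows = []
    for pt_idx, (x, y) in enumerate(itertools.product(x_values, y_values)):
        try:
            build_geometry(x, y)
        except GeometryError:
            warnings.warn(
                f"skipping grid point ({x}, {y}): coincides with an island"
            )
            continue
        pt_seed = int(
            np.random.SeedSequence(base_seed, spawn_key=(pt_idx,)).generate_state(
                1, np.uint64
            )[0]
            % (2**31)
        )
        pt_params = SimulationParams(**{**params.to_dict(), "x": x, "y": y})
        batch = run_replicates(pt_params, n_replicates, pt_seed)
        try:
            summary = summarize(batch)
        except ValueError:
            summary = None
        rows.append(_sweep_row(x, y, summary, n_censored_all=len(batch.results)))
        if progress:
            print(f"({x}, {y}): {rows[-1]}")
    return pd.DataFrame(rows)


def parameter_sweep(
    name: str,
    values,
    n_replicates: int,
    params: SimulationParams,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Batch summaries varying one scalar parameter (mu, DS, q, N_*, ...)."""
    rows = []
    for v_idx, v in enumerate(values):
        v_seed = int(
            np.random.SeedSequence(base_seed, spawn_key=(v_idx,)).generate_state(
                1, np.uint64
            )[0]
            % (2**31)
        )
        v_params = validate_params(
            SimulationParams(**{**params.to_dict(), name: v})
        )
        batch = run_replicates(v_params, n_replicates, v_seed)
        try:
            summary = summarize(batch).to_dict()
        except ValueError:
            summary = dict(n=0, n_censored=len(batch.results))
        rows.append({name: v, **summary})
    return pd.DataFrame(rows)
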