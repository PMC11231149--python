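"""Configuration files, result serialization and Newick export."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import GenerationRecord
from .experiments import BatchSummary, ReplicateBatch
from .params import PAIR_LABELS, SimulationParams, validate_params
from .speciation import MigrantSeries, SpeciationResult

_PARAM_KEYS = {f.name for f in dataclasses.fields(SimulationParams)}
#: keys accepted in config files beyond the simulation parameters
_RUN_KEYS = {"n_replicates"}


class ConfigError(ValueError):
    """A configuration file could not be parsed or validated."""


def load_config(path) -> SimulationParams:
    """Read a flat key-value (YAML) config into validated parameters.

    Missing keys take their defaults; unknown keys are rejected.  The run
    control ``n_replicates`` is accepted (see :func:`load_run_config`).
    """
    params, _ = load_run_config(path)
    return params


def load_run_config(path) -> tuple[SimulationParams, int]:
    """Like :func:`load_config` but also returning ``n_replicates``."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a flat key-value mapping")
    unknown = set(raw) - _PARAM_KEYS - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    n_replicates = int(raw.pop("n_replicates", 1))
    try:
        params = validate_params(SimulationParams(**raw))
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return params, n_replicates


def write_config(params: SimulationParams, path) -> None:
    """Write parameters as a flat YAML document (round-trips exactly)."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True, default_flow_style=False)
    )


@dataclass
class RunManifest:
    """Everything needed to reproduce a run's outputs bit-exactly."""

    params: dict
    seed: int
    software_version: str = __version__
    start_time: str = ""
    end_time: str = ""
    replicate_seeds: list[int] = field(default_factory=list)
    output_files: list[str] = field(default_factory=list)

    @classmethod
    def begin(cls, params: SimulationParams, seed: int, replicate_seeds=None):
        return cls(
            params=params.to_dict(),
            seed=seed,
            replicate_seeds=list(replicate_seeds or []),
            start_time=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )

    def finish(self, output_files) -> "RunManifest":
        if not self.end_time:  # first finish wins: re-writes stay idempotent
            self.end_time = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.output_files = [str(p) for p in output_files]
        return self


def records_to_frame(
    records: list[GenerationRecord], window: int = 50
) -> pd.DataFrame:
    """Per-generation time series with per-pair moving averages.

    Columns: generation; per-island primitive-allele frequencies at the
    adaptation and dispersal loci; per-pair migration events, per-pair
    mean migrants per population (events / 2) and their trailing moving
    averages.
    """
    if not records:
        raise ValueError("no records to serialize")
    rows = []
    for r in records:
        row = {"generation": r.generation}
        for i, isl in enumerate("ABC"):
            row[f"adapt_freq_{isl}"] = r.adapt_freq[i]
            row[f"dispersal_freq_{isl}"] = r.dispersal_freq[i]
        for k, lab in enumerate(PAIR_LABELS):
            row[f"migrants_{lab}"] = r.migrants[k]
            row[f"migration_events_{lab}"] = r.migration_events[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    means = df[[f"migrants_{lab}" for lab in PAIR_LABELS]].to_numpy() / 2.0
    series = MigrantSeries(means, window=window)
    ma = series.moving_averages
    for k, lab in enumerate(PAIR_LABELS):
        df[f"mean_migrants_{lab}"] = means[:, k]
        df[f"ma_{lab}"] = ma[:, k]
    return df


def result_to_frame(result: SpeciationResult) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(result)])


def write_outputs(
    records: list[GenerationRecord],
    result: SpeciationResult,
    manifest: RunManifest,
    out_dir,
    window: int = 50,
) -> list[Path]:
    """Write the time-series table, the run summary and the manifest.

    Idempotent: identical inputs produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts_path = out / "timeseries.csv"
    records_to_frame(records, window=window).to_csv(ts_path, index=False)
    sm_path = out / "summary.csv"
    result_to_frame(result).to_csv(sm_path, index=False)
    mf_path = out / "manifest.json"
    paths = [ts_path, sm_path, mf_path]
    manifest.finish(paths)
    mf_path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return paths


def write_batch_outputs(
    batch: ReplicateBatch,
    summary: BatchSummary | None,
    manifest: RunManifest,
    out_dir,
) -> list[Path]:
    """Write per-replicate rows, the batch aggregate and the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rep_path = out / "replicates.csv"
    batch.to_frame().to_csv(rep_path, index=False)
    paths = [rep_path]
    if summary is not None:
        agg_path = out / "batch_summary.csv"
        pd.DataFrame([summary.to_dict()]).to_csv(agg_path, index=False)
        paths.append(agg_path)
    mf_path = out / "manifest.json"
    paths.append(mf_path)
    manifest.finish(paths)
    mf_path.write_text(json.dumps(dataclasses.asdict(manifest), indent=2))
    return paths


def export_newick(
    result: SpeciationResult, labels: dict[str, str] | None = None
) -> str:
    """Rooted three-taxon Newick tree implied by the two onsets.

    The first-isolated island is the outgroup; branch lengths are the
    speciation interval in generations, measured from the first onset.  A
    zero interval (all pairs crossed together) is emitted as a true
    polytomy.  Censored results cannot be exported.
    """
    if result.censored:
        raise ValueError("cannot export a tree for a censored run")
    lab = {k: k for k in "ABC"}
    if labels:
        lab.update(labels)
    interval = result.interval
    if interval == 0 or result.first_isolated is None:
        return f"({lab['A']}:0,{lab['B']}:0,{lab['C']}:0);"
    out = result.first_isolated
    ingroup = [k for k in "ABC" if k != out]
    return (
        f"(({lab[ingroup[0]]}:{interval:g},{lab[ingroup[1]]}:{interval:g}):0,"
        f"{lab[out]}:{interval:g});"
    )
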