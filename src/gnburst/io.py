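"""CSV/JSON interchange, run configuration, and stage orchestration.

Spike cohorts travel as two CSVs: a spike file (``neuron_id,
spike_time_s``) and a metadata file (``neuron_id, duration_s, treatment,
cycle_stage, location``).  Current-clamp sweeps travel as ``time_s,
voltage_mv`` CSVs with a JSON sidecar holding the acquisition metadata.
Headers are validated strictly so malformed files fail with the offending
column or neuron named.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .burst_analysis import (
    BurstSet,
    burst_table,
    interval_table,
    segment_bursts,
    subsample_bursts,
)
from .core import (
    CycleStage,
    Location,
    SpikeTrain,
    Treatment,
    ValidationError,
    mean_firing_rate,
)
from .group_stats import run_full_comparison_suite
from .pattern_classifier import (
    ClassifierConfig,
    Pattern,
    PatternLabel,
    ThresholdSearchResult,
    classify_train,
)

__all__ = [
    "RunConfig",
    "load_config",
    "load_spike_csv",
    "write_spike_csv",
    "load_sweep_csv",
    "write_sweep_csv",
    "run_classification",
    "run_comparisons",
]

SPIKE_COLUMNS = ["neuron_id", "spike_time_s"]
META_COLUMNS = ["neuron_id", "duration_s", "treatment", "cycle_stage", "location"]


@dataclass(frozen=True)
class RunConfig:
    """Analysis constants; defaults are the study's printed values."""

    burst_min_spikes: int = 4
    subsample_n: int = 100
    ks_alpha: float = 0.001
    proportion_alpha: float = 0.05
    tonic_limit_s: float = 1.0
    dvdt_threshold_v_per_s: float = 5.0
    junction_mv: float = 13.0
    qc_rs_max_mohm: float = 20.0
    qc_rin_min_mohm: float = 500.0
    quiet_rate_hz: float = 0.01
    min_pairs: int = 10
    quantile_lo: float = 0.01
    quantile_hi: float = 0.99
    n_quantiles: int = 99
    seed: int = 0

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            quantile_lo=self.quantile_lo,
            quantile_hi=self.quantile_hi,
            n_quantiles=self.n_quantiles,
            min_pairs=self.min_pairs,
            quiet_rate_hz=self.quiet_rate_hz,
            tonic_limit_s=self.tonic_limit_s,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML (or JSON) config file; keyword overrides win."""
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        unknown = set(loaded) - {f.name for f in dataclasses.fields(RunConfig)}
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def _check_columns(df: pd.DataFrame, expected: list[str], path: str | Path) -> None:
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )


def load_spike_csv(spike_path: str | Path, meta_path: str | Path) -> list[SpikeTrain]:
    """Load a cohort from spike + metadata CSVs, validating every train."""
    spikes = pd.read_csv(spike_path, dtype={"neuron_id": str})
    meta = pd.read_csv(meta_path, dtype={"neuron_id": str})
    _check_columns(spikes, SPIKE_COLUMNS, spike_path)
    _check_columns(meta, META_COLUMNS, meta_path)
    grouped = {nid: g["spike_time_s"].to_numpy(float) for nid, g in spikes.groupby("neuron_id", sort=False)}
    trains = []
    for row in meta.itertuples(index=False):
        times = grouped.pop(row.neuron_id, np.empty(0))
        try:
            trains.append(
                SpikeTrain(
                    neuron_id=row.neuron_id,
                    spike_times=times,
                    duration=float(row.duration_s),
                    treatment=Treatment(row.treatment),
                    cycle_stage=CycleStage(row.cycle_stage),
                    location=Location(row.location),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"neuron {row.neuron_id}: {exc}") from exc
    if grouped:
        raise ValidationError(
            f"{spike_path}: spikes for neurons missing from metadata: {sorted(grouped)}"
        )
    return trains


def write_spike_csv(
    trains: list[SpikeTrain], spike_path: str | Path, meta_path: str | Path
) -> None:
    spike_rows = []
    meta_rows = []
    for tr in trains:
        for t in tr.spike_times:
            spike_rows.append({"neuron_id": tr.neuron_id, "spike_time_s": t})
        meta_rows.append(
            {
                "neuron_id": tr.neuron_id,
                "duration_s": tr.duration,
                "treatment": tr.treatment.value,
                "cycle_stage": tr.cycle_stage.value,
                "location": tr.location.value,
            }
        )
    pd.DataFrame(spike_rows, columns=SPIKE_COLUMNS).to_csv(spike_path, index=False)
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(meta_path, index=False)


def write_sweep_csv(sweep, csv_path: str | Path, cell_id: str = "") -> None:
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        {"time_s": sweep.times_s, "voltage_mv": sweep.voltage_mv}
    )
    df.to_csv(csv_path, index=False)
    sidecar = {
        "cell_id": cell_id,
        "sample_rate_hz": sweep.sample_rate_hz,
        "current_step_pa": sweep.current_step_pa,
        "step_onset_s": sweep.step_onset_s,
        "step_offset_s": sweep.step_offset_s,
        "junction_corrected": sweep.junction_corrected,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_sweep_csv(csv_path: str | Path):
    from .excitability import VoltageSweep

    csv_path = Path(csv_path)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValidationError(f"missing sidecar JSON for sweep file {csv_path}")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    _check_columns(df, ["time_s", "voltage_mv"], csv_path)
    sweep = VoltageSweep(
        sample_rate_hz=float(meta["sample_rate_hz"]),
        voltage_mv=df["voltage_mv"].to_numpy(float),
        current_step_pa=float(meta["current_step_pa"]),
        step_onset_s=float(meta["step_onset_s"]),
        step_offset_s=float(meta["step_offset_s"]),
        junction_corrected=bool(meta.get("junction_corrected", False)),
    )
    return sweep, meta


@dataclass(frozen=True)
class NeuronResult:
    train: SpikeTrain
    label: PatternLabel
    search: ThresholdSearchResult | None
    bursts: BurstSet | None          # full segmentation (bursting cells)
    bursts_subsampled: BurstSet | None


def run_classification(
    trains: list[SpikeTrain], config: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[str, NeuronResult]]:
    """Classify every neuron and segment bursts for the bursting ones.

    Returns the per-neuron report table and the full per-neuron results.
    """
    config = config or RunConfig()
    ccfg = config.classifier_config()
    rows = []
    results: dict[str, NeuronResult] = {}
    for tr in trains:
        label, search = classify_train(tr, ccfg)
        bursts = sub = None
        theta = float("nan")
        counts = (0, 0, 0, 0)
        if search is not None:
            theta = search.optimal_threshold_s
            counts = search.optimal_partition.counts
        if label.label == Pattern.BURSTING and search is not None:
            bursts = segment_bursts(tr, theta, min_spikes=config.burst_min_spikes)
            sub = subsample_bursts(bursts, n=config.subsample_n, seed=config.seed)
        results[tr.neuron_id] = NeuronResult(tr, label, search, bursts, sub)
        rows.append(
            {
                "neuron_id": tr.neuron_id,
                "n_spikes": tr.n_spikes,
                "mean_rate_hz": mean_firing_rate(tr),
                "optimal_threshold_s": theta,
                "n1": counts[0],
                "n2": counts[1],
                "n3": counts[2],
                "n4": counts[3],
                "label": label.label.value,
                "rule_fired": label.rule,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=[
            "neuron_id",
            "n_spikes",
            "mean_rate_hz",
            "optimal_threshold_s",
            "n1",
            "n2",
            "n3",
            "n4",
            "label",
            "rule_fired",
        ],
    )
    return report, results


def run_comparisons(
    results: dict[str, NeuronResult], config: RunConfig | None = None
) -> dict[str, pd.DataFrame]:
    """Group the classified cohort by (treatment, cycle stage) and run the
    KS + Fisher comparison battery."""
    config = config or RunConfig()
    burst_sets: dict[tuple[str, str], list[BurstSet]] = {}
    labels: dict[tuple[str, str], list[Pattern]] = {}
    for res in results.values():
        key = (res.train.treatment.value, res.train.cycle_stage.value)
        labels.setdefault(key, []).append(res.label.label)
        if res.bursts_subsampled is not None and res.bursts_subsampled.n_bursts:
            burst_sets.setdefault(key, []).append(res.bursts_subsampled)
    return run_full_comparison_suite(
        burst_sets,
        labels,
        ks_alpha=config.ks_alpha,
        proportion_alpha=config.proportion_alpha,
    )


def write_reports(
    out_dir: str | Path,
    report: pd.DataFrame,
    results: dict[str, NeuronResult],
    config: RunConfig,
) -> None:
    """Write the classification report, burst/interval tables and provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "classification_report.csv", index=False)
    full_sets = [r.bursts for r in results.values() if r.bursts is not None]
    burst_table(full_sets).to_csv(out / "burst_table.csv", index=False)
    interval_table(full_sets).to_csv(out / "interval_table.csv", index=False)
    provenance = {"config": config.to_dict(), "n_neurons": len(results)}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, sort_keys=True))
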