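"""End-to-end orchestration: simulate/read -> window -> segment -> featurize
-> normalize -> test, as a configured, logged, reproducible run."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import AggregationError, ConfigError, PipelineError
from .features import (
    FEATURES,
    NormalizedFeatureTable,
    normalize_to_baseline,
    per_cycle_features,
    window_mean,
)
from .io import (
    CHANNELS,
    WINDOW_LABELS,
    ImuRecording,
    analysis_windows,
    extract_window,
    read_imu_csv,
    relative_angles,
    write_imu_csv,
    write_strikes,
)
from .segmentation import segment_cycles
from .simulate import FatigueEffect, GaitSimConfig, SimulatedBout, simulate_cohort
from .stats import CohortTable, StatReport, run_battery

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``mode`` selects the input source: ``"simulate"`` generates a seeded
    synthetic cohort, ``"read"`` ingests per-subject CSV files from
    ``input_dir``. All downstream stages are deterministic, so a run is
    fully reproduced by its config and seed.
    """

    mode: str = "simulate"
    input_dir: str | None = None
    out_dir: str | None = None
    n_subjects: int = 18
    duration_min: float = 60.0
    sample_rate: float = 50.0
    window_minutes: tuple[int, int, int] = (1, 30, 60)
    cadence_jitter_cv: float = 0.03
    effects: list[FatigueEffect] = field(default_factory=list)
    baseline_orientation_s: float = 30.0
    min_cycle_s: float = 0.6
    max_cycle_s: float = 2.5
    biased_moments: bool = True
    alpha: float = 0.05
    m_comparisons: int = 3
    friedman_method: str = "chisq"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "read"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if len(self.window_minutes) != 3:
            raise ConfigError("exactly three analysis windows are required")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.mode == "read" and not self.input_dir:
            raise ConfigError("read mode requires input_dir")
        self.window_minutes = tuple(self.window_minutes)
        self.effects = [
            e if isinstance(e, FatigueEffect) else FatigueEffect(**e)
            for e in self.effects
        ]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["effects"] = [dataclasses.asdict(e) for e in self.effects]
        d["window_minutes"] = list(self.window_minutes)
        return d


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    report: StatReport
    subject_tables: list[NormalizedFeatureTable]
    manifest: dict


def sim_config_from_run(config: RunConfig) -> GaitSimConfig:
    """Simulator configuration implied by a pipeline run configuration."""
    return GaitSimConfig(
        sample_rate=config.sample_rate,
        duration_min=config.duration_min,
        cadence_jitter_cv=config.cadence_jitter_cv,
        effects=tuple(config.effects),
        window_minutes=config.window_minutes,
        seed=config.seed,
    )


def analyze_recording(
    recording: ImuRecording,
    window_minutes: Sequence[int] = (1, 30, 60),
    baseline_orientation_s: float = 30.0,
    min_cycle_s: float = 0.6,
    max_cycle_s: float = 2.5,
    biased_moments: bool = True,
) -> NormalizedFeatureTable:
    """One subject's full feature path, raw recording -> normalized ratios.

    Orientation channels are first re-expressed relative to the first
    ``baseline_orientation_s`` seconds of walking; the three analysis
    windows are then extracted, segmented into complete gait cycles,
    featurized per cycle, averaged per window and normalized to the
    baseline window. A window with no complete cycles leaves NaN ratios
    (flagged, excluded listwise downstream).
    """
    rec = relative_angles(recording, baseline_span_s=baseline_orientation_s)
    means: dict[str, pd.DataFrame] = {}
    counts: dict[str, int] = {}
    for spec in analysis_windows(window_minutes):
        window = extract_window(rec, spec)
        cycles = segment_cycles(window, min_cycle_s=min_cycle_s, max_cycle_s=max_cycle_s)
        counts[spec.label] = len(cycles)
        matrix = per_cycle_features(window, cycles, biased=biased_moments)
        try:
            means[spec.label] = window_mean(matrix)
        except AggregationError:
            logger.warning(
                "subject %s window %s: no complete cycles; window flagged",
                recording.subject_id, spec.label,
            )
            means[spec.label] = pd.DataFrame(
                np.nan, index=list(CHANNELS), columns=list(FEATURES)
            )
    if (means[WINDOW_LABELS[0]].isna()).all().all():
        # baseline unusable: every ratio of this subject is undefined
        table = NormalizedFeatureTable(
            subject_id=recording.subject_id,
            ratios={
                w: pd.DataFrame(np.nan, index=list(CHANNELS), columns=list(FEATURES))
                for w in WINDOW_LABELS
            },
            n_cycles=counts,
        )
        return table
    return normalize_to_baseline(means, subject_id=recording.subject_id, n_cycles=counts)


def _load_recordings(config: RunConfig) -> list[ImuRecording]:
    in_dir = Path(config.input_dir)
    if not in_dir.is_dir():
        raise ConfigError(f"input_dir {in_dir} does not exist")
    paths = sorted(
        p for p in in_dir.glob("*.csv") if not p.stem.endswith("_strikes")
    )
    if not paths:
        raise ConfigError(f"no recording CSVs found in {in_dir}")
    return [read_imu_csv(p, sample_rate=config.sample_rate) for p in paths]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute a full cohort run and (optionally) write its artifacts.

    Deterministic given the config and seed. When ``config.out_dir`` is
    set, writes the omnibus and post hoc report tables, the per-subject
    normalized feature table, and a JSON manifest (config echo, versions,
    per-subject cycle counts, exclusions).
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if config.mode == "simulate":
        bouts = simulate_cohort(
            n_subjects=config.n_subjects,
            config=sim_config_from_run(config),
            seed=config.seed,
        )
        recordings = [b.recording for b in bouts]
    else:
        recordings = _load_recordings(config)

    subject_tables = [
        analyze_recording(
            rec,
            window_minutes=config.window_minutes,
            baseline_orientation_s=config.baseline_orientation_s,
            min_cycle_s=config.min_cycle_s,
            max_cycle_s=config.max_cycle_s,
            biased_moments=config.biased_moments,
        )
        for rec in recordings
    ]
    usable = [
        t for t in subject_tables
        if not t.ratios[WINDOW_LABELS[0]].isna().all().all()
    ]
    if len(usable) < 2:
        raise PipelineError(
            f"only {len(usable)} subject(s) usable after exclusions; "
            "at least 2 are required for the repeated-measures battery"
        )
    cohort = CohortTable.from_subject_tables(usable)
    report = run_battery(
        cohort,
        alpha=config.alpha,
        m_comparisons=config.m_comparisons,
        friedman_method=config.friedman_method,
    )
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "n_subjects_input": len(subject_tables),
        "n_subjects_used": len(usable),
        "cycle_counts": {t.subject_id: t.n_cycles for t in subject_tables},
        "block_exclusions": {
            f"{c}/{f}": subs for (c, f), subs in cohort.exclusions.items()
        },
        "n_significant_blocks": report.count_significant(),
    }
    if config.out_dir:
        _write_artifacts(Path(config.out_dir), report, subject_tables, manifest)
    return PipelineResult(report=report, subject_tables=subject_tables, manifest=manifest)


def _write_artifacts(
    out_dir: Path,
    report: StatReport,
    subject_tables: list[NormalizedFeatureTable],
    manifest: dict,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.friedman_p.to_csv(out_dir / "friedman_pvalues.csv")
    report.friedman_table().to_csv(out_dir / "friedman_table.csv")
    report.posthoc.to_csv(out_dir / "posthoc.csv", index=False)
    report.posthoc_table().to_csv(out_dir / "posthoc_table.csv", index=False)
    pd.concat(
        [t.to_frame() for t in subject_tables], ignore_index=True
    ).to_csv(out_dir / "features_normalized.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def write_cohort(
    bouts: Sequence[SimulatedBout], out_dir, float_format: str = "%.6f"
) -> list[Path]:
    """Write a simulated cohort as per-subject CSVs plus strike sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for bout in bouts:
        rec = bout.recording
        path = out_dir / f"{rec.subject_id}.csv"
        write_imu_csv(rec, path, float_format=float_format)
        write_strikes(bout.strikes, rec.sample_rate, out_dir / f"{rec.subject_id}_strikes.csv")
        paths.append(path)
    return paths
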