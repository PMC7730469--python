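"""Per-cycle signal statistics, window aggregation, baseline normalization.

Ten statistics are computed per gait cycle and channel: median absolute
deviation (MAD), excess kurtosis, skewness, root mean square (RMS),
variance, maximum and minimum absolute value, amplitude range, median of
the absolute value, and signal power ("energy consumption", EC). All
moment-based statistics use population (divide-by-n) conventions, so the
per-cycle identity ``EC = RMS**2`` holds exactly; a biased=False switch
enables small-sample-corrected kurtosis/skewness for sensitivity checks.

Within each of the three analysis windows the per-cycle values are
averaged, and each subject's window averages are divided by that
subject's baseline-window averages. Every outcome is therefore a unitless
ratio with the baseline identically 1, removing between-subject scale
differences before any cohort statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, BoundsError
from .io import CHANNELS, ImuRecording, WINDOW_LABELS
from .segmentation import GaitCycle

logger = logging.getLogger(__name__)

#: Canonical feature order.
FEATURES: tuple[str, ...] = (
    "mad", "kurtosis", "skewness", "rms", "variance",
    "max_abs", "min_abs", "range", "median_abs", "ec",
)


def _stats_block(seg: np.ndarray, biased: bool = True) -> np.ndarray:
    """All ten statistics along the last axis of ``seg``.

    ``seg`` has shape ``(..., n_samples)``; the result has shape
    ``(..., 10)`` in :data:`FEATURES` order. Zero-variance inputs get
    kurtosis = skewness = 0 (the 0/0 limit is taken as the value for a
    degenerate constant signal).
    """
    n = seg.shape[-1]
    med = np.median(seg, axis=-1)
    absseg = np.abs(seg)
    mad = np.median(np.abs(seg - med[..., None]), axis=-1)
    mean = seg.mean(axis=-1)
    dev = seg - mean[..., None]
    m2 = (dev * dev).mean(axis=-1)
    # skewness/kurtosis are scale-free: normalize deviations by their max
    # so tiny or huge signals cannot under/overflow the moment ratios
    scale = np.abs(dev).max(axis=-1)
    devn = dev / np.where(scale > 0, scale, 1.0)[..., None]
    devn2 = devn * devn
    m2n = devn2.mean(axis=-1)
    m3n = (devn2 * devn).mean(axis=-1)
    m4n = (devn2 * devn2).mean(axis=-1)
    safe = np.where(m2n > 0, m2n, 1.0)  # m2n >= 1/n when nonzero
    skew = np.where(m2n > 0, m3n / safe**1.5, 0.0)
    kurt = np.where(m2n > 0, m4n / safe**2 - 3.0, 0.0)
    if not biased and n > 3:
        g2 = kurt
        skew = np.sqrt(n * (n - 1)) / (n - 2) * skew
        kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * g2 + 6.0)
    ec = np.mean(seg * seg, axis=-1)
    rms = np.sqrt(ec)
    mx, mn = seg.max(axis=-1), seg.min(axis=-1)
    return np.stack([
        mad, kurt, skew, rms, m2,
        absseg.max(axis=-1), absseg.min(axis=-1), mx - mn,
        np.median(absseg, axis=-1), ec,
    ], axis=-1)


def feature_value(x: Sequence[float], feature: str, biased: bool = True) -> float:
    """One statistic of one sample sequence.

    ``feature`` is a member of :data:`FEATURES`. Kurtosis, skewness and
    variance need at least two samples. A zero-variance input yields
    kurtosis = skewness = 0 (logged) rather than 0/0.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input sequence")
    if feature in ("kurtosis", "skewness", "variance") and x.size < 2:
        raise ValueError(f"{feature} undefined for a single sample")
    if feature in ("kurtosis", "skewness") and np.ptp(x) == 0:
        logger.debug("zero-variance input: %s defined as 0", feature)
    row = _stats_block(x[None, :], biased=biased)[0]
    return float(row[FEATURES.index(feature)])


def _batched_cycle_stats(
    data: np.ndarray, cycles: Sequence[GaitCycle], biased: bool
) -> np.ndarray:
    """Per-cycle statistics, batching cycles of equal length.

    With mild duration jitter a window holds only a few distinct cycle
    lengths, so grouping by length lets every statistic run vectorized
    over ``(n_cycles_of_length, 9, length)`` blocks. Returns an array of
    shape ``(9, 10, n_cycles)``.
    """
    out = np.empty((data.shape[0], len(FEATURES), len(cycles)))
    lengths = np.array([c.end - c.start for c in cycles])
    starts = np.array([c.start for c in cycles])
    for length in np.unique(lengths):
        which = np.flatnonzero(lengths == length)
        idx = starts[which][:, None] + np.arange(length)
        seg = data[:, idx]  # (9, n_group, length)
        stats = _stats_block(np.swapaxes(seg, 0, 1), biased=biased)
        out[:, :, which] = np.moveaxis(stats, 0, -1)
    return out


@dataclass
class FeatureMatrix:
    """Per-cycle statistics of one analysis window.

    ``values`` has shape ``(9 channels, 10 features, n_cycles)`` in
    :data:`CHANNELS` x :data:`FEATURES` order.
    """

    window_label: str
    values: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.values.shape[2]

    def sequence(self, channel: str, feature: str) -> np.ndarray:
        return self.values[CHANNELS.index(channel), FEATURES.index(feature)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: window, channel, feature, cycle, value."""
        idx = pd.MultiIndex.from_product(
            [CHANNELS, FEATURES, range(self.n_cycles)],
            names=["channel", "feature", "cycle"],
        )
        frame = pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()
        frame.insert(0, "window", self.window_label)
        return frame


def per_cycle_features(
    window: ImuRecording, cycles: Sequence[GaitCycle], biased: bool = True
) -> FeatureMatrix:
    """Compute all ten statistics for every channel and gait cycle."""
    label = window.meta.get("window", "window")
    for cyc in cycles:
        if cyc.start < 0 or cyc.end > window.n_samples or cyc.start >= cyc.end:
            raise BoundsError(f"cycle {cyc} outside window of {window.n_samples} samples")
    if not cycles:
        values = np.empty((len(CHANNELS), len(FEATURES), 0))
    else:
        values = _batched_cycle_stats(window.data, cycles, biased)
    return FeatureMatrix(window_label=label, values=values)


def window_mean(matrix: FeatureMatrix) -> pd.DataFrame:
    """Across-cycle arithmetic mean of each (channel, feature).

    Returns a channels x features DataFrame. A window with no complete
    cycles has no defined aggregate and raises; the pipeline flags and
    excludes such subject-windows instead of imputing.
    """
    if matrix.n_cycles == 0:
        raise AggregationError(
            f"window {matrix.window_label!r} has no complete gait cycles"
        )
    return pd.DataFrame(
        matrix.values.mean(axis=2), index=list(CHANNELS), columns=list(FEATURES)
    )


@dataclass
class NormalizedFeatureTable:
    """One subject's window aggregates as ratios to the baseline window.

    ``ratios`` maps each window label to a channels x features DataFrame;
    the baseline entries are exactly 1. Entries whose baseline aggregate
    is zero are NaN (flagged missing, never infinity).
    """

    subject_id: str
    ratios: dict[str, pd.DataFrame]
    n_cycles: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject, window, channel, feature, value."""
        rows = []
        for window, table in self.ratios.items():
            stacked = table.stack()
            frame = stacked.rename("value").reset_index()
            frame.columns = ["channel", "feature", "value"]
            frame.insert(0, "window", window)
            rows.append(frame)
        out = pd.concat(rows, ignore_index=True)
        out.insert(0, "subject", self.subject_id)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "list[NormalizedFeatureTable]":
        """Rebuild per-subject tables from the long interchange format."""
        tables = []
        for subject, group in frame.groupby("subject", sort=False):
            ratios = {}
            for window, wgroup in group.groupby("window", sort=False):
                ratios[str(window)] = wgroup.pivot(
                    index="channel", columns="feature", values="value"
                ).reindex(index=list(CHANNELS), columns=list(FEATURES))
            tables.append(cls(subject_id=str(subject), ratios=ratios))
        return tables


def normalize_to_baseline(
    means: Mapping[str, pd.DataFrame],
    subject_id: str = "",
    n_cycles: Mapping[str, int] | None = None,
) -> NormalizedFeatureTable:
    """Divide each window's aggregates by the baseline-window aggregates.

    ``means`` maps the three window labels to channels x features
    aggregate tables. Baseline entries of the result are set to exactly 1;
    a zero baseline aggregate makes the whole (channel, feature) column
    undefined (NaN, logged) for every window.
    """
    if WINDOW_LABELS[0] not in means:
        raise KeyError("baseline window aggregate is required")
    baseline = means[WINDOW_LABELS[0]]
    zero = baseline == 0
    if zero.to_numpy().any():
        bad = baseline.where(zero).stack().index.tolist()
        logger.warning(
            "subject %s: zero baseline aggregate for %s; ratios flagged missing",
            subject_id or "?", bad,
        )
    ratios: dict[str, pd.DataFrame] = {}
    for window, table in means.items():
        ratio = table / baseline
        ratio = ratio.mask(zero)
        ratios[window] = ratio
    ratios[WINDOW_LABELS[0]] = ratios[WINDOW_LABELS[0]].where(zero, 1.0)
    return NormalizedFeatureTable(
        subject_id=subject_id,
        ratios=ratios,
        n_cycles=dict(n_cycles or {}),
    )
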