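"""Landmark-based batch normalization.

Different acquisition batches shift the intensity distributions of a
channel even for identical biology.  On a transformed channel the cell
populations appear as density peaks ("low" and "high" expressing
cells); this module detects those peaks per sample, matches them across
samples by rank, and warps each sample so same-rank peaks land on a
common target position (the per-rank median across samples).

Peak detection: Gaussian KDE with Silverman's bandwidth evaluated on a
512-point grid; local maxima with prominence >= 5% of the global
density maximum are candidates, and the L most prominent-by-density are
kept.  Samples where fewer than L peaks are found are flagged for
manual override, supplied via a delimited peaks file — the scriptable
replacement for an interactive peak-edition loop.

Warping: the continuous piecewise-linear map sending a sample's peak
positions to the targets, with slope-1 (pure shift) extrapolation
beyond the outermost peaks.  It is strictly increasing whenever peaks
and targets are each strictly increasing, so within-sample event
ordering on the channel is preserved.  L = 1 degenerates to a global
shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .errors import (
    EstimationError,
    NormalizationInfeasibleError,
    WarpError,
)
from .model import Dataset, Sample

__all__ = [
    "LandmarkSpec",
    "LandmarkMap",
    "detect_peaks",
    "build_landmark_map",
    "normalize_dataset",
    "read_peaks_override",
]

KDE_GRID_POINTS = 512
PROMINENCE_FRACTION = 0.05
MIN_EVENTS = 200


@dataclass
class LandmarkSpec:
    """Which channels to align, how many peaks each, manual overrides.

    ``expected_peaks`` maps channel label -> number of landmarks L >= 1.
    ``overrides`` maps (sample_id, channel) -> sorted peak positions
    (length L), taking precedence over automatic detection.
    """

    expected_peaks: dict[str, int]
    overrides: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, L in self.expected_peaks.items():
            if L < 1:
                raise ValueError(f"expected_peaks[{ch!r}] must be >= 1, got {L}")
        for (sid, ch), pos in self.overrides.items():
            pos = tuple(float(p) for p in pos)
            self.overrides[(sid, ch)] = pos
            if list(pos) != sorted(pos):
                raise ValueError(f"override for ({sid!r}, {ch!r}) must be sorted ascending")
            L = self.expected_peaks.get(ch)
            if L is not None and len(pos) != L:
                raise ValueError(
                    f"override for ({sid!r}, {ch!r}) has {len(pos)} positions, "
                    f"expected {L}"
                )


@dataclass
class LandmarkMap:
    detected: dict[tuple[str, str], tuple[float, ...]]
    targets: dict[str, tuple[float, ...]]
    needs_override: list[tuple[str, str]] = field(default_factory=list)


def detect_peaks(
    sample: Sample,
    channel: str,
    L: int,
    prominence_fraction: float = PROMINENCE_FRACTION,
    bandwidth: str | float = "silverman",
) -> tuple[tuple[float, ...], bool]:
    """Detect up to L density peaks on a (transformed) channel.

    Returns (sorted positions, flag); the flag is True when fewer than L
    candidate peaks were found, marking the (sample, channel) as needing
    a manual override.
    """
    if sample.n_events < MIN_EVENTS:
        raise EstimationError(
            f"peak detection needs >= {MIN_EVENTS} events, "
            f"sample {sample.sample_id!r} has {sample.n_events}"
        )
    x = sample.column(channel)
    kde = gaussian_kde(x, bw_method=bandwidth)
    grid = np.linspace(x.min(), x.max(), KDE_GRID_POINTS)
    density = kde(grid)
    idx, _ = find_peaks(density, prominence=prominence_fraction * density.max())
    if idx.size == 0:  # plateau-free monotone density: fall back to the mode
        idx = np.array([int(np.argmax(density))])
    order = np.argsort(density[idx])[::-1][:L]
    positions = np.sort(grid[idx[order]])
    return tuple(float(p) for p in positions), len(positions) < L


def build_landmark_map(dataset: Dataset, spec: LandmarkSpec) -> LandmarkMap:
    """Detect peaks for every (sample, channel) and derive targets.

    Overrides take precedence over detection.  The target for rank r is
    the median across samples of the rank-r peak position; flagged
    samples are excluded from the median.  A channel where more than half
    the samples are flagged cannot be normalized automatically and
    raises, mirroring the manual-intervention loop of interactive use.
    """
    detected: dict[tuple[str, str], tuple[float, ...]] = {}
    flagged: list[tuple[str, str]] = []
    for channel, L in spec.expected_peaks.items():
        for s in dataset.samples:
            key = (s.sample_id, channel)
            if key in spec.overrides:
                detected[key] = spec.overrides[key]
                continue
            positions, needs = detect_peaks(s, channel, L)
            detected[key] = positions
            if needs:
                flagged.append(key)
    targets: dict[str, tuple[float, ...]] = {}
    for channel, L in spec.expected_peaks.items():
        n_flagged = sum(1 for sid, ch in flagged if ch == channel)
        if n_flagged > 0.5 * len(dataset):
            raise NormalizationInfeasibleError(
                f"channel {channel!r}: {n_flagged}/{len(dataset)} samples need "
                "manual peak overrides; supply a peaks override file"
            )
        usable = [
            detected[(s.sample_id, channel)]
            for s in dataset.samples
            if (s.sample_id, channel) not in flagged
        ]
        per_rank = np.array(usable)  # (n_usable, L)
        targets[channel] = tuple(float(v) for v in np.median(per_rank, axis=0))
    return LandmarkMap(detected=detected, targets=targets, needs_override=flagged)


def _warp(x: np.ndarray, peaks: Sequence[float], targets: Sequence[float]) -> np.ndarray:
    peaks = np.asarray(peaks, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if np.any(np.diff(peaks) <= 0) or np.any(np.diff(targets) <= 0):
        raise WarpError("peaks and targets must each be strictly increasing")
    y = np.interp(x, peaks, targets)
    below = x < peaks[0]
    above = x > peaks[-1]
    y[below] = x[below] + (targets[0] - peaks[0])
    y[above] = x[above] + (targets[-1] - peaks[-1])
    return y


def normalize_dataset(
    dataset: Dataset, landmark_map: LandmarkMap
) -> tuple[Dataset, pd.DataFrame]:
    """Warp every sample so its peaks land on the channel targets.

    Returns the normalized dataset and a long-format before/after
    density table (sample_id, channel, grid, density_before,
    density_after) for QC plotting.
    """
    out = dataset.copy()
    qc_rows = []
    for channel, targets in landmark_map.targets.items():
        for s in out.samples:
            key = (s.sample_id, channel)
            peaks = landmark_map.detected.get(key)
            if peaks is None:
                raise WarpError(f"no landmarks for sample {s.sample_id!r}, channel {channel!r}")
            if len(peaks) != len(targets):
                raise WarpError(
                    f"sample {s.sample_id!r}, channel {channel!r}: {len(peaks)} "
                    f"peaks but {len(targets)} targets; supply an override"
                )
            j = s.channel_index(channel)
            before = s.events[:, j].copy()
            try:
                s.events[:, j] = _warp(before, peaks, targets)
            except WarpError as exc:
                raise WarpError(
                    f"non-monotone warp for sample {s.sample_id!r}, "
                    f"channel {channel!r}: {exc}"
                ) from exc
            grid = np.linspace(
                min(before.min(), s.events[:, j].min()),
                max(before.max(), s.events[:, j].max()),
                KDE_GRID_POINTS,
            )
            kb = gaussian_kde(before)(grid)
            ka = gaussian_kde(s.events[:, j])(grid)
            qc_rows.append(
                pd.DataFrame(
                    {
                        "sample_id": s.sample_id,
                        "channel": channel,
                        "grid": grid,
                        "density_before": kb,
                        "density_after": ka,
                    }
                )
            )
            s.log(
                "normalize",
                channel=channel,
                peaks=list(peaks),
                targets=list(targets),
            )
    qc = pd.concat(qc_rows, ignore_index=True) if qc_rows else pd.DataFrame(
        columns=["sample_id", "channel", "grid", "density_before", "density_after"]
    )
    return out, qc


def read_peaks_override(path: str | Path) -> dict[tuple[str, str], tuple[float, ...]]:
    """Read a TSV peaks override file (sample_id, channel, rank, position)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "channel", "rank", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peaks file missing columns: {sorted(missing)}")
    overrides: dict[tuple[str, str], tuple[float, ...]] = {}
    for (sid, ch), sub in df.groupby(["sample_id", "channel"]):
        sub = sub.sort_values("rank")
        overrides[(str(sid), str(ch))] = tuple(float(p) for p in sub["position"])
    return overrides
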