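"""Synthetic multi-sample, multi-group cytometry datasets.

Every pipeline stage is testable without external data: samples are
drawn from Gaussian mixtures over a marker panel with known population
structure, optional additive batch shifts, and optional spillover
mixing, with per-event ground-truth population labels kept in side
tables that the pipeline itself never sees.

Two generation modes:

``transformed``
    Events are drawn directly on the transformed (decades-like) scale
    where clustering and normalization operate.  Batch shifts are
    additive here, matching what landmark normalization corrects.
``linear``
    Population centers are interpreted as transformed-scale values,
    mapped through ``sinh`` to a linear scale, and optionally mixed
    through a spillover matrix — this exercises the transform and
    compensation stages with known ground truth.

The standard benchmark design — 8 populations with distinct binary
marker patterns over 6 channels, 2 groups x 4 samples, 10^4 events per
sample, a 0.4 transformed-unit batch shift on 2 channels for the second
batch, and one population whose weight differs between groups (30% vs
5%) — exercises every module and is what the test suite and the
reproduction script run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compensate import SpilloverMatrix
from .model import ChannelInfo, Dataset, Sample

__all__ = [
    "PopulationSpec",
    "SimulationDesign",
    "simulate_sample",
    "simulate_dataset",
    "benchmark_design",
    "load_design",
]


@dataclass
class PopulationSpec:
    """One cell population: mixture weight, per-channel mean and spread,
    and the true binary marker pattern it was built from."""

    name: str
    weight: float
    centers: dict[str, float]
    sigma: dict[str, float]
    binary_truth: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.weight <= 1):
            raise ValueError(f"population {self.name!r}: weight must be in (0, 1]")
        for ch, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"population {self.name!r}: sigma[{ch!r}] must be > 0")


@dataclass
class SimulationDesign:
    channels: list[str]
    groups: dict[str, int]  # group -> number of samples
    populations: dict[str, list[PopulationSpec]]  # per group
    n_events: int
    batch_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    spillover: SpilloverMatrix | None = None
    mode: str = "transformed"  # or "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("transformed", "linear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for group, pops in self.populations.items():
            total = sum(p.weight for p in pops)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"group {group!r}: population weights sum to {total}, expected 1"
                )

    def sample_ids(self) -> list[tuple[str, str]]:
        ids = []
        for group in self.groups:
            for r in range(1, self.groups[group] + 1):
                ids.append((f"{group}_{r:02d}", group))
        return ids


def _sample_seed(design_seed: int, sample_id: str) -> np.random.Generator:
    import hashlib

    digest = hashlib.sha256(sample_id.encode()).digest()
    return np.random.default_rng(
        [int(design_seed) % (2**31), int.from_bytes(digest[:4], "big") % (2**31)]
    )


def simulate_sample(
    design: SimulationDesign, sample_id: str
) -> tuple[Sample, pd.DataFrame]:
    """Draw one sample; returns (Sample, truth table).

    The truth table (event_row, population) lives outside the Sample so
    ground-truth labels can never leak into the pipeline.
    """
    group = dict(design.sample_ids()).get(sample_id)
    if group is None:
        raise KeyError(f"sample {sample_id!r} not in design")
    pops = design.populations[group]
    rng = _sample_seed(design.seed, sample_id)
    n = design.n_events
    assignment = rng.choice(len(pops), size=n, p=[p.weight for p in pops])
    events = np.empty((n, len(design.channels)), dtype=np.float64)
    for j, ch in enumerate(design.channels):
        mu = np.array([p.centers[ch] for p in pops])[assignment]
        sd = np.array([p.sigma[ch] for p in pops])[assignment]
        events[:, j] = rng.normal(mu, sd)

    for j, ch in enumerate(design.channels):
        shift = design.batch_shifts.get((sample_id, ch), 0.0)
        events[:, j] += shift

    keywords: dict[str, str] = {}
    if design.mode == "linear":
        # transformed-scale centers -> linear intensities; asinh-like scale
        events = np.sinh(events)
        if design.spillover is not None:
            idx = [design.channels.index(c) for c in design.spillover.channels]
            events[:, idx] = events[:, idx] @ design.spillover.matrix
            keywords["$SPILLOVER"] = design.spillover.to_keyword()

    channels = [
        ChannelInfo(short_name=ch, label=ch, role="fluorescence", index=j + 1)
        for j, ch in enumerate(design.channels)
    ]
    sample = Sample(
        sample_id=sample_id,
        events=events,
        channels=channels,
        group=group,
        keywords=keywords,
    )
    sample.log("simulate_sample", mode=design.mode, seed=int(design.seed))
    truth = pd.DataFrame(
        {
            "event_row": np.arange(n),
            "population": [pops[a].name for a in assignment],
        }
    )
    return sample, truth


def simulate_dataset(
    design: SimulationDesign,
) -> tuple[Dataset, dict[str, pd.DataFrame]]:
    """Draw every sample of the design; returns (Dataset, truth tables)."""
    samples, truths, groups = [], {}, {}
    for sample_id, group in design.sample_ids():
        s, truth = simulate_sample(design, sample_id)
        samples.append(s)
        truths[sample_id] = truth
        groups[sample_id] = group
    return Dataset(samples, groups), truths


# ---------------------------------------------------------------------------
# the standard benchmark design

# 8 distinct positivity patterns over 6 markers; none all-zero so every
# population is positive for something, as phenotyping assumes
_BENCHMARK_PATTERNS = (
    ("P1", (1, 0, 0, 0, 0, 0)),
    ("P2", (0, 1, 0, 0, 0, 0)),
    ("P3", (1, 1, 0, 0, 0, 0)),
    ("P4", (0, 0, 1, 1, 0, 0)),
    ("P5", (1, 0, 1, 0, 1, 0)),
    ("P6", (0, 1, 0, 1, 0, 1)),
    ("P7", (0, 0, 0, 0, 1, 1)),
    ("P8", (1, 1, 1, 1, 1, 1)),
)
# transformed-scale component means for negative/positive marker states
_NEG_CENTER, _POS_CENTER = 1.0, 3.0
_SIGMA = 0.15


def benchmark_design(
    seed: int = 0,
    n_events: int = 10_000,
    samples_per_group: int = 4,
    batch_shift: float = 0.4,
    differential_weights: tuple[float, float] = (0.30, 0.05),
    mode: str = "transformed",
    spillover: SpilloverMatrix | None = None,
) -> SimulationDesign:
    """The standard two-group benchmark.

    8 populations with distinct binary patterns over 6 channels
    (M1..M6).  The last population (P8) carries the group effect: its
    weight is ``differential_weights[0]`` in the disease group and
    ``[1]`` in the control group, the remaining weight being spread
    evenly over the other populations.  The second half of each group's
    samples forms batch 2 and is shifted by ``batch_shift`` transformed
    units on channels M1 and M2.
    """
    channels = [f"M{i}" for i in range(1, 7)]

    def pops_for(p8_weight: float) -> list[PopulationSpec]:
        rest = (1.0 - p8_weight) / (len(_BENCHMARK_PATTERNS) - 1)
        pops = []
        for name, bits in _BENCHMARK_PATTERNS:
            weight = p8_weight if name == "P8" else rest
            centers = {
                ch: (_POS_CENTER if b else _NEG_CENTER)
                for ch, b in zip(channels, bits)
            }
            pops.append(
                PopulationSpec(
                    name=name,
                    weight=weight,
                    centers=centers,
                    sigma={ch: _SIGMA for ch in channels},
                    binary_truth=dict(zip(channels, bits)),
                )
            )
        return pops

    groups = {"disease": samples_per_group, "control": samples_per_group}
    populations = {
        "disease": pops_for(differential_weights[0]),
        "control": pops_for(differential_weights[1]),
    }
    batch_shifts: dict[tuple[str, str], float] = {}
    if batch_shift:
        for group, count in groups.items():
            for r in range(count // 2 + 1, count + 1):  # second half = batch 2
                for ch in ("M1", "M2"):
                    batch_shifts[(f"{group}_{r:02d}", ch)] = batch_shift
    return SimulationDesign(
        channels=channels,
        groups=groups,
        populations=populations,
        n_events=n_events,
        batch_shifts=batch_shifts,
        spillover=spillover,
        mode=mode,
        seed=seed,
    )


def load_design(path) -> SimulationDesign:
    """Load a design from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    populations = {
        group: [PopulationSpec(**p) for p in pops]
        for group, pops in raw["populations"].items()
    }
    batch_shifts = {
        (e["sample_id"], e["channel"]): float(e["shift"])
        for e in raw.get("batch_shifts", [])
    }
    spill = None
    if "spillover" in raw:
        spill = SpilloverMatrix(
            tuple(raw["spillover"]["channels"]),
            np.asarray(raw["spillover"]["matrix"], dtype=float),
        )
    return SimulationDesign(
        channels=list(raw["channels"]),
        groups=dict(raw["groups"]),
        populations=populations,
        n_events=int(raw["n_events"]),
        batch_shifts=batch_shifts,
        spillover=spill,
        mode=raw.get("mode", "transformed"),
        seed=int(raw.get("seed", 0)),
    )
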