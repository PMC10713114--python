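"""Non-destructive gating: rectangle, polygon, quadrant and 1D interval.

A gate selects a cell subpopulation by geometry on one or two channels.
Applying a gate never deletes events; it sets a boolean membership tag
``gate:<gate_id>`` on every sample (quadrant gates set four tags
``gate:<id>:Q1..Q4``).  Gates form a tree: a child gate's membership is
ANDed with its parent's, so iterative gating strategies compose.

One global geometry should fit all samples once the data are
normalized, but per-sample geometry overrides are supported for the
stragglers.

Boundary convention: regions are closed on their lower/left bounds and
open on upper/right (half-open), so the four quadrants partition the
parent population exactly.  Polygon boundary points count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from matplotlib.path import Path as MplPath

from .errors import DependencyError, ChannelLookupError
from .model import Dataset, Sample

__all__ = ["Gate", "apply_gate", "gate_frequencies", "load_gates", "apply_gates"]

_SHAPES = ("rectangle", "polygon", "quadrant", "interval")
QUADRANT_SUFFIXES = ("Q1", "Q2", "Q3", "Q4")  # ++, -+, --, +-


@dataclass
class Gate:
    gate_id: str
    shape: str
    channels: tuple[str, ...]
    geometry: tuple
    parent: str = "root"
    overrides: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown gate shape {self.shape!r}")
        self.channels = tuple(self.channels)
        n_expected = 1 if self.shape == "interval" else 2
        if len(self.channels) != n_expected:
            raise ValueError(
                f"{self.shape} gate needs {n_expected} channel(s), got {len(self.channels)}"
            )
        self.geometry = self._check_geometry(self.geometry)
        self.overrides = {
            sid: self._check_geometry(geo) for sid, geo in self.overrides.items()
        }

    def _check_geometry(self, geo) -> tuple:
        if self.shape == "rectangle":
            xmin, xmax, ymin, ymax = (float(v) for v in geo)
            if xmin >= xmax or ymin >= ymax:
                raise ValueError(f"rectangle bounds must be ordered, got {geo}")
            return (xmin, xmax, ymin, ymax)
        if self.shape == "interval":
            lo, hi = (float(v) for v in geo)
            if lo >= hi:
                raise ValueError(f"interval bounds must be ordered, got {geo}")
            return (lo, hi)
        if self.shape == "quadrant":
            cx, cy = (float(v) for v in geo)
            return (cx, cy)
        vertices = tuple((float(x), float(y)) for x, y in geo)
        if len(vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        return vertices


def _polygon_mask(xy: np.ndarray, vertices: Sequence[tuple[float, float]]) -> np.ndarray:
    # contains_points' radius expands or shrinks depending on path
    # orientation; OR-ing both signs makes boundary points inside either way
    path = MplPath(np.asarray(vertices))
    eps = 1e-9
    return path.contains_points(xy, radius=eps) | path.contains_points(xy, radius=-eps)


def _membership(sample: Sample, gate: Gate) -> dict[str, np.ndarray]:
    geo = gate.overrides.get(sample.sample_id, gate.geometry)
    if gate.shape == "interval":
        x = sample.column(gate.channels[0])
        lo, hi = geo
        return {"": (x >= lo) & (x < hi)}
    x = sample.column(gate.channels[0])
    y = sample.column(gate.channels[1])
    if gate.shape == "rectangle":
        xmin, xmax, ymin, ymax = geo
        return {"": (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)}
    if gate.shape == "quadrant":
        cx, cy = geo
        xpos, ypos = x >= cx, y >= cy
        return {
            ":Q1": xpos & ypos,
            ":Q2": ~xpos & ypos,
            ":Q3": ~xpos & ~ypos,
            ":Q4": xpos & ~ypos,
        }
    return {"": _polygon_mask(np.column_stack([x, y]), geo)}


def apply_gate(dataset: Dataset, gate: Gate) -> Dataset:
    """Tag every sample's events with membership in the gate.

    Membership is ANDed with the parent gate's tag, so gating trees
    compose iteratively.  Raises :class:`DependencyError` if the parent
    tag has not been applied yet.
    """
    for ch in gate.channels:
        if ch not in dataset.channel_labels:
            raise ChannelLookupError(
                f"gate {gate.gate_id!r} uses unknown channel {ch!r}"
            )
    out = dataset.copy()
    for s in out.samples:
        if gate.parent != "root" and f"gate:{gate.parent}" not in s.tags:
            raise DependencyError(
                f"gate {gate.gate_id!r} requires parent tag "
                f"'gate:{gate.parent}', absent from sample {s.sample_id!r}"
            )
        parent_mask = s.tag_or_all(None if gate.parent == "root" else f"gate:{gate.parent}")
        for suffix, mask in _membership(s, gate).items():
            s.set_tag(f"gate:{gate.gate_id}{suffix}", mask & parent_mask)
        s.log(
            "apply_gate",
            gate_id=gate.gate_id,
            shape=gate.shape,
            parent=gate.parent,
            overridden=s.sample_id in gate.overrides,
        )
    return out


def gate_frequencies(
    dataset: Dataset, gate_id: str, parent: str = "root"
) -> pd.DataFrame:
    """Per-sample membership counts and percent-of-parent for one gate tag.

    An empty parent population yields percent 0 with a warning flag
    rather than a division error.
    """
    tag = f"gate:{gate_id}"
    rows = []
    for s in dataset.samples:
        if tag not in s.tags:
            raise ChannelLookupError(
                f"tag {tag!r} not found in sample {s.sample_id!r}; apply the gate first"
            )
        n_in = int(np.count_nonzero(s.tags[tag]))
        parent_mask = s.tag_or_all(None if parent == "root" else f"gate:{parent}")
        n_parent = int(np.count_nonzero(parent_mask))
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "n_in": n_in,
                "n_parent": n_parent,
                "percent": 100.0 * n_in / n_parent if n_parent else 0.0,
                "empty_parent": n_parent == 0,
            }
        )
    return pd.DataFrame(rows)


def load_gates(path: str | Path) -> list[Gate]:
    """Load a declarative gates file (YAML list, tree order)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    gates = []
    for entry in raw:
        gates.append(
            Gate(
                gate_id=entry["id"],
                shape=entry["shape"],
                channels=tuple(
                    [entry["channels"]] if isinstance(entry["channels"], str) else entry["channels"]
                ),
                geometry=entry["geometry"],
                parent=entry.get("parent", "root"),
                overrides=entry.get("overrides", {}),
            )
        )
    return gates


def apply_gates(dataset: Dataset, gates: Sequence[Gate]) -> Dataset:
    """Apply a whole gating strategy in order (parents before children)."""
    for gate in gates:
        dataset = apply_gate(dataset, gate)
    return dataset
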