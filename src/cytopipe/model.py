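"""Core in-memory containers: channels, samples, datasets.

A :class:`Sample` is one FCS file in memory: an events matrix (rows =
cells, columns = channels), channel metadata, named per-event tag vectors
(gate membership, downsample flag, split assignment, cluster labels) and
an append-only provenance log.  A :class:`Dataset` is an ordered
collection of samples sharing a channel panel, with a group assignment
per sample.

Events are stored transformed-in-place: each processing stage overwrites
the matrix and records itself in the provenance log, mirroring a
sequential checkpoint design.  Raw values are recoverable only by
applying inverse transforms, never cached.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import ChannelLookupError, DimensionError

__all__ = ["ChannelInfo", "Sample", "Dataset", "CHANNEL_ROLES"]

CHANNEL_ROLES = ("scatter", "fluorescence", "metal", "time", "derived")


@dataclass
class ChannelInfo:
    """One detector/parameter of the panel.

    Parameters
    ----------
    short_name : str
        The FCS ``$PnN`` short name; stable identity across samples.
    label : str
        User-facing name, renameable (exported as ``$PnS``).
    role : str
        One of ``scatter``, ``fluorescence``, ``metal``, ``time``,
        ``derived``.
    index : int
        1-based detector position within the current panel.
    """

    short_name: str
    label: str
    role: str = "fluorescence"
    index: int = 1

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}")


def _now() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


@dataclass
class Sample:
    sample_id: str
    events: np.ndarray
    channels: list[ChannelInfo]
    group: str = ""
    tags: dict[str, np.ndarray] = field(default_factory=dict)
    keywords: dict[str, str] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.float64)
        if self.events.ndim != 2:
            raise DimensionError("events must be a 2-D matrix")
        if self.events.shape[1] != len(self.channels):
            raise DimensionError(
                f"events has {self.events.shape[1]} columns but "
                f"{len(self.channels)} channels are declared"
            )
        for name, vec in self.tags.items():
            if len(vec) != self.n_events:
                raise DimensionError(
                    f"tag {name!r} has length {len(vec)}, expected {self.n_events}"
                )

    @property
    def n_events(self) -> int:
        return self.events.shape[0]

    @property
    def n_channels(self) -> int:
        return self.events.shape[1]

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, name: str) -> int:
        """0-based column index for a channel label or $PnN short name.

        Labels take precedence; falls back to short names so freshly read
        files can be addressed before renaming.
        """
        for i, c in enumerate(self.channels):
            if c.label == name:
                return i
        for i, c in enumerate(self.channels):
            if c.short_name == name:
                return i
        raise ChannelLookupError(
            f"channel {name!r} not found; available: {self.channel_labels}"
        )

    def column(self, name: str) -> np.ndarray:
        return self.events[:, self.channel_index(name)]

    def set_tag(self, name: str, values: np.ndarray) -> None:
        values = np.asarray(values)
        if len(values) != self.n_events:
            raise DimensionError(
                f"tag {name!r} has length {len(values)}, expected {self.n_events}"
            )
        self.tags[name] = values

    def tag_or_all(self, name: str | None) -> np.ndarray:
        """Boolean mask for a tag; the root (None or 'root') selects everything."""
        if name is None or name == "root":
            return np.ones(self.n_events, dtype=bool)
        if name not in self.tags:
            raise ChannelLookupError(f"tag {name!r} not found in sample {self.sample_id!r}")
        return np.asarray(self.tags[name], dtype=bool)

    def log(self, operation: str, **parameters) -> None:
        """Append one provenance entry (operation, parameters, timestamp)."""
        self.provenance.append(
            {"operation": operation, "parameters": parameters, "timestamp": _now()}
        )

    def copy(self) -> "Sample":
        return Sample(
            sample_id=self.sample_id,
            events=self.events.copy(),
            channels=[ChannelInfo(c.short_name, c.label, c.role, c.index) for c in self.channels],
            group=self.group,
            tags={k: v.copy() for k, v in self.tags.items()},
            keywords=dict(self.keywords),
            provenance=[dict(p) for p in self.provenance],
        )


class Dataset:
    """Ordered collection of samples with a shared panel and group map."""

    def __init__(self, samples: Sequence[Sample], groups: Mapping[str, str] | None = None):
        self.samples: list[Sample] = list(samples)
        if groups is None:
            groups = {s.sample_id: s.group for s in self.samples}
        self.groups: dict[str, str] = dict(groups)
        self._validate()

    def _validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in dataset")
        for s in self.samples:
            if s.sample_id not in self.groups:
                raise ValueError(f"sample {s.sample_id!r} has no group assignment")
            s.group = self.groups[s.sample_id]
        if self.samples:
            ref = self.samples[0].channel_labels
            for s in self.samples[1:]:
                if s.channel_labels != ref:
                    raise ValueError(
                        f"sample {s.sample_id!r} panel {s.channel_labels} "
                        f"differs from {ref}"
                    )

    @property
    def panel(self) -> list[ChannelInfo]:
        if not self.samples:
            return []
        return self.samples[0].channels

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.panel]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[Sample]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def copy(self) -> "Dataset":
        return Dataset([s.copy() for s in self.samples], dict(self.groups))

    def log_all(self, operation: str, **parameters) -> None:
        for s in self.samples:
            s.log(operation, **parameters)

    def pooled(self, labels: Sequence[str], tag: str | None = None) -> np.ndarray:
        """Stack the named channels of every sample (optionally tag-masked)."""
        cols = []
        for s in self.samples:
            mask = s.tag_or_all(tag)
            idx = [s.channel_index(l) for l in labels]
            cols.append(s.events[np.ix_(mask, idx)])
        return np.vstack(cols) if cols else np.empty((0, len(labels)))
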