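"""Spillover compensation.

Fluorophore emission spectra overlap, so each detector records a linear
mixture of the true signals: observed = true @ S, where S[i, j] is the
fraction of channel-i signal spilling into channel j (diagonal = 1).
Compensation right-multiplies by S^-1.  Spillover is linear in signal,
so when the dataset has already been transformed the covered channels
are inverse-transformed, compensated, and re-transformed.

The matrix comes either from the FCS ``$SPILLOVER``/``SPILL`` keyword
each sample carries, or from a single dataset-wide matrix file.  This
stage is generally irrelevant for mass cytometry and simply skipped
there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    AvailabilityError,
    ChannelLookupError,
    ConstraintError,
    NumericalError,
    SpilloverParseError,
)
from .model import Dataset, Sample
from .transform import TransformSpec, inverse_transform, transform_values

__all__ = [
    "SpilloverMatrix",
    "extract_spillover",
    "set_spillover",
    "apply_compensation",
    "read_spillover_csv",
    "write_spillover_csv",
]


@dataclass(frozen=True)
class SpilloverMatrix:
    channels: tuple[str, ...]
    matrix: np.ndarray  # square, row i = source channel, col j = target

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "channels", tuple(self.channels))
        n = len(self.channels)
        if m.shape != (n, n):
            raise SpilloverParseError(
                f"spillover matrix is {m.shape}, expected ({n}, {n})"
            )
        if not np.allclose(np.diag(m), 1.0):
            raise SpilloverParseError("spillover diagonal must be 1")
        if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
            raise NumericalError("spillover matrix is singular or near-singular")

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_keyword(self) -> str:
        vals = ",".join(repr(float(v)) for v in self.matrix.ravel())
        return f"{len(self.channels)},{','.join(self.channels)},{vals}"


def extract_spillover(sample: Sample) -> SpilloverMatrix | None:
    """Parse the sample's $SPILLOVER or SPILL keyword; None if absent.

    Keyword format: ``n,name_1,...,name_n,v_11,...,v_nn`` (row-major).
    """
    raw = sample.keywords.get("$SPILLOVER") or sample.keywords.get("SPILL")
    if raw is None:
        return None
    fields = [f.strip() for f in raw.split(",")]
    try:
        n = int(fields[0])
    except (ValueError, IndexError) as exc:
        raise SpilloverParseError(f"bad spillover keyword: {raw!r}") from exc
    if len(fields) != 1 + n + n * n:
        raise SpilloverParseError(
            f"spillover keyword declares n={n} but has {len(fields) - 1} "
            f"fields (expected {n} names + {n * n} values)"
        )
    names = fields[1 : 1 + n]
    try:
        values = np.array([float(v) for v in fields[1 + n :]], dtype=np.float64)
    except ValueError as exc:
        raise SpilloverParseError(f"non-numeric spillover value in {raw!r}") from exc
    return SpilloverMatrix(tuple(names), values.reshape(n, n))


def set_spillover(
    matrix: SpilloverMatrix, source: str, target: str, value: float
) -> SpilloverMatrix:
    """Return a copy with one off-diagonal coefficient changed."""
    for name in (source, target):
        if name not in matrix.channels:
            raise ChannelLookupError(
                f"channel {name!r} not in spillover matrix {list(matrix.channels)}"
            )
    if source == target:
        raise ConstraintError("the spillover diagonal is fixed at 1 and cannot be edited")
    i = matrix.channels.index(source)
    j = matrix.channels.index(target)
    m = matrix.matrix.copy()
    m[i, j] = value
    return SpilloverMatrix(matrix.channels, m)


def apply_compensation(
    dataset: Dataset,
    matrix: SpilloverMatrix | str,
    transform_specs: Mapping[str, TransformSpec] | None = None,
) -> Dataset:
    """Unmix spillover from the covered channels of every sample.

    ``matrix`` is either one :class:`SpilloverMatrix` for the whole
    dataset or the string ``"per-sample"`` to use each sample's embedded
    keyword.  If ``transform_specs`` is given the covered channels are
    inverse-transformed first (spillover algebra is only valid on the
    linear scale), compensated, then re-transformed.  A warning is
    emitted if provenance shows compensation already applied, since the
    operation is not idempotent.
    """
    per_sample = isinstance(matrix, str)
    if per_sample and matrix != "per-sample":
        raise ValueError(f"matrix must be a SpilloverMatrix or 'per-sample', got {matrix!r}")
    if not per_sample:
        unknown = set(matrix.channels) - set(dataset.channel_labels)
        if unknown:
            raise ChannelLookupError(
                f"spillover channels {sorted(unknown)} not in panel"
            )
    out = dataset.copy()
    for s in out.samples:
        if any(p["operation"] == "apply_compensation" for p in s.provenance):
            warnings.warn(
                f"sample {s.sample_id!r} already compensated; applying a "
                "spillover inverse twice is not idempotent",
                stacklevel=2,
            )
        if per_sample:
            sm = extract_spillover(s)
            if sm is None:
                raise AvailabilityError(
                    f"sample {s.sample_id!r} carries no $SPILLOVER/SPILL keyword"
                )
        else:
            sm = matrix
        idx = [s.channel_index(c) for c in sm.channels]
        block = s.events[:, idx]
        specs = {c: transform_specs[c] for c in sm.channels} if transform_specs else {}
        if specs:
            for k, c in enumerate(sm.channels):
                block[:, k] = inverse_transform(block[:, k], specs[c])
        block = block @ sm.inverse()
        if specs:
            for k, c in enumerate(sm.channels):
                block[:, k] = transform_values(block[:, k], specs[c])
        s.events[:, idx] = block
        s.log(
            "apply_compensation",
            channels=list(sm.channels),
            per_sample=per_sample,
            on_linear_scale=bool(specs),
        )
    return out


def read_spillover_csv(path: str | Path) -> SpilloverMatrix:
    """Read a spillover matrix from a delimited file (labels in the
    first row and first column)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise SpilloverParseError(
            "spillover file row labels must equal column labels"
        )
    return SpilloverMatrix(tuple(df.columns), df.to_numpy(dtype=np.float64))


def write_spillover_csv(matrix: SpilloverMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(matrix.matrix, index=matrix.channels, columns=matrix.channels).to_csv(path)
    return path
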