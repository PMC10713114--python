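"""Balanced downsampling, parameter-wise rescaling, cell-wise splitting.

Downsampling builds a subdataset in which every group contributes
equally and every sample of a group contributes equally to its group —
without deleting anything: selected cells are tagged ``downsampled``.
The largest quota satisfying both equality constraints without
replacement is Q = min over groups g of (m_g * min_{s in g} n_s),
where m_g is the number of samples in g and n_s the eligible events of
sample s; each sample of group g then contributes floor(Q / m_g) cells.

Rescaling maps each channel to [0, 1] by clipped percentile min-max
(defaults 0.1 / 99.9), computed over ALL events of ALL samples — the
downsample tag is deliberately ignored — so that highly expressed
parameters cannot overwhelm lowly expressed ones downstream purely by
absolute magnitude.

Splitting divides the cells of each sample (not the samples) into two
tagged halves ``split:A`` / ``split:B``, so both halves contain every
sample; useful for building training/validation datasets when groups
have too few samples to split sample-wise.
"""

from __future__ import annotations

import hashlib
from typing import Sequence

import numpy as np

from .errors import DegenerateChannelError, InfeasibilityError
from .model import Dataset

__all__ = ["downsample_balanced", "rescale", "split_dataset"]

DOWNSAMPLE_TAG = "downsampled"


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # per-sample substream: adding or reordering samples never perturbs
    # the draws of the others
    digest = hashlib.sha256(sample_id.encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([int(seed) % (2**31), sub])


def downsample_balanced(
    dataset: Dataset, base_tag: str | None = None, seed: int = 0
) -> Dataset:
    """Tag a balanced subset of events as ``downsampled``.

    ``base_tag`` restricts eligibility (e.g. a gate tag); None means all
    events.  Draws are uniform without replacement, seeded, with one
    substream per sample.  No events are removed.
    """
    out = dataset.copy()
    eligible: dict[str, np.ndarray] = {}
    for s in out.samples:
        idx = np.flatnonzero(s.tag_or_all(base_tag))
        if idx.size == 0:
            raise InfeasibilityError(
                f"sample {s.sample_id!r} has no eligible events under "
                f"tag {base_tag!r}"
            )
        eligible[s.sample_id] = idx

    by_group: dict[str, list[str]] = {}
    for s in out.samples:
        by_group.setdefault(s.group, []).append(s.sample_id)
    quota = min(
        len(members) * min(eligible[sid].size for sid in members)
        for members in by_group.values()
    )
    for s in out.samples:
        m_g = len(by_group[s.group])
        take = quota // m_g
        rng = _sample_rng(seed, s.sample_id)
        chosen = rng.choice(eligible[s.sample_id], size=take, replace=False)
        mask = np.zeros(s.n_events, dtype=bool)
        mask[chosen] = True
        s.set_tag(DOWNSAMPLE_TAG, mask)
        s.log(
            "downsample_balanced",
            base_tag=base_tag,
            seed=int(seed),
            group_quota=int(quota),
            taken=int(take),
        )
    return out


def rescale(
    dataset: Dataset,
    channels: Sequence[str] | None = None,
    lo_pct: float = 0.1,
    hi_pct: float = 99.9,
) -> Dataset:
    """Min-max rescale channels to [0, 1] using pooled clipped percentiles.

    Percentiles are pooled over every event of every sample regardless
    of the downsample tag; both bounds are recorded in provenance so the
    mapping is reproducible.
    """
    if not (0 <= lo_pct < hi_pct <= 100):
        raise ValueError(f"need 0 <= lo < hi <= 100, got ({lo_pct}, {hi_pct})")
    channels = list(channels) if channels is not None else list(dataset.channel_labels)
    out = dataset.copy()
    pooled = out.pooled(channels)
    p_lo = np.percentile(pooled, lo_pct, axis=0)
    p_hi = np.percentile(pooled, hi_pct, axis=0)
    for k, ch in enumerate(channels):
        if p_hi[k] <= p_lo[k]:
            raise DegenerateChannelError(
                f"channel {ch!r} is constant between percentiles "
                f"{lo_pct} and {hi_pct}; cannot rescale"
            )
    for s in out.samples:
        for k, ch in enumerate(channels):
            j = s.channel_index(ch)
            s.events[:, j] = np.clip(
                (s.events[:, j] - p_lo[k]) / (p_hi[k] - p_lo[k]), 0.0, 1.0
            )
        s.log(
            "rescale",
            channels=channels,
            lo_pct=lo_pct,
            hi_pct=hi_pct,
            p_lo=[float(v) for v in p_lo],
            p_hi=[float(v) for v in p_hi],
        )
    return out


def split_dataset(dataset: Dataset, fraction: float, seed: int = 0) -> Dataset:
    """Split each sample's cells into tagged halves ``split:A``/``split:B``.

    Eligibility is the ``downsampled`` tag when present, else all
    events; floor(fraction * n) cells go to A, the rest to B.  Every
    sample must end up with events in both halves.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    out = dataset.copy()
    for s in out.samples:
        base = (
            np.flatnonzero(s.tags[DOWNSAMPLE_TAG])
            if DOWNSAMPLE_TAG in s.tags
            else np.arange(s.n_events)
        )
        if base.size < 2:
            raise InfeasibilityError(
                f"sample {s.sample_id!r} has {base.size} eligible events; "
                "cannot split into two non-empty halves"
            )
        n_a = int(np.floor(fraction * base.size))
        n_a = min(max(n_a, 1), base.size - 1)  # both halves non-empty
        rng = _sample_rng(seed, s.sample_id)
        perm = rng.permutation(base)
        mask_a = np.zeros(s.n_events, dtype=bool)
        mask_b = np.zeros(s.n_events, dtype=bool)
        mask_a[perm[:n_a]] = True
        mask_b[perm[n_a:]] = True
        s.set_tag("split:A", mask_a)
        s.set_tag("split:B", mask_b)
        s.log("split_dataset", fraction=fraction, seed=int(seed), n_a=int(n_a))
    return out
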