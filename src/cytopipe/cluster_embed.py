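"""UMAP embedding and guided semi-supervised clustering.

The clustering method works in four stages on the downsampled,
rescaled events:

1. **Hierarchical training** — a random "training" subset of cells is
   clustered agglomeratively (Ward linkage, Euclidean distance) and the
   tree is cut at a deliberately large K_init (default 100).
2. **kNN propagation** — every remaining cell receives the majority
   label of its k nearest training cells (default k = 11); ties go to
   the label of the single nearest neighbor.
3. **Binarization** — each initial cluster is summarized as a bit
   vector of marker positivity: bit = 1 iff more than half its cells
   exceed the channel's positivity threshold.
4. **Collapse** — clusters with identical bit vectors merge; then,
   while more than K_max remain (default 40, the upper end of the
   "reasonable" 10-40 range), the pair at smallest Hamming distance
   merges, recomputing the pooled phenotype after each merge.  Final
   clusters are renumbered by decreasing size.

Positivity thresholds are normally set by eye on the marker
distributions; :func:`estimate_thresholds` provides an automated
default (KDE valley between the two main modes, else the pooled
median), and any threshold can be overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde
from sklearn.neighbors import NearestNeighbors

from .errors import InfeasibilityError, ParameterError
from .model import Dataset
from .partition import DOWNSAMPLE_TAG

__all__ = [
    "EmbeddingResult",
    "ClusterModel",
    "BinaryPhenotype",
    "run_umap",
    "train_hierarchical",
    "knn_assign",
    "binarize_phenotypes",
    "collapse_clusters",
    "guided_cluster",
    "estimate_thresholds",
    "attach_labels",
]

UMAP_DEFAULTS = {"n_neighbors": 15, "min_dist": 0.1, "metric": "euclidean"}
DEFAULT_TRAINING_FRACTION = 0.1
DEFAULT_K_INIT = 100
DEFAULT_K_NN = 11
DEFAULT_K_MAX = 40


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # (n_tagged, 2)
    params: dict
    event_index: list[tuple[str, int]]  # embedding row -> (sample_id, event row)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coordinates, columns=["UMAP1", "UMAP2"])
        df.insert(0, "sample_id", [sid for sid, _ in self.event_index])
        df.insert(1, "event_row", [r for _, r in self.event_index])
        return df


@dataclass
class BinaryPhenotype:
    bits: dict[str, int]
    derivation: dict[str, float]  # channel -> fraction of cells positive

    def vector(self, channels: Sequence[str]) -> tuple[int, ...]:
        return tuple(self.bits[c] for c in channels)


@dataclass
class ClusterModel:
    channels: tuple[str, ...]
    training_index: np.ndarray  # rows into the tagged-event matrix
    training_labels: np.ndarray  # 1..K_init
    linkage_method: str
    k_init: int
    k_nn: int = DEFAULT_K_NN
    thresholds: dict[str, float] = field(default_factory=dict)
    phenotypes: dict[int, BinaryPhenotype] = field(default_factory=dict)
    collapse_map: dict[int, int] = field(default_factory=dict)
    k_final: int = 0


def _tagged_matrix(
    dataset: Dataset, channels: Sequence[str]
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    blocks, index = [], []
    for s in dataset.samples:
        if DOWNSAMPLE_TAG not in s.tags:
            raise InfeasibilityError(
                f"sample {s.sample_id!r} has no '{DOWNSAMPLE_TAG}' tag; "
                "run downsample_balanced first"
            )
        rows = np.flatnonzero(s.tags[DOWNSAMPLE_TAG])
        cols = [s.channel_index(c) for c in channels]
        blocks.append(s.events[np.ix_(rows, cols)])
        index.extend((s.sample_id, int(r)) for r in rows)
    return np.vstack(blocks), index


def run_umap(
    dataset: Dataset,
    channels: Sequence[str],
    params: Mapping | None = None,
    seed: int = 0,
) -> EmbeddingResult:
    """2-D UMAP of all downsampled-tagged events over the stated channels.

    Deterministic for a given seed: a fixed random_state forces
    single-threaded layout.
    """
    import umap  # deferred: numba compilation is slow at import

    p = dict(UMAP_DEFAULTS)
    p.update(params or {})
    X, index = _tagged_matrix(dataset, channels)
    if X.shape[0] < p["n_neighbors"] + 1:
        raise InfeasibilityError(
            f"UMAP needs more than n_neighbors={p['n_neighbors']} tagged "
            f"events, got {X.shape[0]}"
        )
    reducer = umap.UMAP(
        n_neighbors=p["n_neighbors"],
        min_dist=p["min_dist"],
        metric=p["metric"],
        n_components=2,
        random_state=int(seed),
    )
    coords = np.asarray(reducer.fit_transform(X), dtype=np.float64)
    return EmbeddingResult(
        coordinates=coords,
        params={**p, "seed": int(seed)},
        event_index=index,
    )


def train_hierarchical(
    dataset: Dataset,
    channels: Sequence[str],
    training_fraction: float = DEFAULT_TRAINING_FRACTION,
    k_init: int = DEFAULT_K_INIT,
    seed: int = 0,
    linkage_method: str = "ward",
) -> ClusterModel:
    """Agglomerative clustering of a random training subset, cut at k_init."""
    X, _ = _tagged_matrix(dataset, channels)
    n = X.shape[0]
    if n < k_init * 10:
        raise InfeasibilityError(
            f"need >= {k_init * 10} tagged events to train with k_init={k_init}, got {n}"
        )
    n_train = int(np.floor(training_fraction * n)) if training_fraction < 1.0 else n
    if n_train < k_init:
        raise InfeasibilityError(
            f"training set of {n_train} events is smaller than k_init={k_init}"
        )
    rng = np.random.default_rng(int(seed) % (2**31))
    training_index = np.sort(rng.choice(n, size=n_train, replace=False))
    Z = linkage(X[training_index], method=linkage_method, metric="euclidean")
    labels = fcluster(Z, t=k_init, criterion="maxclust")
    return ClusterModel(
        channels=tuple(channels),
        training_index=training_index,
        training_labels=labels.astype(np.int64),
        linkage_method=linkage_method,
        k_init=int(k_init),
    )


def knn_assign(
    model: ClusterModel,
    dataset: Dataset,
    channels: Sequence[str] | None = None,
    k_nn: int = DEFAULT_K_NN,
) -> np.ndarray:
    """Propagate training labels to every tagged event by k-nearest neighbors.

    Majority vote among the k nearest training cells (Euclidean on the
    rescaled channels); vote ties resolve to the label of the single
    nearest neighbor.  Training cells keep their own labels.
    """
    channels = tuple(channels) if channels is not None else model.channels
    if k_nn > len(model.training_index):
        raise ParameterError(
            f"k_nn={k_nn} exceeds training size {len(model.training_index)}"
        )
    X, _ = _tagged_matrix(dataset, channels)
    train_X = X[model.training_index]
    labels = np.zeros(X.shape[0], dtype=np.int64)
    labels[model.training_index] = model.training_labels
    query_rows = np.setdiff1d(np.arange(X.shape[0]), model.training_index)
    if query_rows.size:
        nn = NearestNeighbors(n_neighbors=k_nn).fit(train_X)
        _, nbr = nn.kneighbors(X[query_rows])
        nbr_labels = model.training_labels[nbr]  # (n_query, k)
        out = np.empty(query_rows.size, dtype=np.int64)
        for i in range(query_rows.size):
            counts = np.bincount(nbr_labels[i])
            best = counts.max()
            winners = np.flatnonzero(counts == best)
            if winners.size == 1:
                out[i] = winners[0]
            else:  # tie: label of the single nearest neighbor
                out[i] = nbr_labels[i, 0]
        labels[query_rows] = out
    model.k_nn = int(k_nn)
    return labels


def binarize_phenotypes(
    X: np.ndarray,
    labels: np.ndarray,
    channels: Sequence[str],
    thresholds: Mapping[str, float],
) -> dict[int, BinaryPhenotype]:
    """Summarize each cluster as a positivity bit vector.

    For cluster c and channel j, derivation = fraction of member events
    strictly above the channel threshold; bit = 1 iff that fraction
    exceeds one half (strict).  Empty clusters are simply absent.
    """
    missing = set(channels) - set(thresholds)
    if missing:
        raise ParameterError(f"thresholds missing for channels {sorted(missing)}")
    phenos: dict[int, BinaryPhenotype] = {}
    for c in np.unique(labels):
        member = X[labels == c]
        bits, deriv = {}, {}
        for j, ch in enumerate(channels):
            frac = float(np.mean(member[:, j] > thresholds[ch]))
            deriv[ch] = frac
            bits[ch] = int(frac > 0.5)
        phenos[int(c)] = BinaryPhenotype(bits=bits, derivation=deriv)
    return phenos


def collapse_clusters(
    phenotypes: Mapping[int, BinaryPhenotype],
    k_max: int = DEFAULT_K_MAX,
    sizes: Mapping[int, int] | None = None,
    channels: Sequence[str] | None = None,
) -> tuple[dict[int, int], dict[int, BinaryPhenotype]]:
    """Merge clusters by binary proximity of their phenotypes.

    Stage 1 merges clusters with identical bit vectors.  Stage 2 then
    greedily merges the pair at smallest Hamming distance until at most
    ``k_max`` remain, recomputing the merged phenotype from the pooled
    member events (size-weighted positivity fractions).  Ties break to
    the pair containing the smallest cluster, then to lowest IDs.
    Returns (initial-ID -> final-ID map, final phenotypes) with final
    IDs 1..K_final ordered by decreasing size.
    """
    if k_max < 1:
        raise ParameterError(f"k_max must be >= 1, got {k_max}")
    ids = sorted(phenotypes)
    if channels is None:
        channels = sorted(phenotypes[ids[0]].bits) if ids else []
    channels = list(channels)
    sizes = {i: (sizes[i] if sizes else 1) for i in ids}

    # working state: groups of initial IDs with pooled fractions
    groups: dict[int, dict] = {
        i: {
            "members": [i],
            "n": sizes[i],
            "frac": np.array([phenotypes[i].derivation[c] for c in channels]),
        }
        for i in ids
    }

    def bits_of(g) -> tuple[int, ...]:
        return tuple(int(f > 0.5) for f in g["frac"])

    def merge(a: int, b: int) -> None:
        ga, gb = groups[a], groups[b]
        n = ga["n"] + gb["n"]
        frac = (ga["n"] * ga["frac"] + gb["n"] * gb["frac"]) / n
        groups[a] = {"members": sorted(ga["members"] + gb["members"]), "n": n, "frac": frac}
        del groups[b]

    # stage 1: identical bit vectors
    changed = True
    while changed:
        changed = False
        keys = sorted(groups)
        seen: dict[tuple, int] = {}
        for k in keys:
            v = bits_of(groups[k])
            if v in seen:
                merge(seen[v], k)
                changed = True
            else:
                seen[v] = k

    # stage 2: greedy smallest-Hamming merging down to k_max
    while len(groups) > k_max:
        keys = sorted(groups)
        best = None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                ham = sum(
                    x != y for x, y in zip(bits_of(groups[a]), bits_of(groups[b]))
                )
                min_size = min(groups[a]["n"], groups[b]["n"])
                cand = (ham, min_size, a, b)
                if best is None or cand < best:
                    best = cand
        merge(best[2], best[3])

    # renumber 1..K_final by decreasing pooled size (ties: lowest member id)
    ordered = sorted(groups.values(), key=lambda g: (-g["n"], g["members"][0]))
    collapse_map: dict[int, int] = {}
    final_phenos: dict[int, BinaryPhenotype] = {}
    for new_id, g in enumerate(ordered, start=1):
        for member in g["members"]:
            collapse_map[member] = new_id
        final_phenos[new_id] = BinaryPhenotype(
            bits={c: int(f > 0.5) for c, f in zip(channels, g["frac"])},
            derivation={c: float(f) for c, f in zip(channels, g["frac"])},
        )
    return collapse_map, final_phenos


def estimate_thresholds(
    dataset: Dataset, channels: Sequence[str], overrides: Mapping[str, float] | None = None
) -> dict[str, float]:
    """Automated positivity cutoffs per channel.

    If the pooled KDE is bimodal the threshold is the minimum-density
    valley between the two highest peaks; otherwise the pooled median.
    User overrides always win.
    """
    overrides = dict(overrides or {})
    X = dataset.pooled(channels, tag=None)
    out: dict[str, float] = {}
    for j, ch in enumerate(channels):
        if ch in overrides:
            out[ch] = float(overrides[ch])
            continue
        x = X[:, j]
        kde = gaussian_kde(x)
        grid = np.linspace(x.min(), x.max(), 512)
        density = kde(grid)
        peaks, _ = find_peaks(density, prominence=0.05 * density.max())
        if peaks.size >= 2:
            top2 = peaks[np.argsort(density[peaks])[::-1][:2]]
            lo, hi = np.sort(top2)
            valley = lo + int(np.argmin(density[lo : hi + 1]))
            out[ch] = float(grid[valley])
        else:
            out[ch] = float(np.median(x))
    return out


def attach_labels(dataset: Dataset, labels: np.ndarray, tag: str = "cluster") -> Dataset:
    """Store final per-event integer labels as a tag (0 = not clustered)."""
    out = dataset.copy()
    pos = 0
    for s in out.samples:
        rows = np.flatnonzero(s.tags[DOWNSAMPLE_TAG])
        vec = np.zeros(s.n_events, dtype=np.int64)
        vec[rows] = labels[pos : pos + rows.size]
        pos += rows.size
        s.set_tag(tag, vec)
        s.log("guided_cluster", tag=tag)
    if pos != len(labels):
        raise InfeasibilityError(
            f"label vector length {len(labels)} does not match tagged events {pos}"
        )
    return out


def guided_cluster(
    dataset: Dataset,
    channels: Sequence[str],
    thresholds: Mapping[str, float] | None = None,
    training_fraction: float = DEFAULT_TRAINING_FRACTION,
    k_init: int = DEFAULT_K_INIT,
    k_nn: int = DEFAULT_K_NN,
    k_max: int = DEFAULT_K_MAX,
    seed: int = 0,
    embedding: EmbeddingResult | None = None,
) -> tuple[Dataset, np.ndarray, ClusterModel, pd.DataFrame | None]:
    """Full guided semi-supervised clustering of the tagged events.

    Orchestrates training, kNN propagation, binarization and collapse;
    returns (dataset with 'cluster' tag, final labels aligned to the
    tagged-event matrix, fitted model, optional UMAP overlay table).
    """
    channels = tuple(channels)
    if thresholds is None:
        thresholds = estimate_thresholds(dataset, channels)
    model = train_hierarchical(dataset, channels, training_fraction, k_init, seed)
    initial_labels = knn_assign(model, dataset, channels, k_nn)
    X, _ = _tagged_matrix(dataset, channels)
    model.thresholds = dict(thresholds)
    model.phenotypes = binarize_phenotypes(X, initial_labels, channels, thresholds)
    sizes = {int(c): int(n) for c, n in zip(*np.unique(initial_labels, return_counts=True))}
    collapse_map, final_phenos = collapse_clusters(
        model.phenotypes, k_max, sizes=sizes, channels=channels
    )
    model.collapse_map = collapse_map
    model.k_final = len(final_phenos)
    final_labels = np.array([collapse_map[int(l)] for l in initial_labels], dtype=np.int64)
    tagged = attach_labels(dataset, final_labels)
    overlay = None
    if embedding is not None:
        overlay = embedding.to_frame()
        overlay["cluster"] = final_labels
    return tagged, final_labels, model, overlay
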