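"""Cluster phenotype/abundance outputs, sample-level UMAP, group
statistics, outlier flagging and ROC analysis.

After clustering, each sample is summarized by the percentage of its
clustered cells falling in each final cluster.  That abundance table is
the substrate for everything here: phenotype heatmaps, nonparametric
group comparisons with Benjamini-Hochberg correction, a sample-level
UMAP (samples as points in abundance space, metadata joined for
coloring, outliers flagged but never removed), and ROC curves for any
per-sample feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kruskal, rankdata, ranksums
from statsmodels.stats.multitest import multipletests

from .errors import InfeasibilityError, ParameterError
from .model import Dataset

__all__ = [
    "phenotype_table",
    "abundance_table",
    "sample_umap",
    "group_compare",
    "roc_analysis",
    "ROCResult",
]


def phenotype_table(
    dataset: Dataset,
    channels: Sequence[str],
    label_tag: str = "cluster",
) -> pd.DataFrame:
    """Median rescaled intensity per (final cluster, channel).

    Rows are clusters ordered by ID; label 0 (unclustered events) is
    excluded.
    """
    pooled, labels = [], []
    for s in dataset.samples:
        if label_tag not in s.tags:
            raise InfeasibilityError(f"sample {s.sample_id!r} lacks tag {label_tag!r}")
        lab = np.asarray(s.tags[label_tag])
        mask = lab > 0
        cols = [s.channel_index(c) for c in channels]
        pooled.append(s.events[np.ix_(mask, cols)])
        labels.append(lab[mask])
    X = np.vstack(pooled)
    lab = np.concatenate(labels)
    rows = {}
    for c in np.unique(lab):
        rows[int(c)] = np.median(X[lab == c], axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(channels))
    df.index.name = "cluster"
    return df.sort_index()


def abundance_table(
    dataset: Dataset,
    label_tag: str = "cluster",
) -> pd.DataFrame:
    """Percent of each sample's clustered events in each final cluster.

    Rows sum to 100; clusters absent from a sample are zero-filled; a
    group column is appended.  Samples with no clustered events are
    excluded with a warning.
    """
    all_clusters: set[int] = set()
    per_sample: dict[str, np.ndarray] = {}
    for s in dataset.samples:
        lab = np.asarray(s.tags[label_tag])
        lab = lab[lab > 0]
        if lab.size == 0:
            warnings.warn(
                f"sample {s.sample_id!r} has no clustered events; excluded "
                "from the abundance table",
                stacklevel=2,
            )
            continue
        per_sample[s.sample_id] = lab
        all_clusters.update(int(c) for c in np.unique(lab))
    clusters = sorted(all_clusters)
    rows = {}
    for sid, lab in per_sample.items():
        counts = np.array([np.count_nonzero(lab == c) for c in clusters], dtype=float)
        rows[sid] = 100.0 * counts / lab.size
    df = pd.DataFrame.from_dict(rows, orient="index", columns=clusters)
    df.index.name = "sample_id"
    df["group"] = [dataset.groups[sid] for sid in df.index]
    return df


def _abundance_matrix(abundance: pd.DataFrame) -> tuple[np.ndarray, list]:
    cols = [c for c in abundance.columns if c != "group"]
    return abundance[cols].to_numpy(dtype=float), cols


def sample_umap(
    abundance: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    seed: int = 0,
    n_neighbors: int | None = None,
    min_dist: float = 0.1,
) -> pd.DataFrame:
    """UMAP of samples in cluster-abundance space.

    Returns one row per sample with UMAP1/UMAP2 coordinates, the group,
    joined metadata columns, and an ``outlier`` flag: True when the
    sample's nearest-neighbor distance in abundance space exceeds the
    median + 3 * MAD of those distances.  Outliers are only flagged,
    never removed.
    """
    import umap

    X, _ = _abundance_matrix(abundance)
    n = X.shape[0]
    if n_neighbors is None:
        n_neighbors = min(15, n - 1)
    if n < n_neighbors + 1:
        raise InfeasibilityError(
            f"sample UMAP needs more than n_neighbors={n_neighbors} samples, got {n}"
        )
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=2,
        random_state=int(seed),
    )
    coords = np.asarray(reducer.fit_transform(X), dtype=np.float64)

    # nearest-neighbor distance in the original abundance space
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_dist = np.sqrt(d2.min(axis=1))
    med = np.median(nn_dist)
    mad = np.median(np.abs(nn_dist - med))
    outlier = nn_dist > med + 3.0 * mad if mad > 0 else np.zeros(n, dtype=bool)

    out = pd.DataFrame(
        {
            "sample_id": abundance.index,
            "group": abundance["group"].to_numpy(),
            "UMAP1": coords[:, 0],
            "UMAP2": coords[:, 1],
            "nn_distance": nn_dist,
            "outlier": outlier,
        }
    ).set_index("sample_id")
    if metadata is not None:
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        out = out.join(meta, how="left")
    return out


def group_compare(abundance: pd.DataFrame) -> pd.DataFrame:
    """Nonparametric per-cluster frequency comparison across groups.

    Two groups: two-sided Wilcoxon rank-sum; more: Kruskal-Wallis.
    P-values are Benjamini-Hochberg adjusted across clusters.
    """
    X, clusters = _abundance_matrix(abundance)
    groups = abundance["group"].to_numpy()
    names, counts = np.unique(groups, return_counts=True)
    if len(names) < 2 or np.any(counts < 2):
        raise ParameterError(
            f"group comparison needs >= 2 groups with >= 2 samples each; "
            f"got {dict(zip(names, counts))}"
        )
    rows = []
    for j, cluster in enumerate(clusters):
        vals = [X[groups == g, j] for g in names]
        if len(names) == 2:
            stat, p = ranksums(vals[0], vals[1])
            test = "wilcoxon_rank_sum"
        else:
            if np.ptp(np.concatenate(vals)) == 0:  # kruskal rejects all-identical
                stat, p = 0.0, 1.0
            else:
                stat, p = kruskal(*vals)
            test = "kruskal_wallis"
        row = {"cluster": cluster, "test": test, "statistic": stat, "p": p}
        for g, v in zip(names, vals):
            row[f"median_{g}"] = float(np.median(v))
        rows.append(row)
    df = pd.DataFrame(rows)
    df["p_adjusted"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    positive_group: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_analysis(
    values: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str],
    positive_group: str,
) -> ROCResult:
    """Empirical ROC of a per-sample feature for separating two classes.

    The feature may be a cluster abundance, a manually computed score —
    any per-sample real value; higher values are taken to indicate the
    positive group.  The curve sweeps every distinct observed value as a
    cutoff (predict positive when value >= cutoff).  AUC uses the
    rank-based (Mann-Whitney) formulation, which handles ties and equals
    the trapezoidal area under the empirical curve on tie-free data.
    The Youden cutoff maximizes sensitivity + specificity - 1, ties
    resolving to the lower cutoff.
    """
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    y = np.array([groups[sid] == positive_group for sid in series.index], dtype=bool)
    x = series.to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError(
            f"ROC needs both classes non-empty; positive={n_pos}, negative={n_neg}"
        )

    # rank-based AUC (midranks handle ties)
    ranks = rankdata(x)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    cutoffs = np.unique(x)  # ascending; predict positive when x >= cutoff
    sens = np.array([np.mean(x[y] >= c) for c in cutoffs])
    spec = np.array([np.mean(x[~y] < c) for c in cutoffs])
    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())[0]  # lower cutoff on ties
    return ROCResult(
        thresholds=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        youden_cutoff=float(cutoffs[best]),
        positive_group=positive_group,
    )
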