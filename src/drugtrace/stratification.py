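"""Cohort stratification by drug-exposure profiles and downstream group
tests.

Samples are clustered on log(1 + summed peak area) exposure matrices by
agglomerative hierarchical clustering (Ward linkage, Euclidean distance by
default).  Metabolite differences between the resulting exposure groups are
tested with a Kruskal-Wallis omnibus followed by all pairwise two-sided
Mann-Whitney rank-sum tests with Benjamini-Hochberg adjustment over the
pairwise family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterAssignment",
    "cluster_samples",
    "group_difference_test",
    "chi_square_independence",
]


@dataclass(frozen=True)
class ClusterAssignment:
    labels: dict[str, int]  # sample id -> cluster label, 1..k
    method: str
    metric: str
    k: int

    def __post_init__(self) -> None:
        found = set(self.labels.values())
        if found != set(range(1, self.k + 1)):
            raise ValueError(
                f"labels must be contiguous 1..{self.k}, found {sorted(found)}"
            )

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {c: [] for c in range(1, self.k + 1)}
        for sample, label in self.labels.items():
            out[label].append(sample)
        return out


def cluster_samples(
    matrix: pd.DataFrame,
    k: int,
    method: str = "ward",
    metric: str = "euclidean",
    log_transform: bool = True,
) -> ClusterAssignment:
    """Hierarchical clustering of samples (rows) by exposure profile.

    Areas are transformed as log(1 + x) (handles zeros) unless the caller
    already transformed.  The dendrogram is cut at ``k`` groups and labels
    are renumbered by decreasing cluster size for reproducible reports.
    """
    if not 1 <= k <= len(matrix):
        raise ValueError(f"k must be in [1, n_samples={len(matrix)}]")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("exposure matrix must be finite")
    if log_transform:
        values = np.log1p(values)
    if k == len(matrix):
        raw = np.arange(1, len(matrix) + 1)
    else:
        linkage = hierarchy.linkage(pdist(values, metric=metric), method=method)
        raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    # renumber by decreasing size; ties by first occurrence
    order = sorted(
        set(raw),
        key=lambda c: (-(raw == c).sum(), int(np.argmax(raw == c))),
    )
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = {
        str(sample): remap[c] for sample, c in zip(matrix.index, raw)
    }
    return ClusterAssignment(labels=labels, method=method, metric=metric, k=k)


def group_difference_test(
    values: pd.Series, clusters: ClusterAssignment
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus plus BH-adjusted pairwise rank-sum tests.

    ``values`` is one metabolite's per-sample intensity, indexed by sample
    id.  Groups with fewer than 2 members are excluded with a warning.
    Returns the omnibus p-value and a long DataFrame with columns
    group_a, group_b, p_raw, p_adjusted.
    """
    groups = {}
    for label, members in clusters.groups().items():
        present = [m for m in members if m in values.index]
        if len(present) < 2:
            warnings.warn(f"cluster {label} has < 2 samples with data; excluded")
            continue
        groups[label] = values.loc[present].to_numpy(dtype=float)
    if len(groups) < 2:
        raise ValueError("need at least two groups with >= 2 members each")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        # all observations tied: zero evidence against the null
        statistic, omnibus_p = 0.0, 1.0
    else:
        statistic, omnibus_p = stats.kruskal(*arrays)
    pairs = list(combinations(sorted(groups), 2))
    raw = []
    for a, b in pairs:
        _, p = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
        raw.append(p)
    adjusted = multipletests(raw, method="fdr_bh")[1] if raw else []
    table = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_adjusted": adjusted,
        }
    )
    table.attrs["omnibus_statistic"] = float(statistic)
    return float(omnibus_p), table


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns (statistic, degrees of freedom, p-value); raises on negative
    counts or a zero row/column marginal.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("table has a zero marginal")
    statistic, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(statistic), int(df), float(p)
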