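"""Down-sampled one-way ANOVA between two genetic clusters.

Genetic clusters can differ greatly in how many accessions they contain
(e.g. 75 vs 13), which biases a single ANOVA. The down-sampling scheme
repeatedly draws the same number of accessions (default 13) from each
cluster without replacement, runs a classical one-way ANOVA on each draw,
and aggregates the per-run p-values — the median p and the fraction of
runs significant at alpha.

Accessions are assigned to clusters by majority membership proportion.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ClusterCompareResult", "one_way_anova", "downsampled_anova", "cluster_compare_screen", "majority_cluster"]


@dataclasses.dataclass
class ClusterCompareResult:
    feature_id: str
    cluster_a: str
    cluster_b: str
    n_runs: int
    n_downsample: int
    p_values: np.ndarray
    median_p: float
    fraction_significant: float
    alpha: float
    mean_a: float
    mean_b: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.median_p <= 1.0):
            raise ValueError("median_p outside [0, 1]")
        if not (0.0 <= self.fraction_significant <= 1.0):
            raise ValueError("fraction_significant outside [0, 1]")


def one_way_anova(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Two-group one-way ANOVA: F = MS_between / MS_within, df (1, n-2).

    Degenerate cases: zero within-group variance with equal group means
    gives (0, 1); with unequal means the F statistic is infinite and p 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 observations")
    n = len(values)
    grand = values.mean()
    ssb = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ssw = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ssw == 0:
        if ssb == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / 1.0) / (ssw / (n - 2))
    p = float(stats.f.sf(f, 1, n - 2))
    return float(f), p


def majority_cluster(membership: pd.DataFrame) -> pd.Series:
    """Assign each accession to its highest-membership cluster."""
    return membership.idxmax(axis=1)


def downsampled_anova(
    x: pd.Series,
    clusters: pd.Series,
    a: str,
    b: str,
    n_down: int = 13,
    runs: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
    feature_id: str = "",
) -> ClusterCompareResult:
    """Repeated equal-size ANOVA between clusters ``a`` and ``b``.

    Per run, ``n_down`` accessions are drawn without replacement from each
    cluster and a one-way ANOVA is run on their values of ``x``
    (accession-mean abundance of one feature).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids_a = clusters.index[clusters == a]
    ids_b = clusters.index[clusters == b]
    if len(ids_a) < n_down or len(ids_b) < n_down:
        raise ValueError(
            f"cluster sizes ({len(ids_a)}, {len(ids_b)}) below n_down={n_down}"
        )
    va = x.loc[ids_a].to_numpy(dtype=float)
    vb = x.loc[ids_b].to_numpy(dtype=float)
    labels = np.array([0] * n_down + [1] * n_down)
    ps = np.empty(runs)
    for r in range(runs):
        sa = va[rng.choice(len(va), size=n_down, replace=False)]
        sb = vb[rng.choice(len(vb), size=n_down, replace=False)]
        _, ps[r] = one_way_anova(np.concatenate([sa, sb]), labels)
    return ClusterCompareResult(
        feature_id=feature_id,
        cluster_a=a,
        cluster_b=b,
        n_runs=runs,
        n_downsample=n_down,
        p_values=ps,
        median_p=float(np.median(ps)),
        fraction_significant=float((ps < alpha).mean()),
        alpha=alpha,
        mean_a=float(va.mean()),
        mean_b=float(vb.mean()),
    )


def cluster_compare_screen(
    means: pd.DataFrame,
    clusters: pd.Series,
    a: str,
    b: str,
    n_down: int = 13,
    runs: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Down-sampled ANOVA for every feature column of an accession-mean table.

    A feature is called differential when its median p < 0.05.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for fid in means.columns:
        res = downsampled_anova(
            means[fid], clusters, a, b, n_down=n_down, runs=runs, alpha=alpha,
            seed=rng, feature_id=str(fid),
        )
        rows.append(
            dict(
                feature_id=str(fid), median_p=res.median_p,
                fraction_significant=res.fraction_significant,
                mean_a=res.mean_a, mean_b=res.mean_b,
                differential=res.median_p < 0.05,
            )
        )
    return pd.DataFrame(rows).set_index("feature_id")
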