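"""Pairwise accession distance matrices and ordinations.

Chemical dissimilarity between accessions is Bray-Curtis on accession-mean
relative abundances, computed over all features or over the subset
belonging to one NPC pathway (alkaloids, terpenoids, ...). Classical
principal coordinates analysis (PCoA) summarises a distance matrix into a
low-dimensional configuration; Euclidean distance on the first few axes
gives a denoised "ordination distance". Geographic distance is planar
Euclidean on GPS coordinates; environmental and life-history distances are
Euclidean on the first PCA axes of standardized covariate tables; genetic
cluster membership distances are absolute differences of admixture
proportions.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "bray_curtis",
    "pcoa",
    "ordination_distance",
    "standardize",
    "pca",
    "pca_distance",
    "euclidean_geographic",
    "membership_distance",
    "membership_distances",
    "select_uncorrelated",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with accession labels."""

    labels: list[str]
    d: np.ndarray
    kind: str = "euclidean"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(self.d)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if self.d.min(initial=0.0) < -1e-12:
            raise ValueError("negative distances")
        if self.kind == "bray_curtis" and self.d.max(initial=0.0) > 1 + 1e-9:
            raise ValueError("Bray-Curtis entries must be <= 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        return squareform(self.d, checks=False)

    def triangle_violations(self) -> int:
        """Count of (i, j, k) triples violating the triangle inequality.

        Bray-Curtis is a semimetric: violations are legal and merely
        counted for reporting.
        """
        d = self.d
        n = self.n
        count = 0
        for k in range(n):
            count += int(np.sum(d > d[:, [k]] + d[[k], :] + 1e-12) // 2)
        return count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str = "euclidean"):
        return cls(list(frame.index), frame.to_numpy(dtype=float), kind)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[str(l)] for l in labels])
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], self.kind)


@dataclasses.dataclass
class Ordination:
    """Low-dimensional coordinates plus per-axis variance fractions."""

    coordinates: pd.DataFrame  # accession x axis
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray

    def __post_init__(self) -> None:
        vf = np.asarray(self.variance_fraction, dtype=float)
        if (vf < -1e-12).any() or (vf > 1 + 1e-12).any():
            raise ValueError("variance fractions outside [0, 1]")
        if np.any(np.diff(vf) > 1e-12):
            raise ValueError("variance fractions must be non-increasing")
        if vf.sum() > 1 + 1e-9:
            raise ValueError("variance fractions sum above 1")


def bray_curtis(
    x: pd.DataFrame, feature_subset: Sequence[str] | None = None
) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between accession-mean profiles.

    d(i, j) = sum_f |x_if - x_jf| / sum_f (x_if + x_jf), over the given
    feature subset (default: all columns). Entries lie in [0, 1].
    """
    if feature_subset is not None:
        feature_subset = list(feature_subset)
        if not feature_subset:
            raise ValueError("empty feature subset")
        missing = set(feature_subset) - set(x.columns)
        if missing:
            raise ValueError(f"features not in table: {sorted(missing)}")
        x = x[feature_subset]
    vals = x.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("Bray-Curtis requires non-negative abundances")
    rowsum = vals.sum(axis=1)
    zero = np.flatnonzero(rowsum == 0)
    if len(zero) >= 2 or (len(zero) == 1 and len(vals) > 1):
        bad = [x.index[i] for i in zero]
        raise ValueError(
            f"all-zero profile(s) make pairwise denominators zero: {bad}"
        )
    d = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(list(x.index), d, kind="bray_curtis")


def pcoa(d: DistanceMatrix, k: int = 3) -> Ordination:
    """Classical scaling (principal coordinates analysis).

    Eigendecomposes the double-centered -0.5 * D^2 Gower matrix. Negative
    eigenvalues (non-Euclidean distances) are excluded from both the
    returned axes and the variance-fraction denominator.
    """
    n = d.n
    a = -0.5 * d.d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = 1e-9 * max(abs(eigval[0]), 1.0)
    pos = eigval > tol
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes, not {k}"
        )
        k = n_pos
    lam = eigval[:k]
    coords = eigvec[:, :k] * np.sqrt(lam)
    vf = lam / eigval[pos].sum() if n_pos else np.zeros(0)
    return Ordination(
        coordinates=pd.DataFrame(
            coords, index=d.labels, columns=[f"PCo{i + 1}" for i in range(k)]
        ),
        eigenvalues=lam,
        variance_fraction=vf,
    )


def ordination_distance(ord_: Ordination, kind: str = "euclidean") -> DistanceMatrix:
    """Euclidean distances on ordination scores (PCoA- or PCA-axis space)."""
    coords = ord_.coordinates
    d = squareform(pdist(coords.to_numpy(dtype=float)))
    return DistanceMatrix(list(coords.index), d, kind=kind)


def standardize(table: pd.DataFrame, by: str = "sd") -> pd.DataFrame:
    """Center each column and scale to unit spread.

    ``by='sd'`` (default) is conventional z-scoring (divide by the sample
    standard deviation); ``by='variance'`` divides by the variance instead,
    for compatibility with tools that phrase scaling that way.
    """
    if by not in ("sd", "variance"):
        raise ValueError("by must be 'sd' or 'variance'")
    out = {}
    for col in table.columns:
        v = table[col].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0 or table[col].nunique() < 2:
            raise ValueError(f"constant column {col!r} cannot be standardized")
        scale = sd if by == "sd" else sd**2
        out[col] = (v - v.mean()) / scale
    return pd.DataFrame(out, index=table.index)


def pca(table: pd.DataFrame, n_axes: int = 3) -> Ordination:
    """PCA by SVD of a column-centered table.

    Variance fractions come from squared singular values. The input is
    expected to be standardized already when a correlation-matrix PCA is
    intended.
    """
    x = table.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in PCA input")
    x = x - x.mean(axis=0)
    u, sv, vt = np.linalg.svd(x, full_matrices=False)
    var = sv**2
    rank = int((sv > 1e-12 * max(sv[0], 1.0)).sum())
    if n_axes > rank:
        warnings.warn(f"rank {rank} < requested {n_axes} axes; reducing")
        n_axes = rank
    scores = u[:, :n_axes] * sv[:n_axes]
    vf = var[:n_axes] / var.sum()
    return Ordination(
        coordinates=pd.DataFrame(
            scores, index=table.index, columns=[f"PC{i + 1}" for i in range(n_axes)]
        ),
        eigenvalues=var[:n_axes] / (len(table) - 1),
        variance_fraction=vf,
    )


def pca_distance(
    table: pd.DataFrame, n_axes: int = 3
) -> tuple[Ordination, DistanceMatrix]:
    """PCA-reduce a standardized covariate table, then Euclidean distance.

    This is the construction used for environmental and life-history
    distances: z-scored variables -> PCA -> Euclidean distance on the
    first ``n_axes`` score columns. The Ordination carries the variance
    fraction explained per axis (their sum is the reported "% of variation
    accounted for").
    """
    ord_ = pca(table, n_axes=n_axes)
    return ord_, ordination_distance(ord_)


def euclidean_geographic(coords: pd.DataFrame) -> DistanceMatrix:
    """Planar Euclidean distance on GPS coordinates (degrees as-is).

    ``coords`` holds one row per accession with two columns (longitude,
    latitude). Raw degrees are treated as planar coordinates; use
    :func:`great_circle_geographic` when a spherical treatment is wanted.
    """
    v = coords.to_numpy(dtype=float)
    if v.shape[1] != 2:
        raise ValueError("expected two coordinate columns (lon, lat)")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite coordinates")
    d = squareform(pdist(v))
    return DistanceMatrix(list(coords.index), d, kind="euclidean")


def great_circle_geographic(coords: pd.DataFrame, radius_km: float = 6371.0) -> DistanceMatrix:
    """Haversine great-circle distance (km) as the spherical alternative."""
    lon = np.radians(coords.iloc[:, 0].to_numpy(dtype=float))
    lat = np.radians(coords.iloc[:, 1].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * radius_km * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    return DistanceMatrix(list(coords.index), d, kind="euclidean")


def membership_distance(m: pd.Series) -> DistanceMatrix:
    """|m_i - m_j| on one cluster's membership proportions."""
    v = m.to_numpy(dtype=float)
    if (v < 0).any() or (v > 1).any():
        raise ValueError("membership proportions must lie in [0, 1]")
    d = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(list(m.index), d, kind="membership")


def membership_distances(m: pd.DataFrame) -> dict[str, DistanceMatrix]:
    """One membership distance matrix per cluster column."""
    return {str(c): membership_distance(m[c]) for c in m.columns}


def select_uncorrelated(table: pd.DataFrame, threshold: float = 0.7) -> list[str]:
    """Greedy screen keeping variables with pairwise |Pearson r| < threshold.

    Columns are scanned in input order; a column is dropped if its |r|
    with any already-retained column is >= threshold.
    """
    if table.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    retained: list[str] = []
    for col in table.columns:
        ok = True
        for kept in retained:
            r = np.corrcoef(
                table[col].to_numpy(dtype=float), table[kept].to_numpy(dtype=float)
            )[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            retained.append(col)
    return retained


# Variable lists the screen settled on for the study system; shipped as
# defaults for Dataset S1-shaped metadata tables.
ENVIRONMENTAL_VARIABLES = [
    "annual_mean_temperature",
    "isothermality",
    "temperature_seasonality",
    "annual_precipitation",
    "precipitation_seasonality",
    "humanized_habitat",
    "topsoil_ph",
]
LIFE_HISTORY_TRAITS = [
    "seed_weight",
    "dsds50",
    "germination",
    "recruitment",
    "survival",
    "flowering_time",
    "fecundity",
]
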